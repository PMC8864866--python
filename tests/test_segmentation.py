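"""Detector training, inference, refinement, HITL and cropping contracts."""

import numpy as np
import pytest

from aplvision import synthgen
from aplvision.errors import DataError, InvalidConfigError, StateError
from aplvision.evaluation import iou, mean_ap_ar
from aplvision.geometry import ellipse_mask_window
from aplvision.segmentation import (DetectedRegion, DetectorConfig, crop_cells,
                                    detect_cells, detections_to_annotations,
                                    hitl_round, load_model, nms,
                                    refine_ellipse, save_model, train_detector)
from conftest import mixed_spec


def subset(ds, ids):
    return [ds.images[i] for i in ids], [ds.annotations[i] for i in ids]


class TestTrainDetector:
    def test_loss_decreases_over_epochs(self, trained_detector):
        hist = trained_detector.loss_history
        assert len(hist) == trained_detector.config.epochs
        assert hist[-1] < hist[0]

    def test_zero_epochs_returns_untrained_flagged_model(self, tiny_dataset):
        imgs, anns = subset(tiny_dataset, tiny_dataset.image_ids()[:2])
        model = train_detector(imgs, anns, DetectorConfig(epochs=0))
        assert not model.is_trained
        with pytest.raises(StateError):
            detect_cells(model, imgs[0])

    def test_empty_training_set_rejected(self):
        with pytest.raises(DataError):
            train_detector([], [], DetectorConfig())

    def test_same_seed_reproduces_final_loss(self, tiny_dataset):
        imgs, anns = subset(tiny_dataset, tiny_dataset.image_ids()[:3])
        cfg = DetectorConfig(seed=9, epochs=3)
        m1 = train_detector(imgs, anns, cfg)
        m2 = train_detector(imgs, anns, cfg)
        assert m1.loss_history[-1] == pytest.approx(m2.loss_history[-1],
                                                    abs=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            DetectorConfig(score_threshold=1.5)
        with pytest.raises(InvalidConfigError):
            DetectorConfig(crop_size=0)


class TestDetectCells:
    def test_threshold_one_gives_no_detections(self, tiny_dataset,
                                               trained_detector):
        img = tiny_dataset.images[tiny_dataset.image_ids()[6]]
        assert detect_cells(trained_detector, img, score_threshold=1.0) == []

    def test_count_close_to_truth_on_held_out_smear(self, trained_detector):
        spec = mixed_spec(n_images=1, cells_range=(25, 25))
        img, anns = synthgen.generate_smear(spec, "HELD-OUT", 77)
        regions = detect_cells(trained_detector, img)
        assert 20 <= len(regions) <= 30      # within +/-20% of 25

    def test_regions_sorted_clipped_and_confident(self, tiny_dataset,
                                                  trained_detector):
        iid = tiny_dataset.image_ids()[7]
        img = tiny_dataset.images[iid]
        regions = detect_cells(trained_detector, img)
        h, w = img.shape[:2]
        confs = [r.confidence for r in regions]
        assert confs == sorted(confs, reverse=True)
        for r in regions:
            x0, y0, x1, y1 = r.bbox
            assert 0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h
            assert 0.0 <= r.confidence <= 1.0


class TestNms:
    def test_duplicate_proposals_keep_highest_confidence(self):
        a = DetectedRegion((0, 0, 10, 10), (5, 5, 5, 5, 0), 0.9, region_id=0)
        b = DetectedRegion((0, 0, 10, 10), (5, 5, 5, 5, 0), 0.8, region_id=1)
        kept = nms([a, b], 0.5)
        assert kept == [a]

    def test_idempotence(self, tiny_dataset, trained_detector):
        iid = tiny_dataset.image_ids()[6]
        regions = detect_cells(trained_detector, tiny_dataset.images[iid])
        once = nms(regions, 0.5)
        assert nms(once, 0.5) == once


class TestRefineEllipse:
    def test_recovers_ground_truth_ellipse(self, tiny_dataset,
                                           trained_detector):
        iid = tiny_dataset.image_ids()[6]
        img = tiny_dataset.images[iid]
        gt = tiny_dataset.annotations[iid][0]
        seed_region = DetectedRegion(gt.bbox, (*gt.center, *gt.semi_axes,
                                               gt.rotation), 1.0)
        refined = refine_ellipse(img, seed_region)
        assert refined.source == "refined"

        def mask_of(ell):
            m = np.zeros(img.shape[:2], bool)
            ys, xs, mm = ellipse_mask_window(img.shape, *ell)
            m[ys, xs] = mm
            return m

        mg = mask_of((*gt.center, *gt.semi_axes, gt.rotation))
        mr = mask_of(refined.ellipse)
        assert (mg & mr).sum() / (mg | mr).sum() >= 0.9

    def test_uniform_background_returns_input_unchanged(self):
        img = np.full((80, 80, 3), 230, dtype=np.uint8)
        region = DetectedRegion((10, 10, 40, 40), (25, 25, 15, 15, 0), 0.7)
        out = refine_ellipse(img, region)
        assert out.source == "proposed"
        assert out.bbox == region.bbox

    def test_refined_box_stays_inside_expanded_box(self, tiny_dataset):
        iid = tiny_dataset.image_ids()[5]
        img = tiny_dataset.images[iid]
        for gt in tiny_dataset.annotations[iid][:5]:
            x0, y0, x1, y1 = gt.bbox
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            hw, hh = (x1 - x0) / 2 * 1.25, (y1 - y0) / 2 * 1.25
            region = DetectedRegion(gt.bbox, (*gt.center, *gt.semi_axes,
                                              gt.rotation), 1.0)
            r = refine_ellipse(img, region)
            rx0, ry0, rx1, ry1 = r.bbox
            assert rx0 >= cx - hw - 1e-6 and ry0 >= cy - hh - 1e-6
            assert rx1 <= cx + hw + 1e-6 and ry1 <= cy + hh + 1e-6


class TestHitl:
    def test_round_zero_reproduces_ground_truth(self, tiny_dataset):
        ids = tiny_dataset.image_ids()[:3]
        imgs, anns = subset(tiny_dataset, ids)
        untrained = train_detector(imgs, anns, DetectorConfig(epochs=0))
        corrected, model = hitl_round(untrained, imgs, anns, iou_accept=0.5,
                                      config=DetectorConfig(epochs=2, seed=1))
        assert model.is_trained
        for got, want in zip(corrected, anns):
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g.center == pytest.approx(w.center)
                assert g.extra.get("source") == "corrected"

    def test_map_non_decreasing_over_rounds(self, tiny_dataset):
        ids = tiny_dataset.image_ids()
        imgs, anns = subset(tiny_dataset, ids[:4])
        val_imgs, val_anns = subset(tiny_dataset, ids[4:6])
        cfg = DetectorConfig(epochs=3, seed=2)
        model = train_detector(imgs, anns, DetectorConfig(epochs=0))
        maps = []
        for _ in range(3):
            _, model = hitl_round(model, imgs, anns, iou_accept=0.5, config=cfg)
            dets = [detect_cells(model, v) for v in val_imgs]
            m_ap, _ = mean_ap_ar(dets, val_anns, (0.5,))
            maps.append(m_ap)
        for prev, cur in zip(maps, maps[1:]):
            assert cur >= prev - 0.02

    def test_zero_iou_accept_keeps_all_proposals(self, tiny_dataset,
                                                 trained_detector):
        ids = tiny_dataset.image_ids()[6:7]
        imgs, anns = subset(tiny_dataset, ids)
        proposals = detect_cells(trained_detector, imgs[0])
        corrected, _ = hitl_round(trained_detector, imgs, anns, iou_accept=0.0,
                                  config=DetectorConfig(epochs=1, seed=3))
        kept = [c for c in corrected[0] if c.extra.get("source") != "corrected"]
        assert len(kept) == len(proposals)

    def test_empty_image_set_rejected(self, trained_detector):
        with pytest.raises(DataError):
            hitl_round(trained_detector, [], [], 0.5)


class TestCropCells:
    def test_default_crop_contract_is_299(self, tiny_dataset):
        iid = tiny_dataset.image_ids()[0]
        anns = tiny_dataset.annotations[iid][:3]
        crops = crop_cells(tiny_dataset.images[iid], anns)
        assert all(c.shape == (299, 299, 3) for c in crops)

    def test_corner_region_fully_padded(self, tiny_dataset):
        iid = tiny_dataset.image_ids()[0]
        region = DetectedRegion((-20, -20, 30, 30), (5, 5, 25, 25, 0), 1.0)
        crops = crop_cells(tiny_dataset.images[iid], [region], crop_size=64)
        assert crops[0].shape == (64, 64, 3)

    def test_empty_region_list(self, tiny_dataset):
        iid = tiny_dataset.image_ids()[0]
        assert crop_cells(tiny_dataset.images[iid], []) == []

    def test_output_count_always_matches_input(self, tiny_dataset,
                                               trained_detector):
        iid = tiny_dataset.image_ids()[6]
        regions = detect_cells(trained_detector, tiny_dataset.images[iid])
        crops = crop_cells(tiny_dataset.images[iid], regions, crop_size=32)
        assert len(crops) == len(regions)


def test_checkpoint_round_trip(tmp_path, trained_detector, tiny_dataset):
    path = tmp_path / "detector.pkl"
    save_model(trained_detector, path)
    loaded = load_model(path)
    iid = tiny_dataset.image_ids()[7]
    img = tiny_dataset.images[iid]
    a = detect_cells(trained_detector, img)
    b = detect_cells(loaded, img)
    assert [r.bbox for r in a] == [r.bbox for r in b]


def test_detections_exportable_to_annotation_dialect(tmp_path, tiny_dataset,
                                                     trained_detector):
    from aplvision import annotio
    iid = tiny_dataset.image_ids()[6]
    regions = detect_cells(trained_detector, tiny_dataset.images[iid])
    anns = detections_to_annotations(regions, image_id=iid)
    path = tmp_path / "dets.json"
    annotio.write_annotations(anns, path)
    back = annotio.read_annotations(path)
    assert len(back) == len(regions)
    assert all("confidence" in a.extra for a in back)
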