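"""Metric implementations against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aplvision import evaluation
from aplvision.errors import DataError, UndefinedMetricError
from aplvision.segmentation import DetectedRegion


def region(box, conf, rid=0):
    return DetectedRegion(bbox=box, ellipse=(0, 0, 1, 1, 0), confidence=conf,
                          region_id=rid)


# ------------------------------------------------------------------ oracles

def roc_auc_pairwise(scores, labels):
    """Probability a random positive outscores a random negative (ties 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def pr_auc_threshold_sweep(scores, labels):
    """Area under the PR step curve: sum over descending-threshold steps."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    n_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    scores_sorted = np.asarray(scores)[order]
    i = 0
    tp = fp = 0
    while i < len(y):
        j = i
        while j < len(y) and scores_sorted[j] == scores_sorted[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def ap_threshold_sweep(confidences, tp_flags, n_gt):
    """AP from explicit PR points over all confidence thresholds, using the
    interpolated (running-max from the right) precision envelope."""
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    points = []
    for k in range(1, len(tp) + 1):
        points.append((tp[:k].sum() / n_gt, tp[:k].sum() / k))
    area = 0.0
    prev_r = 0.0
    for idx, (r, _) in enumerate(points):
        env = max(p for rr, p in points if rr >= r)
        area += (r - prev_r) * env
        prev_r = r
    return area


# --------------------------------------------------------------------- IoU

class TestIoU:
    @pytest.mark.parametrize("a, b, expected", [
        ((0, 0, 10, 10), (0, 0, 10, 10), 1.0),
        ((0, 0, 10, 10), (20, 20, 30, 30), 0.0),
        ((0, 0, 10, 10), (5, 0, 15, 10), 50.0 / 150.0),
        ((0, 0, 10, 10), (5, 5, 5, 10), 0.0),       # degenerate box
    ])
    def test_closed_form_cases(self, a, b, expected):
        assert evaluation.iou(a, b) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 50), min_size=8, max_size=8))
    def test_symmetry_and_bounds(self, vals):
        a = (min(vals[0], vals[1]), min(vals[2], vals[3]),
             max(vals[0], vals[1]) + 1, max(vals[2], vals[3]) + 1)
        b = (min(vals[4], vals[5]), min(vals[6], vals[7]),
             max(vals[4], vals[5]) + 1, max(vals[6], vals[7]) + 1)
        v = evaluation.iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(evaluation.iou(b, a))
        assert evaluation.iou(a, a) == pytest.approx(1.0)


# ----------------------------------------------------------------- matching

class TestMatchDetections:
    def test_perfect_predictions_all_tp(self):
        gt = [(0, 0, 10, 10), (20, 20, 30, 30), (40, 0, 50, 10)]
        preds = [region(b, 1.0, i) for i, b in enumerate(gt)]
        tp, matched = evaluation.match_detections(preds, gt, 0.5)
        assert all(tp) and all(matched)

    def test_higher_confidence_claims_the_gt(self):
        gt = [(0, 0, 10, 10)]
        # IoU 0.9 at conf 0.7, IoU 0.8 at conf 0.9 -> conf 0.9 wins
        p_low = region((0, 0, 10, 9), 0.7, rid=0)       # IoU 0.9
        p_high = region((0, 2, 10, 10), 0.9, rid=1)     # IoU 0.8
        tp, matched = evaluation.match_detections([p_low, p_high], gt, 0.5)
        assert tp == [False, True]
        assert matched == [True]

    def test_no_predictions(self):
        tp, matched = evaluation.match_detections(
            [], [(0, 0, 5, 5)] * 3, 0.5)
        assert tp == [] and matched == [False, False, False]


# -------------------------------------------------------------------- AP/AR

class TestMeanApAr:
    def test_perfect_detector_hits_one(self):
        gt = [(0, 0, 10, 10), (20, 20, 30, 30)]
        preds = [region(b, 1.0, i) for i, b in enumerate(gt)]
        m_ap, m_ar = evaluation.mean_ap_ar([preds], [gt])
        assert m_ap == pytest.approx(1.0)
        assert m_ar == pytest.approx(1.0)

    def test_no_detections_gives_zero(self):
        m_ap, m_ar = evaluation.mean_ap_ar([[]], [[(0, 0, 10, 10)]], (0.5,))
        assert m_ap == 0.0 and m_ar == 0.0

    def test_tp_fp_tp_ranking_matches_interpolated_value(self):
        gt = [(0, 0, 10, 10), (20, 0, 30, 10), (40, 0, 50, 10)]
        preds = [region((0, 0, 10, 10), 0.9, 0),      # TP
                 region((60, 60, 70, 70), 0.8, 1),    # FP
                 region((20, 0, 30, 10), 0.7, 2)]     # TP
        m_ap, _ = evaluation.mean_ap_ar([preds], [gt], (0.5,))
        assert m_ap == pytest.approx((1 / 3) * 1.0 + (1 / 3) * (2 / 3))

    @pytest.mark.parametrize("flags", list(itertools.product([0, 1], repeat=4)))
    def test_ap_equals_rank_enumeration_oracle(self, flags):
        """Every TP/FP ranking of 4 detections vs the threshold-sweep oracle."""
        n_gt = max(sum(flags), 2)
        confs = [0.9, 0.7, 0.5, 0.3]
        ap = evaluation._average_precision(confs, list(flags), n_gt)
        assert ap == pytest.approx(ap_threshold_sweep(confs, flags, n_gt))

    def test_single_threshold_call_reproduces_map50(self, tiny_dataset,
                                                    trained_detector):
        from aplvision.segmentation import detect_cells
        ids = tiny_dataset.image_ids()[6:]
        dets = [detect_cells(trained_detector, tiny_dataset.images[i])
                for i in ids]
        gts = [tiny_dataset.annotations[i] for i in ids]
        a, b = evaluation.mean_ap_ar(dets, gts, (0.5,))
        sweep_a, _ = evaluation.mean_ap_ar(dets, gts, (0.5, 0.5))
        assert a == pytest.approx(sweep_a)

    def test_zero_ground_truth_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            evaluation.mean_ap_ar([[]], [[]])


# -------------------------------------------------------------------- AUCs

class TestRocAuc:
    def test_perfect_and_inverted(self):
        assert evaluation.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert evaluation.roc_auc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0]) == 0.0

    def test_worked_pairwise_example(self):
        # positives {0.9, 0.4}, negatives {0.6, 0.1}: 3 of 4 pairs concordant
        assert evaluation.roc_auc([0.9, 0.4, 0.6, 0.1],
                                  [1, 1, 0, 0]) == pytest.approx(0.75)

    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 1)),
                    min_size=2, max_size=12))
    def test_matches_exhaustive_pairwise_oracle(self, pairs):
        scores = [s / 4 for s, _ in pairs]
        labels = [l for _, l in pairs]
        if len(set(labels)) < 2:
            with pytest.raises(UndefinedMetricError):
                evaluation.roc_auc(scores, labels)
            return
        assert evaluation.roc_auc(scores, labels) == pytest.approx(
            roc_auc_pairwise(scores, labels))


class TestPrAuc:
    def test_perfect_separation(self):
        assert evaluation.pr_auc([0.9, 0.8, 0.1], [1, 1, 0]) == pytest.approx(1.0)

    def test_single_positive_ranked_last(self):
        scores = list(np.linspace(1.0, 0.1, 10))
        labels = [0] * 9 + [1]
        assert evaluation.pr_auc(scores, labels) == pytest.approx(
            pr_auc_threshold_sweep(scores, labels))

    def test_total_ties_give_prevalence(self):
        labels = [1, 0, 0, 0, 1]
        assert evaluation.pr_auc([0.5] * 5, labels) == pytest.approx(2 / 5)

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 1)),
                    min_size=2, max_size=10))
    def test_matches_threshold_sweep_oracle(self, pairs):
        scores = [s / 3 for s, _ in pairs]
        labels = [l for _, l in pairs]
        if sum(labels) == 0:
            with pytest.raises(UndefinedMetricError):
                evaluation.pr_auc(scores, labels)
            return
        assert evaluation.pr_auc(scores, labels) == pytest.approx(
            pr_auc_threshold_sweep(scores, labels))


# ---------------------------------------------------------------------- CV

def manifest_for(n_per_class, images_per_patient=2, classes=("APL", "HEALTHY")):
    rows = []
    for dx in classes:
        for p in range(n_per_class):
            pid = f"{dx}-{p}"
            for i in range(images_per_patient):
                rows.append({"image_path": f"{pid}_{i}.png",
                             "annotation_path": f"{pid}_{i}.json",
                             "patient_id": pid, "diagnosis": dx})
    return pd.DataFrame(rows)


class TestPatientFolds:
    def test_two_to_one_split_geometry(self):
        m = manifest_for(9)
        folds = evaluation.patient_folds(m, k=3, seed=1)
        for f in range(3):
            test_p = folds[folds == f].index
            train_p = folds[folds != f].index
            per_class_test = m[m.patient_id.isin(test_p)] \
                .drop_duplicates("patient_id").groupby("diagnosis").size()
            assert (per_class_test == 3).all()
            assert len(train_p) == 2 * len(test_p)

    def test_every_patient_in_exactly_one_fold(self):
        m = manifest_for(5)
        folds = evaluation.patient_folds(m, k=3, seed=2)
        assert set(folds.index) == set(m.patient_id)
        assert folds.isin([0, 1, 2]).all()

    def test_no_leakage_even_with_augmented_records(self):
        m = manifest_for(4)
        augmented = m.sample(6, random_state=0).copy()
        augmented["image_path"] = augmented["image_path"] + ".aug0.png"
        m_full = pd.concat([m, augmented], ignore_index=True)
        folds = evaluation.patient_folds(m_full, k=3, seed=3)
        with_fold = m_full.assign(fold=[folds[p] for p in m_full.patient_id])
        # an augmented record's fold equals its parent's fold by construction
        for f in range(3):
            test_patients = set(with_fold[with_fold.fold == f].patient_id)
            train_patients = set(with_fold[with_fold.fold != f].patient_id)
            assert not (test_patients & train_patients)

    def test_too_few_patients_raises(self):
        with pytest.raises(DataError):
            evaluation.patient_folds(manifest_for(2), k=3, seed=0)


class TestMacroAverage:
    @pytest.mark.parametrize("vals, mean, sd", [
        ((0.9, 0.9, 0.9), 0.9, 0.0),
        ((0.8, 1.0), 0.9, 0.1),
        ((0.7,), 0.7, 0.0),
    ])
    def test_mean_and_dispersion(self, vals, mean, sd):
        m, s = evaluation.macro_average(vals)
        assert m == pytest.approx(mean)
        assert s == pytest.approx(sd)
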