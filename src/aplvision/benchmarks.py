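"""Seeded synthetic benchmark protocols for the pipeline's headline metrics.

Each protocol regenerates its data from a seed, runs the relevant stages
and measures the metric from scratch, so the numbers are reproducible
end-to-end: detection mAP/mAR on a held-out synthetic split, per-cell
classifier AUROCs on balanced ground-truth crops, and cross-validated
smear-level AUCs via :func:`aplvision.orchestration.run_pipeline`.
"""

from __future__ import annotations

import numpy as np

from . import synthgen
from .cellnet import train_cell_cnn
from .errors import DataError
from .evaluation import IOU_SWEEP, mean_ap_ar, roc_auc
from .orchestration import PipelineConfig, run_pipeline
from .segmentation import DetectorConfig, crop_cells, detect_cells, refine_ellipse, train_detector

__all__ = ["detection_benchmark", "cell_classifier_benchmark",
           "diagnosis_benchmark", "mixed_composition"]

#: balanced mixture used when harvesting cells of every type
mixed_composition = {"myeloblast": 0.30, "promyelocyte": 0.25,
                     "auer_promyelocyte": 0.20, "other": 0.25}


def _mixed_spec(n_images, cells_range=(18, 32), smudge_rate=1.5):
    return synthgen.CohortSpec(
        diagnosis="MIX", n_patients=n_images, images_per_patient=1,
        cells_per_image_range=cells_range, composition=mixed_composition,
        concentration=1e9, overlap_prob=0.0, smudge_rate=smudge_rate)


def detection_benchmark(seed: int = 42, n_images: int = 60, n_train: int = 40,
                        config: DetectorConfig | None = None) -> dict:
    """Detector metrics on a held-out synthetic split.

    Generates ``n_images`` non-overlapping smears, trains on the first
    ``n_train`` and evaluates the rest: mAP/mAR at IoU 0.5 on the raw
    detections, and mAP/mAR over the 0.50–0.95 sweep with ellipse
    refinement applied.
    """
    ds = synthgen.generate_cohort([_mixed_spec(n_images)], seed)
    ids = ds.image_ids()
    cfg = config or DetectorConfig(seed=seed & 0x7FFFFFFF)
    model = train_detector([ds.images[i] for i in ids[:n_train]],
                           [ds.annotations[i] for i in ids[:n_train]], cfg)
    test_ids = ids[n_train:]
    detections = [detect_cells(model, ds.images[i]) for i in test_ids]
    refined = [[refine_ellipse(ds.images[i], r) for r in dets]
               for i, dets in zip(test_ids, detections)]
    gts = [ds.annotations[i] for i in test_ids]
    map50, mar50 = mean_ap_ar(detections, gts, (0.5,))
    map_sweep, mar_sweep = mean_ap_ar(refined, gts, IOU_SWEEP)
    return {"map_at_50": map50, "mar_at_50": mar50,
            "map_50_95": map_sweep, "mar_50_95": mar_sweep,
            "n_test_images": len(test_ids),
            "n_test_cells": sum(len(g) for g in gts)}


def harvest_crops(seed: int, n_per_class: int, positive, pool=None,
                  crop_size: int = 64, max_images: int = 120):
    """Collect balanced ground-truth crops from generated smears.

    ``positive`` maps an annotation to its binary label; ``pool``
    optionally restricts which cells enter the sample at all (e.g. only
    promyelocyte-family cells for the Auer-rod task).
    """
    spec = _mixed_spec(max_images, smudge_rate=1.0)
    pos, neg = [], []
    for i in range(max_images):
        if len(pos) >= n_per_class and len(neg) >= n_per_class:
            break
        img, anns = synthgen.generate_smear(spec, f"HARVEST-{i:03d}",
                                            (seed + i) & 0x7FFFFFFF)
        crops = crop_cells(img, anns, crop_size=crop_size)
        for crop, ann in zip(crops, anns):
            if pool is not None and not pool(ann):
                continue
            (pos if positive(ann) else neg).append(crop)
    if len(pos) < n_per_class or len(neg) < n_per_class:
        raise DataError("could not harvest enough crops of each class")
    return pos[:n_per_class], neg[:n_per_class]


def cell_classifier_benchmark(task: str, seed: int, n_train: int = 400,
                              n_test: int = 200) -> float:
    """Held-out AUROC of one per-cell classifier on balanced crops."""
    if task == "myeloblast":
        positive, pool = (lambda a: a.is_myeloblast), None
    elif task == "promyelocyte":
        positive, pool = (lambda a: a.is_promyelocyte), None
    elif task == "auer_rod":
        positive = lambda a: a.has_auer_rod
        pool = lambda a: a.is_promyelocyte      # rod-bearing vs rod-free family
    else:
        raise DataError(f"unknown cell task {task!r}")
    half = (n_train + n_test) // 2
    pos, neg = harvest_crops(seed, half, positive, pool)
    crops = pos + neg
    labels = np.array([1] * half + [0] * half)
    order = np.random.default_rng(seed).permutation(len(crops))
    tr, te = order[:n_train], order[n_train:n_train + n_test]
    model = train_cell_cnn([crops[i] for i in tr], labels[tr],
                           seed=seed & 0x7FFFFFFF, task=task)
    return roc_auc(model.predict_proba([crops[i] for i in te]), labels[te])


def diagnosis_benchmark(task: str, seed: int = 7, **config_overrides):
    """Cross-validated smear-level metrics for one binary diagnosis task."""
    config = PipelineConfig(task=task, seed=seed & 0x7FFFFFFF,
                            **config_overrides)
    return run_pipeline(config)
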