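"""Pipeline orchestration: configuration, seeding, HPO and the full workflow.

``run_pipeline`` wires the stages end to end: synthesize (or load) a
cohort, train the cell detector on a dedicated annotated set, detect and
crop cells on every smear, train the three per-cell classifiers and the
smear-level ENN per cross-validation fold on training-fold patients only,
and evaluate with patient-grouped threefold CV.  Hyperparameter
optimization is a seeded random search over a declared space, with an
exhaustive mode for finite grids.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import os
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict

import numpy as np

from . import synthgen
from .cellnet import (CELL_TASKS, HeadConfig, TUNED_POOLING_DROPOUT,
                      encode_label, predict_cells, train_cell_cnn)
from .ensemble import smear_features, train_enn
from .errors import DataError, InvalidParameterError
from .evaluation import (EvalReport, IOU_SWEEP, iou, macro_average, mean_ap_ar,
                         patient_folds, pr_auc, precision_recall_f1, roc_auc)
from .segmentation import (DetectorConfig, crop_cells, detect_cells,
                           refine_ellipse, train_detector)

__all__ = ["PipelineConfig", "PipelineResult", "hpo", "run_pipeline",
           "setup_logging"]

logger = logging.getLogger("aplvision")


def setup_logging(path=None, level=logging.INFO):
    """Line-oriented run log with ISO timestamps."""
    handler = logging.FileHandler(path) if path else logging.StreamHandler()
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S"))
    root = logging.getLogger("aplvision")
    root.addHandler(handler)
    root.setLevel(level)
    return root


@dataclass
class PipelineConfig:
    """Desk-scale defaults for the full workflow."""
    task: str = "APL_vs_HEALTHY"
    seed: int = 7
    out_dir: str | None = None
    desk_scale: bool = True
    n_patients: int = 17
    images_per_patient: int = 3
    k_folds: int = 3
    n_detector_patients: int = 10        # dedicated annotated smears (1 image each)
    cell_crop_size: int = 64
    call_threshold: float = 0.5
    refine: bool = False
    use_morphometrics: bool = False
    use_n_cells: bool = False
    hitl_rounds: int = 0
    enn_lr: float = 0.05
    enn_epochs: int = 400
    hpo_trials: int = 0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    head: HeadConfig | None = None

    def resolved_head(self) -> HeadConfig:
        if self.head is not None:
            return self.head
        dropout = TUNED_POOLING_DROPOUT.get(self.task, 0.2)
        return HeadConfig(n_fc_layers=2, fc_widths=(32, 16, 8), dropout=dropout)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    report: EvalReport
    detector: object
    fold_models: dict                     # fold -> {"cells": {...}, "enn": ENNModel}
    final_cell_models: dict
    final_enn: ENNModel
    features: list                        # per-image dicts (fold, label, features)
    config: PipelineConfig


# ------------------------------------------------------------------- HPO

def hpo(objective, space: dict, n_trials: int = 10, seed: int = 0,
        exhaustive: bool = False):
    """Seeded random search (or exhaustive grid) over a parameter space.

    ``space`` maps parameter names to a list of choices or a ``(lo, hi)``
    tuple for a continuous uniform range.  Returns ``(best_config,
    trials)`` where ``trials`` is the full log of ``(config, score)``
    pairs; the best config is the argmax over evaluated configs.
    """
    if not space:
        raise InvalidParameterError("empty hyperparameter space")
    if not exhaustive and n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(space)
    configs = []
    if exhaustive:
        pools = []
        for name in names:
            spec = space[name]
            if isinstance(spec, tuple) and len(spec) == 2 \
                    and all(isinstance(v, (int, float)) for v in spec):
                raise InvalidParameterError(
                    f"{name}: continuous range not allowed in exhaustive mode")
            pools.append(list(spec))
        for combo in itertools.product(*pools):
            configs.append(dict(zip(names, combo)))
    else:
        for _ in range(n_trials):
            cfg = {}
            for name in names:
                spec = space[name]
                if isinstance(spec, tuple) and len(spec) == 2 \
                        and all(isinstance(v, (int, float)) for v in spec):
                    cfg[name] = float(rng.uniform(spec[0], spec[1]))
                else:
                    pool = list(spec)
                    cfg[name] = pool[int(rng.integers(len(pool)))]
            configs.append(cfg)
    trials = [(cfg, float(objective(cfg))) for cfg in configs]
    best = max(trials, key=lambda t: t[1])[0]
    return best, trials


# -------------------------------------------------------------- pipeline

@contextmanager
def _stage(name):
    logger.info("stage: %s", name)
    try:
        yield
    except Exception as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


def _task_classes(task):
    if task == "APL_vs_HEALTHY":
        return ("APL", "HEALTHY")
    if task == "APL_vs_AML":
        return ("APL", "AML")
    raise InvalidParameterError(f"unknown task {task!r}")


def _subseed(seed, *tokens):
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, *tokens])
               .generate_state(1)[0] & 0x7FFFFFFF)


def _mixed_detector_spec(base_spec, n_images):
    return synthgen.CohortSpec(
        diagnosis="MIX", n_patients=n_images, images_per_patient=1,
        cells_per_image_range=base_spec.cells_per_image_range,
        composition={"myeloblast": 0.3, "promyelocyte": 0.25,
                     "auer_promyelocyte": 0.15, "other": 0.3},
        concentration=1e9, overlap_prob=0.0,
        smudge_rate=base_spec.smudge_rate, image_size=base_spec.image_size)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow for one binary task; returns the report."""
    classes = _task_classes(config.task)
    seed = int(config.seed)
    report = EvalReport(task=config.task)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        setup_logging(os.path.join(config.out_dir, "run.log"))
    logger.info("run_pipeline task=%s seed=%d config=%s",
                config.task, seed, config.config_hash())

    with _stage("synthesize cohort"):
        specs = synthgen.default_cohort_specs(
            n_patients=config.n_patients,
            images_per_patient=config.images_per_patient)
        cohort = synthgen.generate_cohort([specs[c] for c in classes],
                                          _subseed(seed, 1))

    with _stage("train detector"):
        det_spec = _mixed_detector_spec(specs["APL"], config.n_detector_patients)
        det_ds = synthgen.generate_cohort([det_spec], _subseed(seed, 2))
        det_ids = det_ds.image_ids()
        n_tr = max(1, (2 * len(det_ids)) // 3)
        det_cfg = DetectorConfig(**{**config.detector.__dict__,
                                    "seed": _subseed(seed, 3)})
        detector = train_detector([det_ds.images[i] for i in det_ids[:n_tr]],
                                  [det_ds.annotations[i] for i in det_ids[:n_tr]],
                                  det_cfg)
        if config.hitl_rounds:
            for _ in range(config.hitl_rounds):
                from .segmentation import hitl_round
                _, detector = hitl_round(
                    detector, [det_ds.images[i] for i in det_ids[:n_tr]],
                    [det_ds.annotations[i] for i in det_ids[:n_tr]], 0.5)
        det_eval = [(detect_cells(detector, det_ds.images[i]),
                     det_ds.annotations[i]) for i in det_ids[n_tr:]]
        if det_eval and sum(len(g) for _, g in det_eval):
            report.map_at_50, report.mar_at_50 = mean_ap_ar(
                [d for d, _ in det_eval], [g for _, g in det_eval], (0.5,))
            report.map_50_95, report.mar_50_95 = mean_ap_ar(
                [d for d, _ in det_eval], [g for _, g in det_eval], IOU_SWEEP)

    with _stage("detect and crop cohort"):
        crops_by_image, labels_by_image = {}, {}
        for image_id in cohort.image_ids():
            image = cohort.images[image_id]
            regions = detect_cells(detector, image)
            if config.refine:
                regions = [refine_ellipse(image, r) for r in regions]
            gts = cohort.annotations[image_id]
            labels = []
            for r in regions:
                best, best_g = 0.0, None
                for g in gts:
                    v = iou(r.bbox, g.bbox)
                    if v > best:
                        best, best_g = v, g
                if best_g is not None and best >= 0.5:
                    labels.append(encode_label(best_g).as_tuple())
                else:
                    labels.append((0, 0, 0))
            crops_by_image[image_id] = crop_cells(
                image, regions, crop_size=config.cell_crop_size)
            labels_by_image[image_id] = labels

    with _stage("cross-validation"):
        folds = patient_folds(cohort.manifest, k=config.k_folds,
                              seed=_subseed(seed, 4))
        manifest = cohort.manifest.assign(
            fold=[folds[p] for p in cohort.manifest["patient_id"]],
            label=(cohort.manifest["diagnosis"] == "APL").astype(int))
        report.fold_assignments = {p: int(f) for p, f in folds.items()}
        head_cfg = config.resolved_head()
        fold_models, rows = {}, []
        all_calls, all_labels = [], []
        for f in range(config.k_folds):
            train_ids = manifest.loc[manifest["fold"] != f, "image_path"]
            test_ids = manifest.loc[manifest["fold"] == f, "image_path"]
            cell_models = _train_cell_models(
                crops_by_image, labels_by_image, train_ids, head_cfg,
                _subseed(seed, 5, f))
            fv_by_image = {}
            for image_id in manifest["image_path"]:
                crops = crops_by_image[image_id]
                if not crops:
                    continue
                preds = predict_cells(cell_models, crops)
                fv_by_image[image_id] = smear_features(
                    preds, call_threshold=config.call_threshold)
            enn = _train_fold_enn(config, manifest, fv_by_image, train_ids, f)
            test_rows = manifest[manifest["fold"] == f]
            fvs = [fv_by_image[i] for i in test_rows["image_path"]
                   if i in fv_by_image]
            y = [int(l) for i, l in zip(test_rows["image_path"],
                                        test_rows["label"]) if i in fv_by_image]
            p = enn.predict_proba(fvs)
            report.fold_roc_auc.append(roc_auc(p, y))
            report.fold_pr_auc.append(pr_auc(p, y))
            all_calls.extend((p >= enn.decision_threshold).astype(int))
            all_labels.extend(y)
            fold_models[f] = {"cells": cell_models, "enn": enn}
            for image_id, lab in zip(test_rows["image_path"], y):
                rows.append({"image_id": image_id, "fold": f, "label": lab,
                             "features": fv_by_image.get(image_id)})
        report.macro_roc_auc, report.macro_roc_auc_sd = \
            macro_average(report.fold_roc_auc)
        report.macro_pr_auc, report.macro_pr_auc_sd = \
            macro_average(report.fold_pr_auc)
        report.precision, report.recall, report.f1 = \
            precision_recall_f1(all_calls, all_labels)

    with _stage("final models"):
        all_ids = manifest["image_path"]
        final_cells = _train_cell_models(crops_by_image, labels_by_image,
                                         all_ids, head_cfg, _subseed(seed, 6))
        fvs, y = [], []
        for image_id, lab in zip(manifest["image_path"], manifest["label"]):
            crops = crops_by_image[image_id]
            if not crops:
                continue
            fvs.append(smear_features(predict_cells(final_cells, crops),
                                      call_threshold=config.call_threshold))
            y.append(int(lab))
        final_enn = train_enn(fvs, y, task=config.task,
                              seed=_subseed(seed, 7), lr=config.enn_lr,
                              epochs=config.enn_epochs,
                              use_morphometrics=config.use_morphometrics,
                              use_n_cells=config.use_n_cells)

    if config.out_dir:
        report.to_json(os.path.join(config.out_dir, "eval_report.json"))
        with open(os.path.join(config.out_dir, "run.json"), "w") as fh:
            json.dump({"config": asdict(config), "seed": seed,
                       "config_hash": config.config_hash()}, fh,
                      indent=1, default=str)
    logger.info("macro ROC AUC %.4f, macro PR AUC %.4f",
                report.macro_roc_auc, report.macro_pr_auc)
    return PipelineResult(report=report, detector=detector,
                          fold_models=fold_models,
                          final_cell_models=final_cells, final_enn=final_enn,
                          features=rows, config=config)


def _train_cell_models(crops_by_image, labels_by_image, image_ids, head_cfg,
                       seed):
    crops, labels = [], []
    for image_id in image_ids:
        crops.extend(crops_by_image[image_id])
        labels.extend(labels_by_image[image_id])
    if not crops:
        raise DataError("no cells detected on any training image")
    labels = np.asarray(labels, dtype=int)
    models = {}
    for t_idx, task in enumerate(CELL_TASKS):
        targets = labels[:, t_idx]
        if np.unique(targets).size < 2:
            # degenerate training fold (e.g. no rod-bearing cells detected):
            # an untrained head scores at chance rather than failing the run
            from ._nnet import DenseNet
            from .cellnet import CellModel, N_CROP_FEATURES
            models[task] = CellModel(
                task=task, head=DenseNet(N_CROP_FEATURES, seed=seed),
                crop_size=crops[0].shape[0], config=head_cfg)
            continue
        models[task] = train_cell_cnn(
            crops, targets, head_config=head_cfg, seed=_subseed(seed, t_idx),
            task=task, balance=True)
    return models


def _train_fold_enn(config, manifest, fv_by_image, train_ids, fold):
    train_rows = manifest[manifest["image_path"].isin(train_ids)]
    fvs = [fv_by_image[i] for i in train_rows["image_path"] if i in fv_by_image]
    y = [int(l) for i, l in zip(train_rows["image_path"], train_rows["label"])
         if i in fv_by_image]
    seed = _subseed(config.seed, 8, fold)
    lr, epochs = config.enn_lr, config.enn_epochs
    if config.hpo_trials > 0:
        # inner split of the training images for hyperparameter selection
        n = len(fvs)
        cut = max(1, int(0.7 * n))
        def objective(params):
            m = train_enn(fvs[:cut], y[:cut], task=config.task, seed=seed,
                          lr=params["lr"], epochs=int(params["epochs"]),
                          use_morphometrics=config.use_morphometrics,
                          use_n_cells=config.use_n_cells)
            try:
                return roc_auc(m.predict_proba(fvs[cut:]), y[cut:])
            except Exception:
                return 0.0
        best, _ = hpo(objective, {"lr": [0.01, 0.05, 0.1],
                                  "epochs": [200, 400]},
                      n_trials=config.hpo_trials, seed=seed)
        lr, epochs = best["lr"], int(best["epochs"])
    return train_enn(fvs, y, task=config.task, seed=seed, lr=lr, epochs=epochs,
                     use_morphometrics=config.use_morphometrics,
                     use_n_cells=config.use_n_cells)
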