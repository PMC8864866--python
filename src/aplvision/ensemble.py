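"""Smear-level aggregation and the single-layer ensemble classifier (ENN).

Per-cell probabilities are converted to hard calls at a decision threshold
and aggregated into per-smear *ratios* — the fraction of detected cells
called myeloblast, promyelocyte, and Auer-rod-bearing.  A single fully
connected layer with a sigmoid output and no dropout (one weight per
feature plus a bias) maps the ratio vector to the probability that the
smear is APL, separately for the APL-vs-healthy and APL-vs-AML tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nnet import DenseNet
from .errors import DataError, NoCellsError

__all__ = ["TASKS", "SmearFeatureVector", "DiagnosisPrediction", "ENNModel",
           "smear_features", "features_as_array", "train_enn", "classify_smear",
           "predictions_to_csv"]

TASKS = ("APL_vs_HEALTHY", "APL_vs_AML")


@dataclass(frozen=True)
class SmearFeatureVector:
    """Per-smear ratio features (denominator = detected cell count)."""
    ratio_myeloblast: float
    ratio_promyelocyte: float
    ratio_auer_rod: float
    n_cells: int
    mean_size_px2: float = 0.0
    mean_volume_proxy: float = 0.0
    mean_contrast: float = 0.0


@dataclass(frozen=True)
class DiagnosisPrediction:
    task: str
    p_apl: float
    call: str                       # "APL" | "other" | "unanalyzable"
    n_cells: int = 0
    features: SmearFeatureVector | None = None


def smear_features(cell_predictions, call_threshold: float = 0.5
                   ) -> SmearFeatureVector:
    """Aggregate per-cell predictions into the smear ratio vector.

    ``ratio_X = count(p_X >= call_threshold) / n_cells``.  An empty
    prediction list raises :class:`NoCellsError` — the image is flagged
    unanalyzable rather than silently scored.
    """
    preds = list(cell_predictions)
    n = len(preds)
    if n == 0:
        raise NoCellsError("no cells detected; smear cannot be analyzed")
    thr = float(call_threshold)
    return SmearFeatureVector(
        ratio_myeloblast=sum(p.p_myeloblast >= thr for p in preds) / n,
        ratio_promyelocyte=sum(p.p_promyelocyte >= thr for p in preds) / n,
        ratio_auer_rod=sum(p.p_auer_rod >= thr for p in preds) / n,
        n_cells=n,
        mean_size_px2=float(np.mean([p.size_px2 for p in preds])),
        mean_volume_proxy=float(np.mean([p.volume_proxy for p in preds])),
        mean_contrast=float(np.mean([p.contrast for p in preds])),
    )


def features_as_array(fv: SmearFeatureVector, use_morphometrics: bool = False,
                      use_n_cells: bool = False) -> np.ndarray:
    """Feature vector fed to the ENN (the three ratios by default)."""
    feats = [fv.ratio_myeloblast, fv.ratio_promyelocyte, fv.ratio_auer_rod]
    if use_n_cells:
        feats.append(fv.n_cells / 100.0)
    if use_morphometrics:
        feats += [fv.mean_size_px2 / 1e3, fv.mean_volume_proxy / 1e5,
                  fv.mean_contrast]
    return np.asarray(feats, dtype=float)


@dataclass
class ENNModel:
    """Single affine layer + sigmoid over smear features, no dropout."""
    task: str
    net: DenseNet
    use_morphometrics: bool = False
    use_n_cells: bool = False
    decision_threshold: float = 0.5

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def predict_proba(self, feature_vectors) -> np.ndarray:
        X = np.stack([features_as_array(fv, self.use_morphometrics,
                                        self.use_n_cells)
                      for fv in feature_vectors])
        return self.net.predict_proba(X)


def train_enn(feature_vectors, labels, task: str, seed: int = 0,
              lr: float = 0.05, epochs: int = 400,
              use_morphometrics: bool = False, use_n_cells: bool = False
              ) -> ENNModel:
    """Train the single-layer smear classifier.

    ``labels`` are 1 for APL, 0 for the task's control class; both classes
    must be present.  The model is an affine map plus sigmoid — parameter
    count is exactly ``n_features + 1``.
    """
    fvs = list(feature_vectors)
    y = np.asarray(labels, dtype=int)
    if len(fvs) == 0 or np.unique(y).size < 2:
        raise DataError("ENN training needs both classes present")
    X = np.stack([features_as_array(fv, use_morphometrics, use_n_cells)
                  for fv in fvs])
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite smear features")
    net = DenseNet(X.shape[1], hidden=(), dropout=0.0, lr=lr, epochs=epochs,
                   batch_size=32, seed=seed)
    net.fit(X, y)
    return ENNModel(task=task, net=net, use_morphometrics=use_morphometrics,
                    use_n_cells=use_n_cells)


def classify_smear(enn: ENNModel, detector, cell_models, image,
                   call_threshold: float = 0.5, refine: bool = False
                   ) -> DiagnosisPrediction:
    """Run the full chain on one image: detect -> crop -> score -> ENN.

    Propagates :class:`NoCellsError` as an ``unanalyzable`` prediction with
    no probability rather than a spurious call.
    """
    import logging
    import time

    from .cellnet import predict_cells
    from .segmentation import crop_cells, detect_cells, refine_ellipse

    log = logging.getLogger(__name__)
    t0 = time.perf_counter()
    regions = detect_cells(detector, image)
    t1 = time.perf_counter()
    if refine:
        regions = [refine_ellipse(image, r) for r in regions]
    if not regions:
        return DiagnosisPrediction(task=enn.task, p_apl=float("nan"),
                                   call="unanalyzable", n_cells=0)
    crop_size = cell_models[next(iter(cell_models))].crop_size
    crops = crop_cells(image, regions, crop_size=crop_size)
    t2 = time.perf_counter()
    preds = predict_cells(cell_models, crops)
    fv = smear_features(preds, call_threshold=call_threshold)
    p = float(enn.predict_proba([fv])[0])
    t3 = time.perf_counter()
    log.debug("classify_smear timings: detect %.3fs crop %.3fs classify %.3fs",
              t1 - t0, t2 - t1, t3 - t2)
    call = "APL" if p >= enn.decision_threshold else "other"
    return DiagnosisPrediction(task=enn.task, p_apl=p, call=call,
                               n_cells=fv.n_cells, features=fv)


def predictions_to_csv(rows, path):
    """Export smear predictions as CSV.

    ``rows`` is an iterable of ``(image_path, patient_id, prediction)``
    triples; columns are image_path, patient_id, task, p_apl, call,
    n_cells and the three ratios (empty for unanalyzable images).
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "patient_id", "task", "p_apl", "call",
                         "n_cells", "ratio_myeloblast", "ratio_promyelocyte",
                         "ratio_auer_rod"])
        for image_path, patient_id, pred in rows:
            fv = pred.features
            writer.writerow([
                image_path, patient_id, pred.task, pred.p_apl, pred.call,
                pred.n_cells,
                fv.ratio_myeloblast if fv else "",
                fv.ratio_promyelocyte if fv else "",
                fv.ratio_auer_rod if fv else ""])
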