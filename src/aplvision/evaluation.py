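"""Detection and classification metrics plus the grouped CV protocol.

Detection quality follows the standard benchmark recipe: greedy
confidence-ordered matching of predictions to ground truth at an IoU
threshold, average precision as the area under the all-point-interpolated
precision/recall curve of the confidence-ranked detections, average recall
as the maximal recall attained, both averaged over an IoU sweep
(default 0.50:0.05:0.95).  Classifier quality uses ROC and
precision-recall AUCs.  Cross-validation is threefold at the *patient*
level with class stratification, giving each fold a 2:1 train:test patient
split; records derived from an augmented copy inherit their parent's
patient and therefore its fold, so no patient ever crosses the split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import DataError, UndefinedMetricError

__all__ = [
    "EvalReport", "iou", "match_detections", "mean_ap_ar",
    "roc_auc", "pr_auc", "patient_folds", "macro_average", "IOU_SWEEP",
    "curve_points_to_csv",
]

logger = logging.getLogger(__name__)

#: benchmark IoU sweep, 0.50 to 0.95 in steps of 0.05
IOU_SWEEP = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass
class EvalReport:
    """Aggregated metrics for one pipeline run / task."""
    task: str = ""
    map_at_50: float | None = None
    mar_at_50: float | None = None
    map_50_95: float | None = None
    mar_50_95: float | None = None
    fold_roc_auc: list = field(default_factory=list)
    fold_pr_auc: list = field(default_factory=list)
    macro_roc_auc: float | None = None
    macro_roc_auc_sd: float | None = None
    macro_pr_auc: float | None = None
    macro_pr_auc_sd: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    fold_assignments: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ------------------------------------------------------------------- IoU

def iou(box_a, box_b) -> float:
    """Intersection-over-union of two half-open boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    area_b = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if area_a == 0.0 or area_b == 0.0:
        logger.debug("degenerate zero-area box in IoU; returning 0")
        return 0.0
    ix = min(ax1, bx1) - max(ax0, bx0)
    iy = min(ay1, by1) - max(ay0, by0)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (area_a + area_b - inter)


# -------------------------------------------------------------- matching

def _pred_key(p, index):
    conf = getattr(p, "confidence", None)
    if conf is None:
        conf = p[1] if isinstance(p, tuple) else 1.0
    rid = getattr(p, "region_id", index)
    return (-float(conf), rid)


def _pred_box(p):
    box = getattr(p, "bbox", None)
    if box is None:
        box = p[0] if isinstance(p, tuple) else p
    return box


def match_detections(predictions, ground_truth, iou_threshold):
    """Greedy one-to-one matching of predictions to ground-truth regions.

    Predictions are visited in descending confidence (ties broken by
    ``region_id``); each claims the highest-IoU unmatched ground-truth
    region if that IoU reaches the threshold.  Returns ``(tp_flags,
    gt_matched)`` with ``tp_flags`` in prediction input order.
    """
    gt_boxes = [getattr(g, "bbox", g) for g in ground_truth]
    order = sorted(range(len(predictions)),
                   key=lambda i: _pred_key(predictions[i], i))
    tp = [False] * len(predictions)
    gt_matched = [False] * len(gt_boxes)
    for i in order:
        box = _pred_box(predictions[i])
        best_iou, best_j = 0.0, -1
        for j, gbox in enumerate(gt_boxes):
            if gt_matched[j]:
                continue
            v = iou(box, gbox)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[i] = True
            gt_matched[best_j] = True
    return tp, gt_matched


def _average_precision(confidences, tp_flags, n_gt) -> float:
    """AP = area under the all-point-interpolated PR curve."""
    if n_gt == 0:
        raise UndefinedMetricError("AP undefined with zero ground-truth objects")
    if not confidences:
        return 0.0
    order = np.lexsort((np.arange(len(confidences)), -np.asarray(confidences)))
    tp = np.asarray(tp_flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope (monotone non-increasing from the right)
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0] if len(precision) else 0.0],
                                precision])
    return float(np.sum(np.diff(recall) * precision[1:]))


def mean_ap_ar(detections_per_image, ground_truth_per_image,
               iou_thresholds=IOU_SWEEP):
    """Dataset-level (mAP, mAR) averaged over an IoU threshold sweep.

    ``detections_per_image`` / ``ground_truth_per_image`` are parallel
    lists; detections carry ``bbox`` and ``confidence``.  A single-element
    sweep ``{0.5}`` reproduces mAP@0.5.
    """
    n_gt = sum(len(g) for g in ground_truth_per_image)
    if n_gt == 0:
        raise UndefinedMetricError("no ground-truth objects in the evaluation set")
    aps, ars = [], []
    for thr in iou_thresholds:
        confs, tps, matched = [], [], 0
        for preds, gts in zip(detections_per_image, ground_truth_per_image):
            tp, gt_matched = match_detections(preds, gts, thr)
            confs.extend(float(getattr(p, "confidence", 1.0)) for p in preds)
            tps.extend(tp)
            matched += sum(gt_matched)
        aps.append(_average_precision(confs, tps, n_gt))
        ars.append(matched / n_gt)
    return float(np.mean(aps)), float(np.mean(ars))


# ---------------------------------------------------------------- AUCs

def _check_binary(labels):
    labels = np.asarray(labels)
    if labels.size == 0 or np.unique(labels).size < 2:
        raise UndefinedMetricError("metric undefined: need both classes present")
    return labels


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half.
    """
    labels = _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve over all thresholds."""
    labels = np.asarray(labels)
    if labels.size == 0 or not np.any(labels == 1):
        raise UndefinedMetricError("PR AUC undefined without positive labels")
    value = float(average_precision_score(labels, np.asarray(scores, dtype=float)))
    return min(max(value, 0.0), 1.0)


def precision_recall_f1(calls, labels):
    """Precision/recall/F1 of hard binary calls."""
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    tp = int(np.sum((calls == 1) & (labels == 1)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def curve_points_to_csv(scores, labels, path, kind="roc"):
    """Export ROC or precision-recall curve points as CSV for plotting.

    Columns are (fpr, tpr, threshold) for ``kind='roc'`` and
    (recall, precision, threshold) for ``kind='pr'``.
    """
    from sklearn.metrics import precision_recall_curve, roc_curve

    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if kind == "roc":
        x, y, thr = roc_curve(labels, scores)
        frame = pd.DataFrame({"fpr": x, "tpr": y, "threshold": thr})
    elif kind == "pr":
        precision, recall, thr = precision_recall_curve(labels, scores)
        frame = pd.DataFrame({"recall": recall, "precision": precision,
                              "threshold": np.append(thr, np.nan)})
    else:
        raise UndefinedMetricError(f"unknown curve kind {kind!r}")
    frame.to_csv(path, index=False)
    return frame


# ------------------------------------------------------------------- CV

def patient_folds(manifest: pd.DataFrame, k: int = 3, seed: int = 0) -> pd.Series:
    """Assign every patient to exactly one test fold, stratified by diagnosis.

    Patients are shuffled within each diagnosis and dealt round-robin into
    ``k`` folds, so with ``k=3`` each fold's train:test patient ratio is
    2:1 (exact when counts divide) and per-fold class proportions stay
    within one patient of the cohort's.  Returns a Series mapping
    ``patient_id -> fold``.  Because augmented records keep their parent's
    ``patient_id``, they automatically land in the parent's fold.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    groups = manifest.drop_duplicates("patient_id")[["patient_id", "diagnosis"]]
    rng = np.random.default_rng(seed)
    assignment = {}
    for diagnosis, sub in groups.groupby("diagnosis", sort=True):
        patients = sorted(sub["patient_id"])
        if len(patients) < k:
            raise DataError(
                f"class {diagnosis!r} has {len(patients)} patients; need >= {k}")
        rng.shuffle(patients)
        for i, pid in enumerate(patients):
            assignment[pid] = i % k
    return pd.Series(assignment, name="fold")


def macro_average(per_fold_values):
    """Arithmetic mean over folds and the standard deviation of fold values."""
    vals = np.asarray(list(per_fold_values), dtype=float)
    if vals.size == 0:
        raise DataError("need at least one fold value")
    return float(vals.mean()), float(vals.std(ddof=0))
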