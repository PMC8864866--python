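"""Two-stage cell detector, elliptical refinement and per-cell cropping.

Stage one is a per-pixel foreground classifier (color + local-texture
features through a small dense net) whose probability map is split into
cell candidates by a distance-transform watershed.  Stage two scores each
candidate region with a second small net trained to separate true cells
from background fragments and smudge artifacts; its probability is the
detection confidence.  Candidates are thresholded, non-maximum suppressed
on axis-aligned boxes and returned with a moments-fitted ellipse.  The
human-in-the-loop round mimics the annotation workflow in which model
proposals are accepted when they overlap a truth region well enough and
replaced by the corrected region otherwise, after which the detector is
retrained on the corrected set.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed
from skimage.transform import resize

from ._nnet import DenseNet
from .errors import DataError, InvalidConfigError, StateError
from .evaluation import iou
from .geometry import clip_box, ellipse_bbox, ellipse_mask_window
from .synthgen import CellAnnotation

__all__ = ["DetectorConfig", "DetectedRegion", "DetectorModel",
           "train_detector", "detect_cells", "refine_ellipse", "hitl_round",
           "crop_cells", "nms", "save_model", "load_model",
           "detections_to_annotations"]

_N_PIXEL_FEATURES = 5
_N_REGION_FEATURES = 10


@dataclass(frozen=True)
class DetectorConfig:
    """Detector hyperparameters (all exposed; desk-scale defaults)."""
    hidden_width: int = 8            # stage-1 backbone width (one hidden layer)
    anchor_scales: tuple = (10, 16, 24)   # typical cell radii the splitter expects
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    epochs: int = 5
    lr: float = 0.05
    seed: int = 0
    crop_size: int = 299
    min_area: int = 40               # discard fragments below this pixel area
    min_peak_distance: int = 9       # watershed marker separation

    def __post_init__(self):
        if not (0.0 <= self.score_threshold <= 1.0 and 0.0 <= self.nms_iou <= 1.0):
            raise InvalidConfigError("thresholds must lie in [0,1]")
        if self.crop_size <= 0:
            raise InvalidConfigError("crop_size must be > 0")
        if self.epochs < 0:
            raise InvalidConfigError("epochs must be >= 0")


@dataclass
class DetectedRegion:
    """One detector output region."""
    bbox: tuple
    ellipse: tuple                   # (cx, cy, rx, ry, theta)
    confidence: float
    source: str = "proposed"         # proposed | refined | corrected
    region_id: int = 0


# ------------------------------------------------------------- features

def _pixel_features(image: np.ndarray) -> np.ndarray:
    """(H*W, 5) per-pixel features: RGB, gray, local gray std."""
    img = image.astype(np.float64) / 255.0
    gray = img.mean(axis=2)
    mean = ndi.uniform_filter(gray, size=5)
    sq_mean = ndi.uniform_filter(gray * gray, size=5)
    local_std = np.sqrt(np.maximum(sq_mean - mean * mean, 0.0))
    feats = np.stack([img[..., 0], img[..., 1], img[..., 2], gray, local_std],
                     axis=-1)
    return feats.reshape(-1, _N_PIXEL_FEATURES)


def _region_features(image, box, mask_window):
    """Shape + appearance summary of a candidate region."""
    h, w = image.shape[:2]
    x0, y0, x1, y1 = clip_box(box, w, h)
    bw, bh = max(x1 - x0, 1.0), max(y1 - y0, 1.0)
    c0, r0 = int(x0), int(y0)
    c1, r1 = max(int(np.ceil(x1)), c0 + 1), max(int(np.ceil(y1)), r0 + 1)
    window = image[r0:r1, c0:c1].astype(np.float64) / 255.0
    if mask_window is None or mask_window.shape != window.shape[:2] \
            or not mask_window.any():
        mask_window = np.ones(window.shape[:2], dtype=bool)
        fill = 0.0
        area = 0.0
    else:
        area = float(mask_window.sum())
        fill = area / (bw * bh)
    pix = window[mask_window]
    gray = pix.mean(axis=1)
    return np.array([
        np.log1p(area), fill, bh / bw,
        pix[:, 0].mean(), pix[:, 1].mean(), pix[:, 2].mean(),
        gray.std(), gray.min() if gray.size else 0.0,
        bw / max(image.shape[1], 1), bh / max(image.shape[0], 1),
    ])


def _fit_ellipse_moments(rows, cols):
    """Moments-based ellipse fit of a pixel blob -> (cx, cy, rx, ry, theta).

    For a uniformly filled ellipse the covariance eigenvalues are r^2/4,
    so the semi-axes are recovered as twice the singular values.
    """
    cx, cy = cols.mean(), rows.mean()
    dx, dy = cols - cx, rows - cy
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)],
                    [np.mean(dx * dy), np.mean(dy * dy)]])
    vals, vecs = np.linalg.eigh(cov)          # ascending
    rx = 2.0 * np.sqrt(max(vals[1], 1e-6))
    ry = 2.0 * np.sqrt(max(vals[0], 1e-6))
    theta = float(np.arctan2(vecs[1, 1], vecs[0, 1]))
    if theta < 0:
        theta += np.pi
    return float(cx), float(cy), float(rx), float(ry), theta


# ---------------------------------------------------------------- model

class DetectorModel:
    """Trained two-stage detector (pixel classifier + region scorer)."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        self.pixel_clf: DenseNet | None = None
        self.region_clf: DenseNet | None = None
        self.is_trained = False
        self.loss_history: list[float] = []

    # stage 1 ------------------------------------------------------------
    def foreground_probability(self, image) -> np.ndarray:
        h, w = image.shape[:2]
        p = self.pixel_clf.predict_proba(_pixel_features(image))
        return p.reshape(h, w)

    def _candidates(self, image):
        """Watershed-split stage-1 candidates -> list of (box, ellipse, mask)."""
        cfg = self.config
        binary = self.foreground_probability(image) >= 0.5
        binary = ndi.binary_fill_holes(binary)
        distance = ndi.distance_transform_edt(binary)
        peaks = peak_local_max(distance, min_distance=cfg.min_peak_distance,
                               labels=binary, exclude_border=False)
        if len(peaks):
            markers = np.zeros(binary.shape, dtype=np.int32)
            for i, (r, c) in enumerate(peaks, start=1):
                markers[r, c] = i
            labels = watershed(-distance, markers, mask=binary)
        else:
            labels = cc_label(binary)
        out = []
        for prop in regionprops(labels):
            if prop.area < cfg.min_area:
                continue
            rows, cols = prop.coords[:, 0].astype(float), prop.coords[:, 1].astype(float)
            ellipse = _fit_ellipse_moments(rows, cols)
            box = ellipse_bbox(*ellipse)
            r0, c0, r1, c1 = prop.bbox
            mask = labels[r0:r1, c0:c1] == prop.label
            pix_box = (float(c0), float(r0), float(c1), float(r1))
            out.append((box, ellipse, pix_box, mask))
        return out


def train_detector(images, annotations_per_image, config: DetectorConfig
                   ) -> DetectorModel:
    """Train both detector stages on annotated smears.

    ``images`` and ``annotations_per_image`` are parallel lists.  With
    ``epochs=0`` the model is returned untrained (flagged via
    ``is_trained``).  Training is reproducible for a fixed config seed.
    """
    images = list(images)
    annotations_per_image = list(annotations_per_image)
    if not images:
        raise DataError("detector training needs at least one annotated image")
    model = DetectorModel(config)
    if config.epochs == 0:
        return model
    rng = np.random.default_rng(config.seed)

    # ---- stage 1: pixel foreground classifier
    feat_chunks, label_chunks = [], []
    for image, anns in zip(images, annotations_per_image):
        h, w = image.shape[:2]
        fg = np.zeros((h, w), dtype=bool)
        for a in anns:
            ys, xs, mask = ellipse_mask_window((h, w), *_ellipse_of(a))
            fg[ys, xs] |= mask
        feats = _pixel_features(image)
        flat_fg = fg.reshape(-1)
        for cls, idx_pool in ((1, np.flatnonzero(flat_fg)),
                              (0, np.flatnonzero(~flat_fg))):
            if idx_pool.size == 0:
                continue
            take = min(3000, idx_pool.size)
            idx = rng.choice(idx_pool, size=take, replace=False)
            feat_chunks.append(feats[idx])
            label_chunks.append(np.full(take, cls))
    X = np.concatenate(feat_chunks)
    y = np.concatenate(label_chunks)
    model.pixel_clf = DenseNet(
        _N_PIXEL_FEATURES, hidden=(config.hidden_width,), lr=config.lr,
        epochs=config.epochs, batch_size=512, seed=config.seed)
    model.pixel_clf.fit(X, y)
    model.loss_history = list(model.pixel_clf.loss_history)

    # ---- stage 2: region scorer on stage-1 candidates + background boxes
    rf, rl = [], []
    for image, anns in zip(images, annotations_per_image):
        h, w = image.shape[:2]
        gt_boxes = [a.bbox for a in anns]
        for box, _ellipse, pix_box, mask in model._candidates(image):
            best = max((iou(pix_box, g) for g in gt_boxes), default=0.0)
            rf.append(_region_features(image, pix_box, mask))
            rl.append(1 if best >= 0.5 else 0)
        for _ in range(8):      # random background boxes as hard negatives
            bw = rng.uniform(12, 40)
            bh = rng.uniform(12, 40)
            bx = rng.uniform(0, max(w - bw, 1))
            by = rng.uniform(0, max(h - bh, 1))
            box = (bx, by, bx + bw, by + bh)
            if max((iou(box, g) for g in gt_boxes), default=0.0) < 0.1:
                rf.append(_region_features(image, box, None))
                rl.append(0)
    rl = np.asarray(rl)
    model.region_clf = DenseNet(
        _N_REGION_FEATURES, hidden=(8,), lr=0.02,
        epochs=max(40, config.epochs * 8), batch_size=64, seed=config.seed + 1)
    if np.unique(rl).size < 2:      # degenerate toy set: fall back to prior
        model.region_clf.is_trained = False
    else:
        model.region_clf.fit(np.asarray(rf), rl)
    model.is_trained = True
    return model


def _ellipse_of(region):
    if isinstance(region, CellAnnotation):
        return (*region.center, *region.semi_axes, region.rotation)
    return region.ellipse


# ------------------------------------------------------------- inference

def nms(regions, iou_threshold):
    """Greedy confidence-ordered non-maximum suppression (ties by region_id).

    Idempotent: suppressing an already suppressed list changes nothing.
    """
    order = sorted(regions, key=lambda r: (-r.confidence, r.region_id))
    kept = []
    for cand in order:
        if all(iou(cand.bbox, k.bbox) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


def detect_cells(model: DetectorModel, image, score_threshold=None):
    """Detect cells on one image -> regions sorted by descending confidence."""
    if not model.is_trained:
        raise StateError("detector has not been trained")
    cfg = model.config
    thr = cfg.score_threshold if score_threshold is None else float(score_threshold)
    h, w = image.shape[:2]
    regions = []
    for rid, (box, ellipse, pix_box, mask) in enumerate(model._candidates(image)):
        if model.region_clf is not None and model.region_clf.is_trained:
            conf = float(model.region_clf.predict_proba(
                _region_features(image, pix_box, mask)[None, :])[0])
        else:
            conf = 0.5
        if conf < thr:
            continue
        regions.append(DetectedRegion(
            bbox=clip_box(box, w, h), ellipse=ellipse,
            confidence=conf, region_id=rid))
    regions = nms(regions, cfg.nms_iou)
    return sorted(regions, key=lambda r: (-r.confidence, r.region_id))


def refine_ellipse(image, region: DetectedRegion, background_color=None,
                   expand: float = 1.25) -> DetectedRegion:
    """Intensity-based ellipse refinement inside an expanded box.

    Foreground pixels (far from the background color) inside the
    ``expand``-scaled box are re-fitted with image moments.  If no
    foreground is found the input region is returned unchanged; otherwise
    the refined box is clipped to the expanded box, so it can never grow
    beyond it.
    """
    h, w = image.shape[:2]
    x0, y0, x1, y1 = region.bbox
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    hw, hh = (x1 - x0) / 2.0 * expand, (y1 - y0) / 2.0 * expand
    ex0, ey0, ex1, ey1 = clip_box((cx - hw, cy - hh, cx + hw, cy + hh), w, h)
    c0, r0 = int(ex0), int(ey0)
    c1, r1 = int(np.ceil(ex1)), int(np.ceil(ey1))
    if c1 <= c0 or r1 <= r0:
        return region
    window = image[r0:r1, c0:c1].astype(np.float64)
    if background_color is None:
        background_color = np.median(
            image.reshape(-1, image.shape[2])[::17], axis=0)
    dist = np.linalg.norm(window - np.asarray(background_color, float), axis=2)
    fg = dist > 25.0
    if not fg.any():
        return region
    labels = cc_label(fg)
    # keep the component nearest the region center
    best_lab, best_d = 0, np.inf
    for prop in regionprops(labels):
        d = np.hypot(prop.centroid[1] + c0 - cx, prop.centroid[0] + r0 - cy)
        if d < best_d:
            best_d, best_lab = d, prop.label
    rows, cols = np.nonzero(labels == best_lab)
    ellipse = _fit_ellipse_moments(rows.astype(float) + r0,
                                   cols.astype(float) + c0)
    box = clip_box(ellipse_bbox(*ellipse), w, h)
    box = (max(box[0], ex0), max(box[1], ey0), min(box[2], ex1), min(box[3], ey1))
    return replace(region, bbox=box, ellipse=ellipse, source="refined")


# ----------------------------------------------------------- HITL round

def hitl_round(model: DetectorModel, images, ground_truth, iou_accept,
               config: DetectorConfig | None = None):
    """One human-in-the-loop iteration: correct proposals, retrain.

    Proposals whose best IoU against a truth region reaches ``iou_accept``
    are kept; all others are discarded and truth regions not covered by a
    kept proposal are inserted as corrections (an untrained model therefore
    yields exactly the ground truth).  Returns ``(corrected_annotations,
    retrained_model)``.
    """
    images = list(images)
    if not images:
        raise DataError("hitl_round needs at least one image")
    cfg = config or model.config
    corrected_all = []
    for image, gts in zip(images, ground_truth):
        proposals = detect_cells(model, image) if model.is_trained else []
        kept = [p for p in proposals
                if max((iou(p.bbox, g.bbox) for g in gts), default=0.0)
                >= iou_accept]
        corrected = []
        rid = 0
        for p in kept:
            best_g = max(gts, key=lambda g: iou(p.bbox, g.bbox), default=None)
            corrected.append(CellAnnotation(
                region_id=rid, center=(p.ellipse[0], p.ellipse[1]),
                semi_axes=(p.ellipse[2], p.ellipse[3]), rotation=p.ellipse[4],
                is_myeloblast=bool(best_g and best_g.is_myeloblast),
                is_promyelocyte=bool(best_g and best_g.is_promyelocyte),
                has_auer_rod=bool(best_g and best_g.has_auer_rod),
                patient_id=best_g.patient_id if best_g else "",
                image_id=best_g.image_id if best_g else ""))
            rid += 1
        for g in gts:       # corrections for truth cells without a kept proposal
            covered = any(iou(p.bbox, g.bbox) >= max(iou_accept, 1e-9)
                          for p in kept)
            if not covered:
                corr = CellAnnotation(
                    region_id=rid, center=g.center, semi_axes=g.semi_axes,
                    rotation=g.rotation, is_myeloblast=g.is_myeloblast,
                    is_promyelocyte=g.is_promyelocyte,
                    has_auer_rod=g.has_auer_rod, patient_id=g.patient_id,
                    image_id=g.image_id, extra={"source": "corrected"})
                corrected.append(corr)
                rid += 1
        corrected_all.append(corrected)
    new_model = train_detector(images, corrected_all, cfg)
    return corrected_all, new_model


# --------------------------------------------------------------- cropping

def crop_cells(image, regions, crop_size=299, background_color=None):
    """Fixed-size per-cell crops: aspect-preserving resize + padding.

    Box content is scaled so the longer side fits ``crop_size`` and padded
    with the background color; regions at the image border are padded, never
    read out of bounds.  Output count always equals input count.
    """
    if crop_size <= 0:
        raise InvalidConfigError("crop_size must be > 0")
    h, w = image.shape[:2]
    if background_color is None:
        background_color = np.median(
            image.reshape(-1, image.shape[2])[::17], axis=0)
    bg = np.asarray(background_color, dtype=np.float64)
    crops = []
    for region in regions:
        box = getattr(region, "bbox", region)
        x0, y0, x1, y1 = box
        c0, r0 = int(np.floor(x0)), int(np.floor(y0))
        c1, r1 = max(int(np.ceil(x1)), c0 + 1), max(int(np.ceil(y1)), r0 + 1)
        win = np.tile(bg, ((r1 - r0), (c1 - c0), 1))
        ic0, ir0 = max(c0, 0), max(r0, 0)
        ic1, ir1 = min(c1, w), min(r1, h)
        if ic1 > ic0 and ir1 > ir0:
            win[ir0 - r0:ir1 - r0, ic0 - c0:ic1 - c0] = \
                image[ir0:ir1, ic0:ic1].astype(np.float64)
        scale = crop_size / max(win.shape[0], win.shape[1])
        nh = max(1, min(crop_size, int(round(win.shape[0] * scale))))
        nw = max(1, min(crop_size, int(round(win.shape[1] * scale))))
        resized = resize(win, (nh, nw), order=1, preserve_range=True,
                         anti_aliasing=(scale < 1.0))
        canvas = np.tile(bg, (crop_size, crop_size, 1))
        top = (crop_size - nh) // 2
        left = (crop_size - nw) // 2
        canvas[top:top + nh, left:left + nw] = resized
        crops.append(np.clip(canvas, 0, 255).astype(np.uint8))
    return crops


# ----------------------------------------------------------------- IO

def detections_to_annotations(regions, image_id=""):
    """Export detector output in the annotation dialect (confidence kept)."""
    out = []
    for r in regions:
        out.append(CellAnnotation(
            region_id=r.region_id, center=(r.ellipse[0], r.ellipse[1]),
            semi_axes=(r.ellipse[2], r.ellipse[3]), rotation=r.ellipse[4],
            is_myeloblast=False, is_promyelocyte=False, has_auer_rod=False,
            image_id=image_id, extra={"confidence": float(r.confidence),
                                      "source": r.source}))
    return out


def save_model(model, path):
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)
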