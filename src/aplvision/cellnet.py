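"""Per-cell classification: three binary classifiers plus morphometrics.

Each segmented cell is scored independently by three binary classifiers —
myeloblast vs. not, promyelocyte vs. not, Auer rod present vs. absent — so
a single cell receives a multi-label triple; e.g. a promyelocyte carrying
one Auer rod encodes as ``(myeloblast 0, promyelocyte 1, Auer rod 1)``.
Each classifier is a fixed feature extractor (downsampled pixels, channel
percentiles and gradient/texture statistics of the crop) feeding a
configurable head of one to three fully connected layers with dropout.
Classical morphometrics (projected size, a sphere-equivalent volume proxy
and RMS contrast) are computed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from ._nnet import DenseNet
from .augment import augment_image, balance_classes
from .errors import DataError, InvalidConfigError
from .synthgen import CellAnnotation

__all__ = ["CellLabel", "CellPrediction", "HeadConfig", "CellModel",
           "CELL_TASKS", "TUNED_POOLING_DROPOUT", "encode_label",
           "crop_features", "train_cell_cnn", "predict_cells", "morphometrics"]

#: the three per-cell binary tasks, in encoding order
CELL_TASKS = ("myeloblast", "promyelocyte", "auer_rod")

#: head dropout rates selected by hyperparameter search for the two
#: diagnosis tasks' upstream cell classifiers
TUNED_POOLING_DROPOUT = {"APL_vs_HEALTHY": 0.32, "APL_vs_AML": 0.46}


@dataclass(frozen=True)
class CellLabel:
    """Multi-label encoding of one cell (each component 0/1)."""
    is_myeloblast: int
    is_promyelocyte: int
    has_auer_rod: int

    def as_tuple(self):
        return (self.is_myeloblast, self.is_promyelocyte, self.has_auer_rod)


@dataclass
class CellPrediction:
    """Per-cell classifier probabilities plus morphometrics."""
    p_myeloblast: float
    p_promyelocyte: float
    p_auer_rod: float
    size_px2: float = 0.0
    volume_proxy: float = 0.0
    contrast: float = 0.0


@dataclass(frozen=True)
class HeadConfig:
    """Architecture of the fully connected classifier head."""
    n_fc_layers: int = 2
    fc_widths: tuple = (32, 16, 8)
    dropout: float = 0.2
    feature_dim: int | None = None      # inferred from the extractor when None
    seed: int = 0
    lr: float = 0.01
    epochs: int = 120
    batch_size: int = 64

    def __post_init__(self):
        if self.n_fc_layers not in (1, 2, 3):
            raise InvalidConfigError("n_fc_layers must be 1, 2 or 3")
        if not (0.0 <= self.dropout < 1.0):
            raise InvalidConfigError("dropout must lie in [0,1)")
        if len(self.fc_widths) < self.n_fc_layers:
            raise InvalidConfigError("fc_widths must provide a width per layer")


def encode_label(annotation: CellAnnotation) -> CellLabel:
    """Ground-truth annotation -> multi-label (myeloblast, promyelocyte, rod)."""
    return CellLabel(int(annotation.is_myeloblast),
                     int(annotation.is_promyelocyte),
                     int(annotation.has_auer_rod))


# -------------------------------------------------------------- features

_PERCENTILES = (1, 5, 10, 25, 50, 75, 90, 95, 99)
_THUMB = 12


def crop_features(crop: np.ndarray) -> np.ndarray:
    """Fixed feature vector of one crop.

    Concatenates a 12x12 RGB thumbnail (coarse shape/color), per-channel
    intensity percentiles (sensitive to small very dark structures such as
    Auer rods), per-channel spread, gradient-magnitude statistics (granule
    texture) and the dark-pixel fraction (nucleus size).
    """
    img = crop.astype(np.float64) / 255.0
    thumb = resize(img, (_THUMB, _THUMB), order=1, preserve_range=True,
                   anti_aliasing=True).reshape(-1)
    flat = img.reshape(-1, 3)
    pct = np.percentile(flat, _PERCENTILES, axis=0).reshape(-1)
    stds = flat.std(axis=0)
    gray = img.mean(axis=2)
    gy, gx = np.gradient(gray)
    gm = np.hypot(gx, gy)
    grad = np.array([gm.mean(), gm.std(),
                     np.percentile(gm, 90), np.percentile(gm, 99)])
    dark = np.array([np.mean(gray < 0.35), np.mean(gray < 0.25)])
    return np.concatenate([thumb, pct, stds, grad, dark])


N_CROP_FEATURES = _THUMB * _THUMB * 3 + len(_PERCENTILES) * 3 + 3 + 4 + 2


# ----------------------------------------------------------------- model

@dataclass
class CellModel:
    """One binary per-cell classifier (feature extractor + FC head)."""
    task: str
    head: DenseNet
    crop_size: int
    config: HeadConfig = field(default_factory=HeadConfig)

    @property
    def is_trained(self) -> bool:
        return self.head.is_trained

    def predict_proba(self, crops) -> np.ndarray:
        crops = list(crops)
        if not crops:
            return np.zeros(0)
        for c in crops:
            if c.shape[0] != self.crop_size or c.shape[1] != self.crop_size:
                raise DataError(
                    f"crop shape {c.shape[:2]} does not match model input "
                    f"{self.crop_size}x{self.crop_size}")
        X = np.stack([crop_features(c) for c in crops])
        return self.head.predict_proba(X)


def train_cell_cnn(crops, targets, head_config: HeadConfig | None = None,
                   seed: int | None = None, task: str = "",
                   balance: bool = False) -> CellModel:
    """Train one binary cell classifier on fixed-size crops.

    Raises :class:`DataError` unless both classes are present.  With
    ``balance=True`` the minority class is upsampled with augmented copies
    before training.
    """
    cfg = head_config or HeadConfig()
    if seed is not None:
        cfg = HeadConfig(**{**cfg.__dict__, "seed": int(seed)})
    crops = list(crops)
    targets = np.asarray(targets, dtype=int)
    if len(crops) == 0 or np.unique(targets).size < 2:
        raise DataError("cell classifier training needs both classes present")
    crop_size = crops[0].shape[0]
    if balance:
        balanced = balance_classes(crops, targets.tolist(), seed=cfg.seed)
        crops = [augment_image(b.record, b.params) if b.is_augmented else b.record
                 for b in balanced]
        targets = np.asarray([b.label for b in balanced], dtype=int)
    X = np.stack([crop_features(c) for c in crops])
    feature_dim = cfg.feature_dim or X.shape[1]
    if X.shape[1] != feature_dim:
        raise InvalidConfigError(
            f"feature_dim {feature_dim} does not match extractor output {X.shape[1]}")
    head = DenseNet(feature_dim, hidden=tuple(cfg.fc_widths[:cfg.n_fc_layers]),
                    dropout=cfg.dropout, lr=cfg.lr, epochs=cfg.epochs,
                    batch_size=cfg.batch_size, seed=cfg.seed)
    head.fit(X, targets)
    return CellModel(task=task, head=head, crop_size=crop_size, config=cfg)


def predict_cells(models, crops, masks=None) -> list[CellPrediction]:
    """Score every crop with the three task models and attach morphometrics.

    ``models`` maps task name (see :data:`CELL_TASKS`) to a trained
    :class:`CellModel`.
    """
    crops = list(crops)
    if not crops:
        return []
    for task in CELL_TASKS:
        size = models[task].crop_size
        for c in crops:
            if c.shape[0] != size or c.shape[1] != size:
                raise DataError(
                    f"crop shape {c.shape[:2]} does not match {task} model "
                    f"input {size}x{size}")
    # the extractor is shared across tasks: compute features once
    X = np.stack([crop_features(c) for c in crops])
    probs = {task: models[task].head.predict_proba(X) for task in CELL_TASKS}
    preds = []
    for i, crop in enumerate(crops):
        mask = masks[i] if masks is not None else None
        size, volume, contrast = morphometrics(crop, mask)
        preds.append(CellPrediction(
            p_myeloblast=float(probs["myeloblast"][i]),
            p_promyelocyte=float(probs["promyelocyte"][i]),
            p_auer_rod=float(probs["auer_rod"][i]),
            size_px2=size, volume_proxy=volume, contrast=contrast))
    return preds


def morphometrics(crop: np.ndarray, mask: np.ndarray | None = None):
    """(size_px2, volume_proxy, contrast) of one cell crop.

    Size is the foreground pixel count; the volume proxy
    ``(4/3)·sqrt(pi)·size^(3/2)`` is the sphere-equivalent volume of a
    circle with that area; contrast is the RMS deviation of foreground
    luminance.  Without a usable mask the foreground is
    estimated by distance from the median (background) color, falling back
    to the whole crop.
    """
    img = crop.astype(np.float64) / 255.0
    if mask is None or mask.shape != img.shape[:2] or mask.sum() < 4:
        bg = np.median(img.reshape(-1, 3), axis=0)
        mask = np.linalg.norm(img - bg, axis=2) > 0.1
        if mask.sum() < 4:
            mask = np.ones(img.shape[:2], dtype=bool)
    size = float(mask.sum())
    volume = (4.0 / 3.0) * np.sqrt(np.pi) * size ** 1.5
    gray = img.mean(axis=2)[mask]
    contrast = float(np.sqrt(np.mean((gray - gray.mean()) ** 2)))
    return size, float(volume), contrast
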