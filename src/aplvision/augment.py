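"""Annotation-safe image augmentation and class balancing.

The operators are restricted to transforms that keep box/ellipse ground
truth exact: horizontal/vertical flips, right-angle rotations, per-channel
color shifts and a global brightness shift (both clipped to the valid pixel
range).  Class balancing counters the rarity of the APL-defining cell types
by upsampling each minority class to the majority count with augmented
copies; every copy records its parent, and parents' patient identity is
inherited so grouped cross-validation keeps augmented records in their
parent's fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DataError, InvalidParameterError

__all__ = ["AugmentParams", "augment_image", "sample_params",
           "BalancedRecord", "balance_classes"]

_ALLOWED_ROTATIONS = (0, 90, 180, 270)


@dataclass(frozen=True)
class AugmentParams:
    flip_h: bool = False
    flip_v: bool = False
    rotation: int = 0                       # degrees, one of {0, 90, 180, 270}
    color_shift: tuple = (0.0, 0.0, 0.0)    # per-channel additive delta
    brightness: float = 0.0                 # global additive delta


def augment_image(image: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Apply one deterministic augmentation; output is clipped uint8.

    90/270-degree rotations swap width and height; all other operators
    preserve dimensions.
    """
    if params.rotation not in _ALLOWED_ROTATIONS:
        raise InvalidParameterError(
            f"rotation must be one of {_ALLOWED_ROTATIONS}, got {params.rotation}")
    out = np.asarray(image)
    if params.flip_h:
        out = out[:, ::-1]
    if params.flip_v:
        out = out[::-1, :]
    if params.rotation:
        out = np.rot90(out, k=params.rotation // 90)
    out = out.astype(np.float64)
    if any(params.color_shift):
        out = out + np.asarray(params.color_shift, dtype=float)
    if params.brightness:
        out = out + params.brightness
    return np.clip(out, 0, 255).astype(np.uint8)


def sample_params(rng: np.random.Generator, max_color_shift: float = 18.0,
                  max_brightness: float = 22.0) -> AugmentParams:
    """Draw a random augmentation within clip-safe default ranges."""
    return AugmentParams(
        flip_h=bool(rng.integers(2)),
        flip_v=bool(rng.integers(2)),
        rotation=int(rng.choice(_ALLOWED_ROTATIONS)),
        color_shift=tuple(rng.uniform(-max_color_shift, max_color_shift, 3)),
        brightness=float(rng.uniform(-max_brightness, max_brightness)),
    )


@dataclass
class BalancedRecord:
    """One record of a balanced set: an original or an augmented copy."""
    record: Any
    label: Any
    parent_index: int                  # index into the original record list
    params: AugmentParams | None = None    # None for originals

    @property
    def is_augmented(self) -> bool:
        return self.params is not None


def balance_classes(records, labels, seed: int = 0) -> list[BalancedRecord]:
    """Upsample every minority class to the majority class count.

    All originals are retained; minority classes are topped up with
    augmented copies of randomly chosen parents from the same class, each
    with its own augmentation parameter draw.
    """
    records = list(records)
    labels = list(labels)
    if len(records) != len(labels):
        raise DataError("records and labels must align")
    by_class: dict[Any, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    if not by_class or any(len(v) == 0 for v in by_class.values()):
        raise DataError("every class must be non-empty")
    target = max(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    out = [BalancedRecord(records[i], labels[i], parent_index=i)
           for i in range(len(records))]
    for lab in sorted(by_class, key=str):
        members = by_class[lab]
        for _ in range(target - len(members)):
            parent = int(rng.choice(members))
            out.append(BalancedRecord(records[parent], lab, parent_index=parent,
                                      params=sample_params(rng)))
    return out
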