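"""Occlusion sensitivity mapping for smear-level classification.

Patches of the image are replaced by a fill color one grid cell at a
time; the drop of the classifier score relative to the unoccluded
baseline is the patch's importance.  High importance over cells and near
zero over background is the qualitative sanity check that the smear
classifier is actually looking at cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .errors import InvalidParameterError

__all__ = ["OcclusionMap", "occlusion_map", "render_map", "importance_to_csv"]


@dataclass
class OcclusionMap:
    importance: np.ndarray          # (rows, cols) grid
    patch_size: int
    stride: int
    baseline: float
    image_shape: tuple


def occlusion_map(score_fn, image, patch_size: int = 32, stride: int = 16,
                  fill=None) -> OcclusionMap:
    """Slide an occluding patch over the image and record the score drops.

    The grid has ``floor((H - patch)/stride) + 1`` rows and the analogous
    number of columns; importance is ``baseline - occluded`` score.  The
    input image is left unmodified.
    """
    h, w = image.shape[:2]
    if patch_size > min(h, w):
        raise InvalidParameterError("patch_size must not exceed min(H, W)")
    if stride < 1:
        raise InvalidParameterError("stride must be >= 1")
    if fill is None:
        fill = np.median(image.reshape(-1, image.shape[2])[::17], axis=0)
    fill = np.asarray(fill, dtype=image.dtype)
    baseline = float(score_fn(image))
    n_rows = (h - patch_size) // stride + 1
    n_cols = (w - patch_size) // stride + 1
    grid = np.zeros((n_rows, n_cols))
    for i in range(n_rows):
        for j in range(n_cols):
            occluded = image.copy()
            r, c = i * stride, j * stride
            occluded[r:r + patch_size, c:c + patch_size] = fill
            grid[i, j] = baseline - float(score_fn(occluded))
    return OcclusionMap(importance=grid, patch_size=patch_size, stride=stride,
                        baseline=baseline, image_shape=(h, w))


def importance_to_csv(omap: OcclusionMap, path):
    """Write the raw importance grid as CSV (one row per grid row)."""
    np.savetxt(path, omap.importance, delimiter=",")


def render_map(omap: OcclusionMap, image, alpha: float = 0.45,
               cmap: str = "viridis") -> np.ndarray:
    """Overlay the min-max-normalized importance grid on the image.

    An all-equal map renders uniformly at mid-scale.  The overlay has the
    image's dimensions; scalar rescalings of a map render identically.
    """
    h, w = image.shape[:2]
    if omap.image_shape != (h, w):
        raise InvalidParameterError("occlusion map does not match this image")
    grid = omap.importance.astype(float)
    span = grid.max() - grid.min()
    norm = (grid - grid.min()) / span if span > 0 else np.full_like(grid, 0.5)
    heat = resize(norm, (h, w), order=0, preserve_range=True,
                  anti_aliasing=False)
    colors = colormaps[cmap](heat)[..., :3]
    base = image.astype(np.float64) / 255.0
    overlay = (1 - alpha) * base + alpha * colors
    return np.clip(overlay * 255, 0, 255).astype(np.uint8)
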