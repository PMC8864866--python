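"""Ellipse/box geometry shared by the generator, annotation IO and detector.

Conventions (fixed package-wide): images are ``(H, W, 3)`` arrays, origin at
the top-left; ``x`` is the column axis, ``y`` the row axis; boxes are
``(x_min, y_min, x_max, y_max)``, 0-based and half-open; ellipse rotation
``theta`` is in radians, counter-clockwise in the ``(x right, y down)``
frame.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ellipse_bbox", "ellipse_mask_window", "inscribed_ellipse", "clip_box"]


def ellipse_bbox(cx, cy, rx, ry, theta):
    """Tight axis-aligned bounding box of a rotated ellipse.

    Half-extents of a rotated ellipse along the axes are
    ``wx = sqrt((rx cos t)^2 + (ry sin t)^2)`` and the symmetric expression
    for ``wy``.
    """
    wx = float(np.hypot(rx * np.cos(theta), ry * np.sin(theta)))
    wy = float(np.hypot(rx * np.sin(theta), ry * np.cos(theta)))
    return (cx - wx, cy - wy, cx + wx, cy + wy)


def ellipse_mask_window(shape, cx, cy, rx, ry, theta):
    """Boolean interior mask of an ellipse, restricted to its image window.

    Returns ``(ys, xs, mask)`` where ``ys``/``xs`` are slices into an image of
    ``shape=(H, W)`` and ``mask`` is the boolean interior over that window.
    """
    h, w = shape[:2]
    x0, y0, x1, y1 = ellipse_bbox(cx, cy, rx, ry, theta)
    c0 = max(int(np.floor(x0)), 0)
    r0 = max(int(np.floor(y0)), 0)
    c1 = min(int(np.ceil(x1)) + 1, w)
    r1 = min(int(np.ceil(y1)) + 1, h)
    if c0 >= c1 or r0 >= r1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), dtype=bool)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / max(rx, 1e-9)
    v = (-dx * st + dy * ct) / max(ry, 1e-9)
    mask = u * u + v * v <= 1.0
    return slice(r0, r1), slice(c0, c1), mask


def inscribed_ellipse(box):
    """Axis-aligned ellipse inscribed in a box -> (cx, cy, rx, ry, theta=0)."""
    x0, y0, x1, y1 = box
    return ((x0 + x1) / 2.0, (y0 + y1) / 2.0, (x1 - x0) / 2.0, (y1 - y0) / 2.0, 0.0)


def clip_box(box, width, height):
    """Clip a box to image bounds."""
    x0, y0, x1, y1 = box
    return (max(0.0, min(x0, width)), max(0.0, min(y0, height)),
            max(0.0, min(x1, width)), max(0.0, min(y1, height)))
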