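"""Read/write cell annotations in a VGG-Image-Annotator-compatible JSON dialect.

The file maps image filenames to records with a ``regions`` list.  Each
region stores elliptical ``shape_attributes`` (``name='ellipse'``, ``cx``,
``cy``, ``rx``, ``ry``, ``theta`` in radians, counter-clockwise) and
``region_attributes`` with ``cell_type`` in {myeloblast, promyelocyte,
other} and an ``auer_rod`` 0/1 flag.  Unknown region attributes survive a
read/write round trip verbatim.  Bounding boxes are never stored: they are
derived from the ellipse on read.
"""

from __future__ import annotations

import json
import logging

import pandas as pd

from .errors import FormatError
from .synthgen import CellAnnotation

__all__ = ["write_annotations", "read_annotations", "load_manifest", "save_manifest"]

logger = logging.getLogger(__name__)

_KNOWN_REGION_ATTRS = {"cell_type", "auer_rod", "region_id", "patient_id"}


def write_annotations(annotations, path, filename=None):
    """Write annotations to ``path`` grouped by image filename.

    ``filename`` overrides the image key for annotations whose ``image_id``
    is empty; annotations carrying an ``image_id`` are grouped under it.
    """
    by_image: dict[str, list] = {}
    for ann in annotations:
        key = ann.image_id or filename or "image"
        by_image.setdefault(key, []).append(ann)
    if not by_image and filename:
        by_image[filename] = []
    doc = {}
    for key, anns in by_image.items():
        regions = []
        for ann in anns:
            attrs = {
                "cell_type": ann.cell_type,
                "auer_rod": int(ann.has_auer_rod),
                "region_id": int(ann.region_id),
                "patient_id": ann.patient_id,
            }
            attrs.update(ann.extra)
            regions.append({
                "shape_attributes": {
                    "name": "ellipse",
                    "cx": float(ann.center[0]), "cy": float(ann.center[1]),
                    "rx": float(ann.semi_axes[0]), "ry": float(ann.semi_axes[1]),
                    "theta": float(ann.rotation),
                },
                "region_attributes": attrs,
            })
        doc[key] = {"filename": key, "regions": regions}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _region_to_annotation(region, image_id):
    shape = region["shape_attributes"]
    if shape.get("name") != "ellipse":
        raise KeyError("unsupported shape type")
    attrs = region.get("region_attributes", {})
    cell_type = attrs.get("cell_type", "other")
    extra = {k: v for k, v in attrs.items() if k not in _KNOWN_REGION_ATTRS}
    return CellAnnotation(
        region_id=int(attrs.get("region_id", 0)),
        center=(float(shape["cx"]), float(shape["cy"])),
        semi_axes=(float(shape["rx"]), float(shape["ry"])),
        rotation=float(shape["theta"]),
        is_myeloblast=(cell_type == "myeloblast"),
        is_promyelocyte=(cell_type == "promyelocyte"),
        has_auer_rod=bool(int(attrs.get("auer_rod", 0))),
        patient_id=str(attrs.get("patient_id", "")),
        image_id=image_id,
        extra=extra,
    )


def read_annotations(path, return_skipped=False):
    """Parse an annotation file into :class:`CellAnnotation` objects.

    Malformed regions (missing/unknown shape attributes, non-numeric
    fields) are skipped with a logged warning; with
    ``return_skipped=True`` the skip count is returned alongside the list.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: top level must be an object keyed by filename")
    annotations, skipped = [], 0
    for image_id, record in doc.items():
        regions = record.get("regions", []) if isinstance(record, dict) else None
        if regions is None:
            raise FormatError(f"{path}: record {image_id!r} is not an object")
        for i, region in enumerate(regions):
            try:
                annotations.append(_region_to_annotation(region, image_id))
            except (KeyError, TypeError, ValueError) as exc:
                skipped += 1
                logger.warning("skipping malformed region %d of %s in %s: %s",
                               i, image_id, path, exc)
    if return_skipped:
        return annotations, skipped
    return annotations


def save_manifest(manifest: pd.DataFrame, path):
    manifest.to_csv(path, index=False,
                    columns=["image_path", "annotation_path", "patient_id", "diagnosis"])


def load_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype=str)
    required = {"image_path", "annotation_path", "patient_id", "diagnosis"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return manifest
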