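"""Seeded synthetic bone-marrow-smear generator with ground-truth annotations.

The generator emulates the three clinical situations the classifier must
tell apart at the level that matters for the downstream ratio features:

* **healthy marrow** — almost exclusively mature/"other" cells, blast-family
  fraction below 5%;
* **non-APL AML** — a myeloblast excess centered at the cohort median
  marrow-blast fraction of 63.5%;
* **APL** — an abnormal-promyelocyte excess centered at 63% of cells, a
  subset of which carry Auer rods.

Cells are rendered as rotated ellipses with a type-specific appearance:
a pale smooth cytoplasm and a large nucleus for myeloblasts, heavy
azurophilic granulation for promyelocytes, and thin dark-crimson rod
primitives for Auer-rod-bearing promyelocytes.  Annotation-free smudge
artifacts and occasional cell overlap are included so the detector has
something to reject.  Every draw flows from one seeded generator, so a
fixed ``(spec, patient_id, seed)`` triple reproduces images and
annotations byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .geometry import ellipse_bbox, ellipse_mask_window

__all__ = [
    "CellTypeSpec", "CohortSpec", "CellAnnotation", "SynthDataset",
    "default_cell_types", "default_cohort_specs", "sample_composition",
    "generate_smear", "generate_cohort", "BACKGROUND_COLOR",
    "PROMYELOCYTE_FAMILY", "BLAST_FAMILY",
]

BACKGROUND_COLOR = (230, 225, 234)

#: cell types whose excess defines APL (abnormal promyelocytes +/- Auer rods)
PROMYELOCYTE_FAMILY = ("promyelocyte", "auer_promyelocyte")
#: immature precursor types counted as "blasts" in marrow differentials
BLAST_FAMILY = ("myeloblast", "promyelocyte", "auer_promyelocyte")


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class CellTypeSpec:
    """Appearance model for one cell type."""
    type_name: str
    radius_range: tuple[float, float]
    granule_density: float          # granules per 100 px^2 of cell area
    nucleus_fraction: float         # fraction of cell area occupied by nucleus
    auer_rod_count_range: tuple[int, int]
    palette: dict = field(default_factory=dict)  # cytoplasm/nucleus/granule/rod RGB

    def __post_init__(self):
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise InvalidSpecError(f"{self.type_name}: radius range min must be <= max and > 0")
        if self.granule_density < 0:
            raise InvalidSpecError(f"{self.type_name}: granule_density must be >= 0")
        if not (0.0 < self.nucleus_fraction < 1.0):
            raise InvalidSpecError(f"{self.type_name}: nucleus_fraction must lie in (0,1)")
        rlo, rhi = self.auer_rod_count_range
        if rlo > rhi or rlo < 0:
            raise InvalidSpecError(f"{self.type_name}: bad auer_rod_count_range")
        if (self.type_name == "auer_promyelocyte") != (rlo >= 1):
            raise InvalidSpecError(
                "auer_rod_count_range min must be >= 1 exactly for auer_promyelocyte")


@dataclass(frozen=True)
class CohortSpec:
    """One diagnosis cohort: composition, geometry and artifact rates."""
    diagnosis: str                       # APL | AML | HEALTHY
    n_patients: int
    images_per_patient: int
    cells_per_image_range: tuple[int, int]
    composition: dict                    # type_name -> mean fraction
    concentration: float = 12.0          # Dirichlet concentration for patient-level spread
    overlap_prob: float = 0.05
    smudge_rate: float = 1.5             # Poisson mean smudges per image
    image_size: tuple[int, int] = (512, 384)   # (width, height) px
    cell_types: dict = field(default_factory=lambda: default_cell_types())

    def __post_init__(self):
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise InvalidSpecError("image_size must be positive")
        lo, hi = self.cells_per_image_range
        if lo < 0 or lo > hi:
            raise InvalidSpecError("cells_per_image_range must satisfy 0 <= min <= max")
        total = float(sum(self.composition.values()))
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(f"composition fractions must sum to 1, got {total}")
        for name, frac in self.composition.items():
            if frac < 0:
                raise InvalidSpecError(f"negative composition fraction for {name}")
            if name not in self.cell_types:
                raise InvalidSpecError(f"composition names unknown cell type {name!r}")
        for p, label in ((self.overlap_prob, "overlap_prob"),):
            if not (0.0 <= p <= 1.0):
                raise InvalidSpecError(f"{label} must lie in [0,1]")
        if self.smudge_rate < 0 or self.n_patients < 0 or self.images_per_patient < 0:
            raise InvalidSpecError("counts and rates must be non-negative")


@dataclass
class CellAnnotation:
    """Ground truth for one elliptical cell region."""
    region_id: int
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    is_myeloblast: bool
    is_promyelocyte: bool
    has_auer_rod: bool
    patient_id: str = ""
    image_id: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """Tight axis-aligned box of the rotated ellipse (half-open)."""
        cx, cy = self.center
        rx, ry = self.semi_axes
        return ellipse_bbox(cx, cy, rx, ry, self.rotation)

    @property
    def cell_type(self) -> str:
        if self.is_myeloblast:
            return "myeloblast"
        if self.is_promyelocyte:
            return "promyelocyte"
        return "other"


@dataclass
class SynthDataset:
    """A generated cohort: manifest plus in-memory images/annotations.

    ``manifest`` columns: image_path, annotation_path, patient_id, diagnosis.
    When written to disk the paths are real files; in memory they double as
    image ids into ``images``/``annotations``.
    """
    manifest: pd.DataFrame
    images: dict
    annotations: dict

    def image_ids(self):
        return list(self.manifest["image_path"])


# ------------------------------------------------------------------ defaults

def default_cell_types(radius_scale: float = 1.0) -> dict:
    """Desk-scale appearance defaults for the four rendered cell types."""
    s = radius_scale
    return {
        "myeloblast": CellTypeSpec(
            "myeloblast", (14 * s, 20 * s), granule_density=0.05,
            nucleus_fraction=0.78, auer_rod_count_range=(0, 0),
            palette={"cytoplasm": (175, 185, 228), "nucleus": (88, 70, 150),
                     "granule": (140, 100, 170), "rod": (128, 22, 48)}),
        "promyelocyte": CellTypeSpec(
            "promyelocyte", (14 * s, 20 * s), granule_density=2.5,
            nucleus_fraction=0.42, auer_rod_count_range=(0, 0),
            palette={"cytoplasm": (205, 170, 205), "nucleus": (95, 65, 140),
                     "granule": (130, 40, 110), "rod": (128, 22, 48)}),
        "auer_promyelocyte": CellTypeSpec(
            "auer_promyelocyte", (14 * s, 20 * s), granule_density=2.5,
            nucleus_fraction=0.42, auer_rod_count_range=(1, 3),
            palette={"cytoplasm": (205, 170, 205), "nucleus": (95, 65, 140),
                     "granule": (130, 40, 110), "rod": (128, 22, 48)}),
        "other": CellTypeSpec(
            "other", (8 * s, 13 * s), granule_density=0.0,
            nucleus_fraction=0.50, auer_rod_count_range=(0, 0),
            palette={"cytoplasm": (215, 205, 220), "nucleus": (120, 90, 160),
                     "granule": (150, 120, 180), "rod": (128, 22, 48)}),
    }


def default_cohort_specs(n_patients: int = 17, images_per_patient: int = 3,
                         image_size=(512, 384)) -> dict:
    """Cohort defaults mirroring the clinical marrow-blast medians.

    APL marrow centers at 63% promyelocyte-family cells (a fraction of which
    bear Auer rods), non-APL AML at 63.5% myeloblasts, and healthy donor
    marrow keeps the blast family below 5%.  Leukemic cohorts get a loose
    Dirichlet concentration reproducing the wide interquartile blast spread
    seen across patients; healthy marrow varies much less.
    """
    common = dict(n_patients=n_patients, images_per_patient=images_per_patient,
                  cells_per_image_range=(18, 32), image_size=image_size)
    return {
        "APL": CohortSpec(
            diagnosis="APL",
            composition={"myeloblast": 0.07, "promyelocyte": 0.46,
                         "auer_promyelocyte": 0.17, "other": 0.30},
            concentration=12.0, **common),
        "AML": CohortSpec(
            diagnosis="AML",
            composition={"myeloblast": 0.635, "promyelocyte": 0.05,
                         "auer_promyelocyte": 0.015, "other": 0.30},
            concentration=12.0, **common),
        "HEALTHY": CohortSpec(
            diagnosis="HEALTHY",
            composition={"myeloblast": 0.02, "promyelocyte": 0.02,
                         "auer_promyelocyte": 0.0, "other": 0.96},
            concentration=50.0, **common),
    }


def sample_composition(spec: CohortSpec, rng: np.random.Generator) -> dict:
    """Draw one patient's cell-type composition from the cohort Dirichlet.

    Types with zero mean stay exactly zero.  Concentrations above 1e8 are
    treated as degenerate (composition equals the spec mean), which makes
    per-cell type draws exactly binomial per type.
    """
    names = sorted(spec.composition)
    means = np.array([spec.composition[n] for n in names])
    if spec.concentration >= 1e8:
        fracs = means
    else:
        pos = means > 0
        fracs = np.zeros_like(means)
        fracs[pos] = rng.dirichlet(means[pos] * spec.concentration)
    return dict(zip(names, fracs))


# ----------------------------------------------------------------- rendering

def _stable_token(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _paint_ellipse(img, cx, cy, rx, ry, theta, color, noise_sd, rng):
    ys, xs, mask = ellipse_mask_window(img.shape, cx, cy, rx, ry, theta)
    if mask.size == 0:
        return
    patch = img[ys, xs]
    noise = rng.normal(0.0, noise_sd, size=(mask.sum(), 3))
    patch[mask] = np.clip(np.asarray(color, dtype=float) + noise, 0, 255)
    img[ys, xs] = patch


def _sample_in_ellipse(rng, cx, cy, rx, ry, theta, shrink=1.0):
    """Uniform point inside the (shrunken) ellipse."""
    t = rng.uniform(0, 2 * np.pi)
    r = np.sqrt(rng.uniform())
    u = r * np.cos(t) * rx * shrink
    v = r * np.sin(t) * ry * shrink
    ct, st = np.cos(theta), np.sin(theta)
    return cx + u * ct - v * st, cy + u * st + v * ct


def _draw_disk(img, cx, cy, radius, color, rng, jitter=6.0):
    h, w = img.shape[:2]
    r0, r1 = max(int(cy - radius), 0), min(int(np.ceil(cy + radius)) + 1, h)
    c0, c1 = max(int(cx - radius), 0), min(int(np.ceil(cx + radius)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    col = np.clip(np.asarray(color, float) + rng.normal(0, jitter, 3), 0, 255)
    patch = img[r0:r1, c0:c1]
    patch[mask] = col
    img[r0:r1, c0:c1] = patch


def _draw_rod(img, x0, y0, angle, length, width, color, rng):
    """Thin dark rod: filled rotated rectangle centered at (x0, y0)."""
    h, w = img.shape[:2]
    ct, st = np.cos(angle), np.sin(angle)
    hl, hw = length / 2.0, width / 2.0
    pad = int(np.ceil(hl + hw)) + 1
    r0, r1 = max(int(y0) - pad, 0), min(int(y0) + pad + 1, h)
    c0, c1 = max(int(x0) - pad, 0), min(int(x0) + pad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    du = (xx - x0) * ct + (yy - y0) * st
    dv = -(xx - x0) * st + (yy - y0) * ct
    mask = (np.abs(du) <= hl) & (np.abs(dv) <= hw)
    col = np.clip(np.asarray(color, float) + rng.normal(0, 4, 3), 0, 255)
    patch = img[r0:r1, c0:c1]
    patch[mask] = col
    img[r0:r1, c0:c1] = patch


def _draw_smudge(img, rng):
    """Annotation-free artifact: a few overlapping low-saturation blobs."""
    h, w = img.shape[:2]
    cx, cy = rng.uniform(0, w), rng.uniform(0, h)
    for _ in range(rng.integers(2, 5)):
        rx = rng.uniform(6, 18)
        ry = rng.uniform(6, 18)
        theta = rng.uniform(0, np.pi)
        ox, oy = rng.normal(0, 6, 2)
        _paint_ellipse(img, cx + ox, cy + oy, rx, ry, theta,
                       (185, 178, 198), noise_sd=7.0, rng=rng)


def _render_cell(img, ct_spec: CellTypeSpec, cx, cy, rx, ry, theta, rng) -> int:
    """Draw one cell; returns the number of Auer rods drawn."""
    pal = ct_spec.palette
    _paint_ellipse(img, cx, cy, rx, ry, theta, pal["cytoplasm"], 3.0, rng)
    # nucleus: concentric shape scaled to the requested area fraction,
    # slightly off-center for a natural look
    k = np.sqrt(ct_spec.nucleus_fraction)
    off = rng.normal(0, 0.06 * rx, 2)
    _paint_ellipse(img, cx + off[0], cy + off[1], rx * k, ry * k, theta,
                   pal["nucleus"], 4.0, rng)
    area = np.pi * rx * ry
    n_gran = rng.poisson(ct_spec.granule_density * area / 100.0)
    for _ in range(n_gran):
        gx, gy = _sample_in_ellipse(rng, cx, cy, rx, ry, theta, shrink=0.92)
        _draw_disk(img, gx, gy, rng.uniform(0.8, 1.6), pal["granule"], rng)
    lo, hi = ct_spec.auer_rod_count_range
    n_rods = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    for _ in range(n_rods):
        px, py = _sample_in_ellipse(rng, cx, cy, rx, ry, theta, shrink=0.45)
        _draw_rod(img, px, py, rng.uniform(0, np.pi),
                  length=rng.uniform(0.9, 1.3) * min(rx, ry),
                  width=rng.uniform(1.6, 2.2), color=pal["rod"], rng=rng)
    return n_rods


# ---------------------------------------------------------------- generation

def generate_smear(spec: CohortSpec, patient_id: str, seed: int,
                   composition: dict | None = None):
    """Render one synthetic smear image plus its ground-truth annotations.

    ``composition`` overrides the per-patient cell-type fractions; when
    omitted it is drawn deterministically from ``(seed, patient_id)`` so the
    same triple always yields a byte-identical image and annotation list.
    """
    w, h = spec.image_size
    if w <= 0 or h <= 0:
        raise InvalidSpecError("image_size must be positive")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _stable_token(patient_id)]))
    if composition is None:
        composition = sample_composition(spec, rng)
    names = sorted(composition)
    probs = np.array([composition[n] for n in names], dtype=float)
    probs = probs / probs.sum() if probs.sum() > 0 else probs

    img = np.clip(
        np.asarray(BACKGROUND_COLOR, float)
        + rng.normal(0.0, 2.5, size=(h, w, 3)), 0, 255)

    for _ in range(rng.poisson(spec.smudge_rate)):
        _draw_smudge(img, rng)

    lo, hi = spec.cells_per_image_range
    n_cells = int(rng.integers(lo, hi + 1))
    types = [names[i] for i in rng.choice(len(names), size=n_cells, p=probs)] \
        if n_cells else []

    annotations: list[CellAnnotation] = []
    placed: list[tuple[float, float, float]] = []   # (cx, cy, rmax)
    for rid, tname in enumerate(types):
        ct = spec.cell_types[tname]
        rx = rng.uniform(*ct.radius_range)
        ry = rx * rng.uniform(0.75, 1.0)
        theta = rng.uniform(0, np.pi)
        rmax = max(rx, ry)
        allow_overlap = rng.random() < spec.overlap_prob
        cx = cy = None
        for _ in range(300):
            tx = rng.uniform(rmax + 1, w - rmax - 1) if w > 2 * rmax + 2 else w / 2
            ty = rng.uniform(rmax + 1, h - rmax - 1) if h > 2 * rmax + 2 else h / 2
            if allow_overlap or all(
                    (tx - px) ** 2 + (ty - py) ** 2 > (rmax + pr + 2) ** 2
                    for px, py, pr in placed):
                cx, cy = tx, ty
                break
        if cx is None:       # crowded image: accept the last position
            cx, cy = tx, ty
        n_rods = _render_cell(img, ct, cx, cy, rx, ry, theta, rng)
        placed.append((cx, cy, rmax))
        annotations.append(CellAnnotation(
            region_id=rid, center=(cx, cy), semi_axes=(rx, ry), rotation=theta,
            is_myeloblast=(tname == "myeloblast"),
            is_promyelocyte=(tname in PROMYELOCYTE_FAMILY),
            has_auer_rod=(n_rods >= 1),
            patient_id=patient_id))
    return img.astype(np.uint8), annotations


def generate_cohort(specs, seed: int, out_dir=None) -> SynthDataset:
    """Generate a full multi-cohort dataset and its manifest.

    ``specs`` is an iterable of :class:`CohortSpec` with distinct diagnoses.
    With ``out_dir`` set, images (PNG), annotation files (JSON) and
    ``manifest.csv`` are written there; the dataset is always also returned
    in memory.
    """
    specs = list(specs)
    diagnoses = [s.diagnosis for s in specs]
    if len(set(diagnoses)) != len(diagnoses):
        raise InvalidSpecError("duplicate diagnosis across cohort specs")

    rows, images, annotations = [], {}, {}
    for si, spec in enumerate(specs):
        for pi in range(spec.n_patients):
            patient_id = f"{spec.diagnosis}-{pi:03d}"
            comp_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, si, pi, 777]))
            composition = sample_composition(spec, comp_rng)
            for ii in range(spec.images_per_patient):
                img_seed = int(np.random.SeedSequence(
                    [int(seed) & 0x7FFFFFFF, si, pi, ii]).generate_state(1)[0]
                    & 0x7FFFFFFF)
                image_id = f"{patient_id}_img{ii:02d}.png"
                img, anns = generate_smear(spec, patient_id, img_seed,
                                           composition=composition)
                for a in anns:
                    a.image_id = image_id
                ann_id = image_id.replace(".png", ".json")
                images[image_id] = img
                annotations[image_id] = anns
                rows.append({"image_path": image_id, "annotation_path": ann_id,
                             "patient_id": patient_id,
                             "diagnosis": spec.diagnosis})
    manifest = pd.DataFrame(rows, columns=["image_path", "annotation_path",
                                           "patient_id", "diagnosis"])
    ds = SynthDataset(manifest=manifest, images=images, annotations=annotations)
    if out_dir is not None:
        _write_dataset(ds, out_dir)
    return ds


def _write_dataset(ds: SynthDataset, out_dir):
    import os
    from PIL import Image

    from . import annotio

    os.makedirs(out_dir, exist_ok=True)
    new_paths = {}
    for _, row in ds.manifest.iterrows():
        image_id = row["image_path"]
        img_path = os.path.join(out_dir, image_id)
        Image.fromarray(ds.images[image_id]).save(img_path)
        ann_path = os.path.join(out_dir, row["annotation_path"])
        annotio.write_annotations(ds.annotations[image_id], ann_path,
                                  filename=image_id)
        new_paths[image_id] = (img_path, ann_path)
    manifest = ds.manifest.copy()
    manifest["image_path"] = [new_paths[i][0] for i in ds.manifest["image_path"]]
    manifest["annotation_path"] = [new_paths[i][1]
                                   for i in ds.manifest["image_path"]]
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
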