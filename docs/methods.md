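# Methods

This note records the modeling choices behind `aplvision`: what each stage
assumes, which parameters matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Synthetic smear generator

The generator is the package's substitute for digitized bone marrow
smears. Each smear is a noisy pale background with three kinds of content:

- **Cells** are rotated ellipses with a type-specific appearance:
  - *myeloblast* — semi-axes 14–20 px (desk scale), nucleus occupying 78%
    of cell area, smooth pale-blue cytoplasm, essentially no granules;
  - *promyelocyte* — same size range, nucleus 42%, pink cytoplasm with
    heavy azurophilic granulation (2.5 granules / 100 px²);
  - *Auer-rod-bearing promyelocyte* — a promyelocyte plus 1–3 thin
    dark-crimson rod primitives (width ≈ 2 px, length ≈ the minor radius);
  - *other* (mature cells) — smaller (8–13 px), moderate nucleus, no
    granules.
- **Smudge artifacts** are annotation-free clusters of low-saturation
  blobs, drawn at Poisson rate 1.5 per image; the detector must reject
  them.
- **Overlap**: each cell independently ignores the non-overlap constraint
  with probability 0.05 (0 in the detector benchmarks, which use clean
  non-overlapping smears).

Class-conditional compositions are the study conditions. Mean cell-type
fractions per cohort:

| cohort  | myeloblast | promyelocyte | rod-bearing | other | concentration |
|---------|-----------:|-------------:|------------:|------:|--------------:|
| APL     | 0.07       | 0.46         | 0.17        | 0.30  | 12            |
| AML     | 0.635      | 0.05         | 0.015       | 0.30  | 12            |
| HEALTHY | 0.02       | 0.02         | 0.0         | 0.96  | 50            |

APL's promyelocyte-family total (0.63) and AML's myeloblast fraction
(0.635) reproduce the median marrow blast percentages reported for those
cohorts (63 and 63.5); healthy marrow keeps the blast family under 5%.
Each *patient* draws one composition from a Dirichlet with the given
concentration (leukemic cohorts get a loose concentration of 12, matching
the wide interquartile blast spread across patients; healthy marrow varies
less), and all of that patient's images share it — this creates the
patient-level correlation that the grouped cross-validation split must
respect. Per cell, the type is a categorical draw from the patient
composition, so type counts are (beta-)binomial and testable against exact
intervals.

Desk-scale images are 512×384 px with 18–32 cells; the clinical geometry
(2560×1920 px, ≈170 cells) is reachable through `CohortSpec.image_size`
and `cells_per_image_range`. Determinism is strict: one seeded PCG64
stream drives every draw, so a `(spec, patient_id, seed)` triple is
byte-reproducible.

What the generator does **not** emulate: Romanowsky stain variation between
laboratories, out-of-focus regions, dense cell clumps, dry-tap aspirates,
nucleoli and chromatin texture, faggot cells (rod bundles), and continuous
cytologic spectra between cell types. Consequently, passing tests
demonstrate that the pipeline's machinery is correct and recovers the
generator's parameters; they do not establish clinical performance on real
smears, where the reported metrics would be expected to drop.

## Cell detector

The detector is deliberately small so that training is a matter of seconds
on one CPU, while keeping the two-stage structure of region-proposal
detectors:

1. **Stage 1** classifies every pixel as cell/background from five features
   (RGB, gray, 5×5 local gray standard deviation) with a one-hidden-layer
   dense net (width 8), trained with Adam on up to 3000 sampled pixels per
   class per image. The per-epoch mean training loss is recorded;
   `epochs=0` returns a model flagged untrained.
2. The probability map is thresholded at 0.5, hole-filled, and split into
   candidates by a distance-transform watershed (marker separation 9 px,
   minimum area 40 px²). Each candidate gets a subpixel ellipse by image
   moments: for a uniformly filled ellipse the covariance eigenvalues are
   r²/4, so semi-axes are twice the singular values. The detection box is
   the tight box of that ellipse.
3. **Stage 2** scores each candidate with a second small net over ten
   shape/appearance features (log area, fill fraction, aspect, mean RGB,
   gray spread and minimum, normalized extent). Positives are candidates
   matching a reference region at IoU ≥ 0.5; negatives are unmatched
   candidates plus random background boxes. Its probability is the
   detection confidence.

Proposals below the score threshold (default 0.5) are dropped, then greedy
confidence-ordered NMS at IoU 0.5 (ties broken by lower region id — all
orderings in the package break ties this way for reproducibility) and
clipping to image bounds. Matching/NMS operate on axis-aligned boxes;
ellipses are a refinement layered on top, since standard mAP/mAR is defined
on boxes.

`refine_ellipse` re-fits the ellipse from pixels far from the background
color (Euclidean RGB distance > 25 of 255) inside a 1.25×-expanded box,
keeping the component nearest the region center; if no foreground pixel is
found the input region is returned unchanged, and the refined box is
clipped so it can never leave the expanded box.

The human-in-the-loop round mirrors iterative annotation: proposals
overlapping a reference region at IoU ≥ `iou_accept` are kept, everything
else is replaced by the reference region (an untrained model therefore
yields exactly the reference set), and the detector is retrained on the
corrected annotations.

Crops are aspect-preserving: the box content is scaled so its longer side
fits the crop (default 299 px at the cell-classification interface, 64 px
in the desk-scale pipeline) and padded with the median image color;
border regions are padded, never read out of bounds.

## Per-cell classifiers

Three binary classifiers score each crop independently — myeloblast,
promyelocyte, Auer rod — giving the multi-label encoding in which a
rod-bearing promyelocyte is (0, 1, 1). No mutual exclusion is imposed at
prediction time.

Each classifier is a fixed feature extractor feeding a configurable fully
connected head. The extractor concatenates a 12×12 RGB thumbnail (coarse
shape and color), per-channel intensity percentiles 1–99 (low percentiles
are what make a 2-px-wide dark rod visible at all), per-channel spread,
gradient-magnitude statistics (granule texture) and dark-pixel fractions
(nucleus size) — 467 features. The head has 1–3 dense layers (default 2,
widths 32/16) with dropout and a sigmoid unit, trained with Adam on binary
cross-entropy (default 120 epochs, batch 64, lr 0.01). The dropout
defaults for the two diagnosis tasks' upstream heads are the
hyperparameter-search values 0.32 (APL-vs-healthy) and 0.46 (APL-vs-AML);
their assignment to specific models is ambiguous in the source material,
so both are exposed as plain config values. Class imbalance (rod-bearing
cells are rare outside APL) is handled by upsampling minority classes with
augmented copies before training.

Morphometrics: size = foreground pixel count; volume proxy =
(4/3)·√π·size^1.5 (sphere-equivalent from the projected area); contrast =
RMS deviation of foreground luminance. With no usable mask the foreground
is estimated by distance from the median (background) color, falling back
to the whole crop. Whether morphometrics feed the smear classifier is a
config flag (`use_morphometrics`), default off: the smear-level features
are defined as the three ratios, and the extra inputs are not needed on
synthetic data.

## Smear-level ensemble

Per-cell probabilities become hard calls at threshold 0.5 (configurable;
the ROC/PR evaluation is threshold-free, so headline metrics do not depend
on it), and the smear feature vector is the triple of call ratios with
denominator = detected cell count. An image with zero detected cells
raises an explicit no-cells error and is reported "unanalyzable" rather
than scored. The ENN is exactly one affine map plus sigmoid — no hidden
layers, no dropout, n_features + 1 parameters — trained per task
(APL-vs-healthy, APL-vs-AML) with Adam. Feature aggregation is
permutation-invariant in the cell order by construction.

## Evaluation protocol

- **IoU** on half-open boxes; degenerate zero-area boxes score 0 by
  convention (logged).
- **Matching** is greedy in descending confidence, each ground-truth region
  claimed at most once.
- **AP** is the area under the all-point-interpolated precision/recall
  curve of the confidence-ranked detections pooled over the dataset; **AR**
  is the maximal recall attained. Both are averaged over IoU thresholds
  0.50:0.05:0.95 (ten thresholds; a single-element sweep {0.5} reproduces
  the @0.5 metrics). The interpolation convention is pinned by a
  brute-force threshold-sweep oracle in the tests.
- **ROC AUC** follows the rank/trapezoidal convention (ties count ½),
  verified exhaustively against the concordant-pair definition on small
  instances; **PR AUC** is the area under the precision-recall step curve
  over all thresholds (all-ties input yields the class prevalence). Both
  are undefined (error) for single-class inputs.
- **Cross-validation** is threefold at the patient level: patients are
  shuffled within each diagnosis and dealt round-robin, so folds are
  class-stratified within one patient and each fold trains on 2/3 and
  tests on 1/3 of patients. Records keep their patient id through
  augmentation, so augmented copies can never cross the split. Macro
  metrics are the arithmetic mean over folds; dispersion is the
  (population) standard deviation of fold values.

In `run_pipeline`, the detector is trained once on a dedicated annotated
synthetic set generated independently of the diagnosis cohort — the
analogue of a pre-existing expert-annotated segmentation corpus — so
detector training never sees cross-validation data; held-out images from
that set provide the report's mAP/mAR. Cell classifiers and the ENN are
retrained per fold on training-fold patients only. Crops enter classifier
training with the labels of the best-overlapping ground-truth region
(IoU ≥ 0.5), unmatched detections as "other"; a training fold with a
single-class target (e.g. no detected rod-bearing cell) keeps an untrained
chance-level head instead of aborting the run.

## Occlusion maps

A patch (default 32 px, stride 16 at desk scale) is replaced by the median
background color (configurable gray/black) and the smear-level probability
is recomputed; importance = baseline − occluded score, on a grid of
floor((H − patch)/stride)+1 × floor((W − patch)/stride)+1 cells. Rendering
min-max normalizes the grid (an all-equal map renders uniformly at
mid-scale, so scalar rescalings render identically) under a
perceptually ordered colormap alpha-blended onto the image.

## Hyperparameter optimization

A seeded random search over declared per-parameter choices/ranges with a
fixed trial budget, plus an exhaustive mode for finite grids; the full
trial log is returned and the argmax over evaluated configs wins. A
sampling-based strategy was chosen over adaptive optimizers because it is
reproducible from a single seed and adequate at the package's scale; the
strategy is pluggable behind the same interface.

## Numerical and degenerate-input conventions

- All learnable components are small dense nets trained with Adam
  (β₁ = 0.9, β₂ = 0.999) from seeded He-scaled initializations; features
  are standardized with training-set statistics. Single-threaded runs are
  bit-reproducible; tests assert equality to 1e-6.
- Sigmoid logits are clipped to ±35 before exponentiation.
- Ellipse rotation is radians, counter-clockwise in image coordinates,
  converted only at file boundaries; boxes are 0-based half-open,
  origin top-left, x = column.
- Seeds are combined through `numpy.random.SeedSequence` streams (always
  reduced below 2³¹), so sub-protocols have independent reproducible
  streams derived from one run seed.

## Problem sizes

Default problem sizes were chosen so any experiment runs on a single CPU
core in minutes: 512×384 px smears with ~25 cells, 17 patients per cohort
with 3 images each (51 smears per class) for the cross-validated
benchmarks, 60-smear splits (40 train / 20 test) for detection, and
400/200 balanced crop splits for the per-cell classifiers. All are
configuration values, not architectural limits.

## Known limitations

- Synthetic appearance is schematic; none of the reported synthetic
  metrics transfer to clinical data without retraining and revalidation.
- The detector resolves touching cells by watershed only; heavily
  overlapped clusters are out of scope and will merge or fragment.
- Confidence intervals for AUCs are not computed; fold standard deviations
  are reported instead.
- No faggot-cell (rod-bundle) class: the generator does not render
  bundles, and the classifier set stops at the three labels that feed the
  smear-level ratios.
- The ENN scores individual images; patient-level aggregation of multiple
  images per patient is macro-averaged through the fold metrics rather
  than modeled explicitly.
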