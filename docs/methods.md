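# Methods

## Pixel-classification model

Segmentation is framed as supervised per-pixel classification into four
classes: 1 = dentine disc, 2 = pre-osteoclast, 3 = resorption pit,
4 = osteoclast. The classifier is a random forest (scikit-learn,
100 trees, gini impurity, unlimited depth, √F candidate features per split,
fixed `random_state`) trained only on the pixels covered by brushstroke
annotations — sparse supervision, never whole images. Class imbalance is
left as annotated; how many pixels each class receives is a property of the
supervision, not rebalanced internally.

Each pixel's feature vector stacks six filter groups at seven smoothing
scales σ ∈ {0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0} pixels on each of the three
colour channels (168 features):

| group | components | filter |
|---|---|---|
| smoothed_colour | 1 | Gaussian at σ |
| gradient_magnitude | 1 | ‖(∂y, ∂x) Gaussian at σ‖ |
| laplacian | 1 | ∂yy + ∂xx at σ |
| difference_of_gaussians | 1 | Gaussian(0.66 σ) − Gaussian(σ) |
| structure_tensor_eigenvalues | 2 | gradients at σ/2, tensor averaged at σ |
| hessian_eigenvalues | 2 | second derivatives at σ |

Colour features are computed on raw RGB per channel (a `luminance` policy
exists but is not the default): the discrimination between TRAP-purple cells
and tan pits is chromatic, and decorrelating the colour space would buy
little. Eigenvalues are sorted descending within each pixel, and all filters
use mirror-reflection boundaries; together these make the entire bank
equivariant under multiples of 90° rotation up to floating-point rounding,
which is what makes downstream counts orientation-independent. Derivative
kernels are built explicitly with the truncated-kernel DC leakage removed
(the second-order kernel is re-centred to sum exactly to zero), so constant
images produce exactly zero edge/texture response; σ = 0.3 yields a minimal
3-tap kernel rather than being skipped, keeping F uniform across scales.
Features are raw filter responses; standardisation (per-feature z-score
using training-pixel statistics, constant features given unit scale) happens
inside the classifier so that a saved model carries everything needed to
reproduce its predictions.

Probabilities are the forest's vote fractions; the segmentation is the
per-pixel argmax with ties broken toward the lowest class id. The tie-break
is deliberately documented and stable: determinism plus feature equivariance
give identical osteoclast counts at 0°, 90°, 180° and 270°, and identical
results on repeated analysis of the same file — the mechanism behind the
method's ~0% repeat-analysis CV against a manual intra-operator CV above 20%.

Models persist as a single zip archive holding the forest blob and a JSON
manifest (format version, seed, per-class training-pixel counts, feature
configuration, class table). Loading verifies the format version and fails
cleanly on truncated files.

## Quantification

Osteoclast number is the count of connected components of class 4 with area
≥ 825 µm². Choices worth stating:

- **Connectivity 8** by default: irregular cell outlines fragment under
  4-connectivity. Configurable.
- **Inclusive threshold** (≥ 825 µm²): "minimum size" is read as the smallest
  admissible value. At the default 2.031 µm/px calibration the boundary falls
  between 200 pixels (824.99 µm², excluded) and 201 pixels (829.12 µm²,
  retained).
- The threshold is applied in **µm², not pixels**, so the same 825 µm²
  applies across magnifications.
- **Border objects are retained**: fields of view clip cells, and excluding
  them would systematically undercount.
- **No morphological cleanup** precedes counting; the size filter alone
  absorbs speckle noise.

Areas are exact pixel tallies times the squared calibration; the four class
areas always partition the image area. The CSV export prints six significant
digits, `.` decimal separator, comma delimiter, locale-independent.

## Manual comparator and statistics

Dot-counting morphometry overlays a uniform rows × cols lattice (default
12 × 16) with points at cell centres — centre placement keeps all points
strictly inside the image, which corner placement would not. Each point
stands for 0.034 mm² of dentine surface by default; the value is an explicit
parameter rather than derived from the nominal 19.2 mm² disc area divided by
576 points (= 0.0333 mm²), because 0.034 is the conventionally used constant
— the small discrepancy is inherited, not reconciled. CVs use the sample
(n−1) standard deviation: with 2–3 repeats per item that is the defensible
estimator. Pearson r, the regression line and its p-value come from the
standard least-squares machinery; p-values are reported but never gated on.

## Synthetic scenes

The generator renders what the pipeline needs to be tested against, with
exact ground truth:

- **Geometry.** Osteoclasts are star-convex polygons with strong radial
  perturbation (±35%), pre-osteoclasts near-circular (±8%), pits moderately
  irregular blobs placed tangent to a parent osteoclast and written only over
  dentine, so they wrap against the cell boundary — reproducing the
  pit/dentine ambiguity regime. Objects are placed by rejection sampling,
  largest first, with an 8-pixel clearance between cells so that the
  ground-truth count is well defined; a packing that cannot be realised
  within the retry budget raises an error rather than degrading silently.
- **Sizes.** Osteoclasts default to 900–20 000 µm² (above the 825 µm²
  maturity threshold), pre-osteoclasts to 80–500 µm² (below it), pits to
  500–4 000 µm², at 2.031 µm/px on a 320 × 320 px field. Defaults give
  8 osteoclasts, 12 pre-osteoclasts and 5 pits per field — a moderately
  dense culture.
- **Colour.** Dentine (235, 231, 226), osteoclast purple (128, 72, 148),
  pre-osteoclast pink-magenta (190, 70, 200), pit tan (205, 172, 128), with
  per-object jitter (±8), pixel noise (σ = 4) and low-amplitude smoothed
  background texture (±6) standing in for dentine surface heterogeneity.
  The palette is a plausibility choice — no published intensity statistics
  exist for these classes — constrained by two rules: all four means are
  pairwise separated by at least the configurable margin (default 40), and
  no class mean may sit near the mixing line of another class pair, since
  boundary pixels are blends and must not alias a third class. The
  pink-magenta precursor tone satisfies the second rule (TRAP staining is
  pink-to-purple, and mononuclear precursors carry less stain).
- **Uneven staining.** `staining_uniformity` < 1 bleaches osteoclast
  interiors toward the dentine colour with a plateau-shaped profile
  ((d/d_max)^0.3 of the interior distance transform): the cell body pales
  while only a faint rim stays purple, which is how weakly stained very
  large cells actually defeat segmentation. At uniformity ≤ 0.4 recovered
  counts drop below truth on paired seeds — the documented real-world
  failure mode, reproduced rather than engineered around.
- **Annotations.** Brushstrokes are random walks confined to each class
  region eroded by one pixel (boundary-mixed pixels are not supervision),
  with an independent seed so one scene can carry different supervision.
  Non-zero labels agree with ground truth by construction.

What passing on synthetic scenes shows: the feature bank, forest training,
segmentation, component analysis, thresholding, unit conversion and the
statistics are correct and deterministic, and the pipeline's failure modes
move in the right direction under degraded staining. What it does not show:
performance on real micrographs — real cultures have touching cells,
illumination gradients, debris, and pre-osteoclasts that are chromatically
almost identical to osteoclasts (here they are deliberately separable), and
real resorption pits lack crisp boundaries. The published experience — good
osteoclast counts, unreliable pit segmentation, ~25% systematic count offset
against manual observers — should be expected to reappear on real data.

## Problem sizes and numerical choices

Tests and the acceptance script run on 320 × 320 px scenes (~0.65 × 0.65 mm
fields), 3 training scenes with ≤ 200 annotated pixels per class per scene,
and 100-tree forests — sizes chosen so the full suite completes in minutes
on one core while every pipeline stage is exercised end to end. Probability
normalisation is checked to 1e-6; feature equivariance to 1e-6 absolute;
area identities are exact in pixel counts. Degenerate inputs fail loudly:
zero-area images, unknown class ids, scales exceeding half the image,
classes without annotations, non-positive CV means, zero-variance
correlation inputs and unplaceable scenes all raise typed errors.

## Known limitations

Counting merges touching osteoclasts; multinucleation is not assessed;
resorption areas are reported but inherit the pit-boundary ambiguity;
8-bit RGB input only. The HDF5 layout (single gzip `data` dataset, y-x-c,
calibration as an attribute) is this package's own dialect —
interoperability with other tools' project files is not promised.
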