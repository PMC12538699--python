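# Methods

This note documents the statistical models, conventions and numerical
choices behind `topoqc`, in the order the pipeline runs them.

## Chip model and tile naming

A chip is an `n_rows × n_cols` grid (66 × 66 by default) in which every
topography design occupies exactly two TopoUnits and `flat_count` units
(default 4) carry a flat control surface. The flat units double as the
orientation landmark and are placed in the lower-right corner block;
their positions are configurable. Duplicate placement is a stated
convention, not a reconstruction: the non-flat positions are ordered by
(column, row) and split into two equal halves, and each design receives one
seeded-random position in each half. This guarantees spatially separated
replicates and is arity-exact for any grid (a strict column-midline split
is not, once the flat corner block removes four positions from one side).

Tile filenames follow the grammar
`[Channel]_[ChipID]_Col[C]_Row[R]_Seq[S]_[Stain].tif` with 1-based indices.
Numeric field widths are not part of the grammar; the writer defaults to
zero-padding columns/rows to 2 digits and the sequence number to 4 (so
lexicographic order equals grid order), while the parser accepts any width
and records the observed widths, making parse → format an exact identity.
The sequence number is the row-major acquisition index
`(row − 1) · n_cols + col`; it is stored but never trusted for geometry.
All internal arrays are 0-based with a top-left origin; the 1-based
convention is confined to the parse/format pair.

## Synthetic screen: what it emulates

The generator reproduces the statistical structure of the reference
screen — 9 usable chips of 66 × 66 units, 2176 designs in duplicate —
so that every downstream stage can be exercised and calibrated offline.

**Cell counts.** Each chip belongs to one of two density classes: 6 chips
at 39 ± 13 cells/unit and 3 chips ("chip4", "chip7", "chip8") at
15 ± 11. Per-unit counts are rounded normal draws floored at 1; the count
distribution is not otherwise constrained. A per-design count offset
(shared by a design's replicate units, SD = half the smaller class SD) is
nested inside the class SD so the marginal spread stays at the class value.

**Nuclear area.** Single-cell nuclear area is
`A = μ + b_unit + e`, with `μ = 737 px²`, `e ~ N(0, σ_w²)` per cell and
`b_unit ~ N(0, σ_b²)` shared within a unit. The between-unit component is
itself split: `b_unit = design_offset + unit_offset`, where the design
offset (SD `σ_b/2` by default, i.e. a quarter of the between-unit variance)
is shared by a design's replicates and gives the replicate-consistency
filter a real signal to preserve. The split `(σ_b, σ_w)` is solved at
configuration time from two calibration targets:

    σ_b² + σ_w²          = σ_total²        (single-cell SD, 161)
    σ_b² + σ_w² · E[1/n] = unit_mean_sd²   (SD of per-unit means, 65)

`E[1/n]` is computed exactly from the count model (probability mass of the
floored rounded normal, mixed over the two chip classes). Using `E[1/n]`
rather than `1/n̄` matters: with the low-density chip class,
`E[1/n] ≈ 0.085` while `1/n̄ ≈ 0.032`, and the naive solution would
inflate the measured unit-mean SD to ~74. An unsatisfiable configuration
(`unit_mean_sd²` below the sampling floor `σ_total² · E[1/n]`) is rejected
at construction with the computed σ_b². A log-normal tail mixture for the
right-skew seen in real single-cell area histograms is available
(`lognormal_tail_weight`, default 0 — the Gaussian default keeps the
decomposition exact).

**Correlated features.** DAPI and phalloidin mean intensities are bivariate
normal with Pearson r = 0.83; solidity and peripheral actin fraction with
r = −0.87. Marginals are normal, clipped to the valid domains
(solidity ∈ (0, 1], fraction ∈ [0, 1]); means and SDs are chosen so
clipping is rare and the sample Pearson r stays within ±0.02 of target.
Focus score is an abstract unitless score, N(1, 0.05²) per unit (no
concrete focus metric is modeled; the real pipeline's metric is
implementation-defined in its segmentation software).

**Planted artifacts.** `plant_artifacts` corrupts
`⌊rate × total_units⌋` distinct non-flat units per unit-level kind
(underpopulated: cells dropped to a count below the band; overpopulated:
cells resampled with replacement above it; out-of-focus: focus score
shifted down 0.5; NtoC-extreme: cell area rewritten to put the unit's mean
NtoC in the far high or low tail, alternating), and
`⌊rate × n_designs⌋` designs get one replicate position shifted by 3 pooled
SDs of nuclear area. Selections are disjoint within and across calls
(corruption is idempotent per unit) and every corruption is recorded in a
truth registry, against which the QC tiers' recall is measured.

**Toy images.** Stitched-chip rendering draws bright 1-px walls, a faint
periodic pillar texture in non-flat units (flat units stay texture-free so
the landmark is detectable), and one ellipse per cell at a seeded position,
returning the image with a ground-truth label mask. Z-stacks blur a base
plane with a per-plane Gaussian radius (radius 0 = the in-focus plane)
plus seeded noise. These are structural stand-ins for testing the image
ops, not photorealistic microscopy: no pillar-level geometry, illumination
falloff, or stain-specific texture is modeled, so passing image tests
demonstrates the bookkeeping (cropping, naming, orientation, projection),
not segmentation performance on real data.

## Image operations

* **Projection**: `max` is the pixelwise maximum; `average` is the
  arithmetic mean, rounded half-up on integer dtypes. A single-plane stack
  is the identity under both.
* **Orientation**: each rotation in {0°, 90°, 180°, 270°} is scored by the
  median interior texture variance at the layout's flat positions (walls
  are trimmed from each tile before the variance; the median tolerates a
  cell sitting in one flat unit). The winning rotation must beat the
  runner-up by a margin (default: winner < 0.7 × runner-up), otherwise the
  result is flagged ambiguous and the image is returned unrotated with a
  score report. The detector is pluggable.
* **Tilt map**: bilinear interpolation of four corner focus heights over
  unit centers; corners are reproduced exactly and all values stay within
  the corner range. Diagnostic only — no warping is applied.
* **Cropping**: strict divisibility of the image by the grid is required
  (the error suggests the padding that would fix it); this buys a
  bit-exact crop/reassemble round trip, in place of an unspecified manual
  alignment step.

## Derived features and aggregation

Form factor is `4πA/P²` (1 for a circle; on rasterized masks values can
exceed 1 and are reported as computed, flagged, never clamped). NtoC is
`A_nuc / (A_cell − A_nuc)` — the "surrounding cytoplasm" denominator, fixed
by the convention that NtoC = 1 means nucleus and cytoplasm occupy equal
areas; mis-segmentations with `A_cell ≤ A_nuc` yield a NaN sentinel rather
than an exception, because catching them is the NtoC filter's job.
Peripheral actin fraction is the outermost of 4 radial bins over their sum.

Unit aggregation produces count, mean and SD (n−1 denominator throughout,
including the CV curves) per feature, with sentinel values excluded from
means and counted per feature. CV-vs-count curves take SD/mean of a
unit-level feature across all units sharing a cell count, for counts with
at least `min_units` units (bins with zero mean are excluded); they use
unit-level means, not pooled single cells.

## QC tiers and conventions

* Quantiles/percentiles use linear interpolation between order statistics
  (numpy's default, the "type 7" rule); the convention is switchable in
  principle but fixed as the package default.
* Object filter: nucleus diameter band **inclusive** `[15, 65]` px; border
  and wall contact remove the whole cell record (linkage rule). The
  removal log names each cell's first failing rule.
* Count filter, two supported configurations reflecting two published
  accountings of the same screen: IQR bounds (k = 1.5 default, exposed) on
  cell count and focus score, or the fixed stability band retaining
  `[11, 64]` cells. The band can also be derived from CV curves: the
  contiguous count interval free of counts whose CV exceeds
  `ceiling × (curve minimum)`, with the fixed band as fallback. The ledger
  records which configuration ran; the two accountings are alternative tier
  configurations, not one pipeline.
* NtoC filter: thresholds at the 2.5th/97.5th percentiles of the supplied
  units' mean NtoC, frozen at fit; units strictly outside are removed, and
  sentinel-valued units are always removed and counted separately. Because
  thresholds are frozen (not re-estimated on the filter's own output),
  re-application never cascades removals.
* The ledger chains image and object counts independently through the
  tiers, rejecting any tier that would overdraw the running totals.

## Replicate-consistency filter

The k-sample Anderson–Darling statistic is the Scholz–Stephens midrank
(tie-corrected) version with their variance normalization. The p-value
interpolates log(α) quadratically through the tabulated critical values
`tₘ(α) = b₀ + b₁/√m + b₂/m` (α ∈ {0.25, 0.10, 0.05, 0.025, 0.01},
m = k − 1); beyond the largest critical value the interpolant is clamped at
its minimum so p stays monotone in the statistic, and p is clipped to
[10⁻⁴, 1]. A seeded permutation p-value — exhaustive enumeration when the
two-sample assignment count permits — serves as the reference oracle.
For two samples of size 4 (70 assignments) the approximation tracks the
exact p within ±0.05 throughout the decision region (exact p ≤ 0.2); near
p ≈ 0.5 the 70-atom permutation distribution is too coarse for that bound
and deviations up to ~0.12 occur, which does not affect retain/remove
decisions at the 0.05 band edge.

Replicate grouping (default): a design's two duplicate positions, each
pooling its cell-level values across chips (k = 2 groups); a unit-level
mode (per-chip unit means per position) is also provided and the mode is
recorded in the report. Acceptance bands: retain iff AD p > 0.05
(strictly) **and** 2 < SNR < 20, evaluated in parallel on the full design
set with the union removed; per-criterion counts and the union are
reported. The SNR upper bound flags suspiciously noise-free surfaces and
is a documented screen convention without a stated biological rationale.
Designs with a single replicate group are flagged untestable rather than
silently retained or removed. Degenerate groups (all pooled values equal)
are treated as maximally consistent for AD (p = 1) and left to the SNR arm,
which removes them via the +∞ sentinel.

Note a property of the generator's variance model: even "null" designs
carry unit-level offsets (SD ≈ 0.75·σ_b), so their two replicate
distributions differ slightly and the AD arm removes substantially more
than α of them at cell-level grouping — consistent with the large removal
fractions observed in real screens, and distinct from the i.i.d. null under
which the filter's type-I error is verified.

## Ranking and splitting

Top/bottom-N binarization (N = 90 per class by default) with a stable tie
rule by design id. The nested stratified split holds out
round-half-up(0.2 n), then round-half-up(0.2 · holdout) of that as
validation — nominal 0.80/0.16/0.04, e.g. (144, 29, 7) for 180 designs —
stratified at every step and deterministic under seed. Descriptor matrices
are z-scored with statistics fitted on the **training subset only** and
applied to all subsets; this deliberately deviates from the reference
screen's standardize-before-split order to avoid leakage, and a `global`
scope reproduces the original convention. Zero-variance descriptors are
dropped and recorded. The gradient-boosting stage itself is out of scope;
its tuned hyperparameters ship as a YAML fixture
(`topoqc/data/lightgbm_params.yaml`).

## Problem sizes used in the test suite

The calibration checks run on one full-scale default screen (9 chips,
39,204 units, ~1.2 M cells; generated once per session in seconds).
Artifact-recall checks use one full-size chip with rates ≤ 5 %; the
type-I simulation uses 600 i.i.d. designs; structural tests use reduced
geometries (3 chips, 16 × 16 grid, 126 designs) that keep the full
statistical structure.

## Known limitations

* The synthetic generator is Gaussian by default; the right-skew of real
  single-cell area distributions is available only as an opt-in tail
  mixture, and its effect on IQR/percentile thresholds is not
  characterized.
* The focus score is abstract; conclusions about real out-of-focus
  detection do not transfer.
* Table-style replicate-removal counts from the real screen depend on the
  deposited data and on grouping conventions left open there; the package
  verifies distributional properties (type-I error, recall on planted
  inconsistencies, oracle agreement) instead of reproducing those counts.
* Orientation detection assumes flat units are the lowest-texture units;
  heavily confluent flat units could defeat the default detector (it is
  pluggable for that reason).
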