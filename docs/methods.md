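# Methods

## Imaging model

Brightfield chromogens attenuate light multiplicatively, so stain
contributions are linear in optical density: for illumination `I0` (255
for 8-bit data) a pixel's OD per channel is
`OD_c = −log10((pixel_c + ε)/(I0 + ε))` with `ε = 1/255` guarding
`log 0`.  Adding `ε` to both numerator and denominator keeps OD exactly 0
at full transmittance and non-negative below it, while staying within the
ε-induced tolerance of the plain ratio.  A two-stain image is unmixed per
pixel by unconstrained least squares onto the two stain OD vectors;
negative coefficients are clipped to zero and the OD mass the clipped fit
leaves unexplained (including any out-of-plane component) is reported as a
per-pixel residual.  Unmixing refuses stain matrices with condition number
above 1e4.

Default stain vectors (unit OD vectors, always overridable): Iba1/purple
`(0.40, 0.80, 0.45)` normalised — a green-absorbing alkaline-phosphatase
type chromogen — and Pu.1/brown the classical Ruifrok–Johnston DAB vector
`(0.27, 0.57, 0.78)` normalised.  Stain vectors are chromogen- and
scanner-dependent; on real material they should be calibrated from
single-stain controls.

Thresholding is a single global threshold per image, Otsu by default
(the original analysis used an unpublished fixed "minimum threshold";
fixed values are supported for reproducibility).  The mask is strictly
`map > t`, which makes thresholding monotone in `t`.

## Segmentation

Nuclei are 8-connected components of the Pu.1 mask, size-filtered to
[10, 400] µm² by default (a 3.5-µm-radius nucleus is ~38 µm²); ids follow
raster order of each component's first pixel.  8-connectivity is used for
both stains so that 1-px-wide diagonal process segments remain contiguous.

The attribution rule: an 8-connected Iba1 component is cell-associated iff
its minimum Euclidean distance (exact distance transform, scale-aware,
inclusive) to some nucleus pixel is ≤ 2.0 µm.  Components qualifying for
one nucleus are assigned wholly to it.  Components qualifying for several
nuclei are partitioned by within-component hop-count (8-neighbour geodesic)
distance to the nearest qualifying nucleus's seed pixels, ties to the lower
nucleus id; this avoids double counting, which also guarantees the
partition identity (cell masks ⊎ non-process = Iba1 mask) that is asserted
pixel-exactly in the tests.  Whether the original instrument assigned
shared components to one cell, both, or split them is unknowable from its
published description; the geodesic partition is this package's choice.

## Morphometry

Areas are pixel counts × mpp².  Per region: nuclei per mm²; total Iba1
area (non-process included) ÷ nucleus count; and means over cells of the
nucleus-attached process area and perimeter.  "Total Iba1 area per
nucleus" is deliberately region-total over count — it is reported
alongside, and is never smaller than, the nucleus-attached process area.
Per-nucleus metrics are NaN when a region has no nuclei.

Perimeter uses a Cauchy–Crofton line-intercept estimator: foreground runs
are counted along digital lines in each sampled direction (one run = two
boundary crossings) and combined with the line spacing and the angular
sector each direction represents.  The classical 4-direction variant
{0°, 45°, 90°, 135°} carries an intrinsic ≈−5.2% bias on axis-aligned
rectangles (π × the mean projection width of a square over those four
directions is 3.79a, not 4a), so the default adds the four knight-move
directions (±1,±2): measured bias is ≈−3.7% on a 20-px square and ≈−0.9%
on an r=20-px disc, both within the 5% the validation demands.  The
4-direction variant and a naive exposed-edge count (exact on rectilinear
shapes, +27% on discs) remain available for sensitivity analysis.  Like
all intercept estimators it underestimates structures ~1 px wide; the
generator's default processes are ≥ 3 px wide at 0.5 µm/px.

## Statistics

The unit of analysis is one animal × region.  Each metric is fit as a
full-factorial OLS with interaction; F tests use Type-III sums of squares
with sum-to-zero contrasts, matching the commercial software family these
figures are usually made with and coinciding with the classical
decomposition on balanced designs (asserted in the tests).  Degrees of
freedom are checked against the identity `df_A + df_B + df_AB + df_resid
= N − 1` on every fit.  Empty design cells are an error under Type III;
zero residual variance yields NaN F/p with a warning rather than a crash.
Genders are pooled by default; `combine_factors` builds the 4-level
genotype × gender factor for the stratified design (df 3 over 28 at
N = 36).  Tukey HSD uses the studentized range over all group pairs with
pooled within-group variance; with two groups it reduces to the pooled
t-test (tested against scipy).  Stars are strict: `*` < 0.05, `**` < 0.01,
`***` < 0.001, `****` < 0.0001.

## Omics filters

BH adjustment is the step-up `adj_(i) = min_{j≥i} p_(j)·m/j` capped at 1
(statsmodels `fdr_bh` behind the package surface; the tests compare it to
a literal reimplementation).  The DEG rule is strict on expression
("greater than 4 TPM"), strict on FDR (< 0.05), and symmetric on the
ratio scale for the 30% fold-change criterion (≥ 1.3 or ≤ 1/1.3); the
linear reading (≤ 0.7) is a config switch.  The 4-TPM average is taken
over the samples of the comparison at hand.  Top-k lists sort ascending by
p with gene-id tie-breaks; unions preserve first-seen order.  ChIP peaks
are retained when |TSS distance| ≤ 1000 bp (inclusive; negative =
upstream) and some genotype has ≥ 4 reads; significance additionally needs
a 2-fold change in either direction and IDR < 0.05.  qPCR expression is
`2^−(Ct_gene − Ct_ref)` per sample, divided by the mean over the reference
(WT) group, whose mean is therefore exactly 1.  All filters are idempotent.

## Synthetic data

The generator emulates the structure the pipeline relies on, not the
appearance of real tissue.  Each ramified cell is a soma disc (5 µm
radius) containing a nuclear disc (3.5 µm); 4 primary processes per cell
leave the soma rim at jittered regular angles as random-walk polylines
(segment ≈ 4 µm, heading SD 0.3 rad, ~50% of processes carry one side
branch), arc length uniform in 10–22 µm, stroke thickness 2 µm.  The
amoeboid (cerebellar) variant fuses three jittered soma discs and halves
process count at 0.3× length and 1.5× thickness.  Geometry is continuous;
masks are pixel-centre membership, so recorded areas are exact pixel
counts × mpp² and an independent recount reproduces them bit-for-bit.
Process paths reflect off the image border: a clipped path would render as
a disconnected fragment no contiguity rule could attribute.  Somas are
placed by rejection sampling with ≥ 60 µm centre separation (bounded
retries, then the cell is dropped and the ground truth reflects actual
placements), which keeps arbors of distinct cells disjoint at the default
process lengths — the regime in which per-cell recovery is testable
pixel-for-pixel.  Fields are 256×256 px at 0.5 µm/px (a typical 20×
whole-slide scan scale; the instrument's true scale is not published),
4 cells per field.

Rendering places stain concentrations (0.8 OD Iba1, 0.9 OD Pu.1 peak) on
the masks, adds a neutral 0.05 OD background, optional Gaussian OD noise
(default SD 0.02), and inverts Beer–Lambert to 8-bit RGB.  Everything is a
pure function of (params, seed): the geometry and noise streams are
spawned separately from the seed so ground-truth-only generation is
identical to rendered generation.

Cohorts are factorial (genotype × age cells, genders rotated within a
cell, about five per gender subgroup at the default n = 9 per cell,
mirroring a typical design of ~5 mice per group); per-factor-level effect
multipliers scale process thickness/length, soma radius or cell count.
With the 0.7 thickness multiplier the soma-exclusive process area scales
by ≈ 0.7 (verified within 5%); the per-cell *total* area the pipeline
measures scales less (the soma is unscaled), which is why the recovery
test asserts detection and direction rather than the raw ratio.

Gene tables: null genes have Uniform(0,1) p and FC = 2^N(0, 0.05); true
DE genes have FC magnitude uniform in 1.5–4 (random direction) and
p = 10^U(−12, −6); TPM is log-normal(2, 1.2), so a realistic fraction of
true DEGs fails the 4-TPM expression floor.  Peak tables use Poisson(12)
reads and ±3 kb TSS distances with 2–6-fold true changes at IDR < 0.04.

## What passing tests do and do not show

The synthetic fields have exactly the two assumed stain vectors, uniform
background, no section artefacts, no overlapping somas and no microglial
clusters; cells are well separated.  Pixel-perfect recovery under these
conditions validates the algorithmic chain (unmixing algebra, contiguity
rule, partition bookkeeping, estimator calibration, test statistics), not
robustness to real-slide variability — stain crosstalk miscalibration,
uneven illumination, touching cells and clustered microglia are explicitly
out of the generator's scope.  The null-calibration result (rejection rate
≈ 0.05 over 200 effect-free cohorts) is computed on ground-truth
morphometrics: it is a property of the ANOVA under the generator's
between-animal variability, independent of the imaging chain.

## Problem sizes

The validation suite uses 256×256-px fields with 4 cells, 20 fields for
segmentation recovery, 36-animal cohorts for the ANOVA structure (images
rendered and fully processed), 200 ground-truth-only cohorts for null
calibration, and 50 × 1000-gene tables for the filter oracles — sizes at
which every property under test is already exercised (shared components,
unbalanced gender counts, borderline DEGs) while the whole suite runs in
about a minute per stage.

## Known limitations

- Global (not adaptive) thresholding only; no cross-slide colour
  normalisation, no whole-slide tiling.
- No watershed splitting of merged Pu.1 nuclei; merged nuclei become one
  cell.
- The shared-component partition is one defensible reading of "contiguous
  within 2 µm"; instruments that double-count would report larger per-cell
  areas.
- Perimeter estimates on sub-2-px-wide structures are biased low.
- DEG/peak p-values are consumed, not computed: there is no
  negative-binomial model or IDR computation here.
- PCA-based outlier removal has no published numeric rule and is not
  implemented.
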