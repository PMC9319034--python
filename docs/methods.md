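# Methods

`dermccm` implements a perceptually grounded color–texture pipeline for
dermoscopic lesion tiles: uniform-color-space colorimetry, two-stage
palette learning, a ΔE-weighted color co-occurrence matrix (CCM) with five
texture statistics, a small multilabel detector of seven dermoscopic
patterns, and the clinical rule that turns pattern detections into a
BCC / non-BCC call. This note records the model, the defaults and the
numerical choices, and what the synthetic test harness does and does not
demonstrate.

## Colorimetry

All perceptual computations run in one of two *uniform* color spaces, in
which Euclidean distance approximates perceived color difference:

* **CIELAB** (L\*, a\*, b\*), with ΔE\*<sub>ab</sub> the Euclidean
  distance;
* **CAM16-UCS** (J′, a′, b′), derived from the CIECAM16 color appearance
  model through the compressions J′ = 1.7J/(1 + 0.007J) and
  M′ = ln(1 + 0.0228M)/0.0228, a′ = M′cos h, b′ = M′sin h, with
  ΔE′ = √(ΔJ′² + Δa′² + Δb′²).

Inputs are gamma-encoded sRGB (consumer dermoscopy cameras emit sRGB and
no camera profile is assumed); the IEC 61966-2-1 piecewise decode is
applied before the linear matrix. The RGB→XYZ matrix is derived from the
sRGB primary chromaticities and balanced so that RGB white maps exactly
to the D65 2° white (95.047, 100, 108.883); XYZ is kept on the 0–100
scale to match CIE worked examples.

CIECAM16 viewing conditions default to D65 white, adapting luminance
L<sub>A</sub> = 64 cd/m², background Y<sub>b</sub> = 20, average
surround — the customary defaults of the color-appearance literature when
the acquisition geometry is unknown. The degree of adaptation defaults to
full discounting (D = 1): with a computed D < 1 the adapted white retains
a residual chroma of ≈ 0.3, so the identities "white → (100, 0, 0)" and
"achromatic ⇒ zero chroma" that the rest of the pipeline relies on hold
exactly only at D = 1. `discount_illuminant=False` restores the
exponential D(L<sub>A</sub>) formula.

Numerical choices: the chromaticity signal *t* is snapped to 0 below
1e-8 — exactly neutral stimuli otherwise retain t ≈ 1e-12 of rounding
noise, which the saturation correlate s = 100√(M/Q) would amplify to
≈ 1e-5. The hue-composition correlate H is computed for completeness but
unused downstream. The full CAM16 inverse is implemented only as a
display helper (palette swatch rendering); round-trip error on in-gamut
colors is below 1e-13.

The published form of the UCS distance contains a duplicated ΔJ′²
term and no Δb′ (resp. ΔM′) term; the standard CAM16-UCS Euclidean
distance over (J′, a′, b′) is implemented, treating the duplication as a
typographical slip — a′ and b′ already encode M′.

## Palette learning and quantization

Stage 1 pools the pixels of all training tiles of one dermoscopic
pattern (optionally subsampled per image, seeded) and runs Euclidean
K-means in the working space: k = 18 centroids per pattern, random-pixel
initialization, 10 restarts keeping the best objective, ≤ 300 iterations,
relative tolerance 1e-6. Cluster weights are pixel counts. With 7
patterns this yields 126 centroids.

Stage 2 merges centroids closer than a ΔE threshold into their
weight-weighted means and auto-adjusts the threshold so that exactly 20
colors remain. Because a pairwise "merge if closer than t" rule is
order-dependent, merging is defined as single-linkage connected
components of the ΔE < t graph, which is order-free and deterministic.
The threshold is found by bisection over [0, max pairwise ΔE] (≤ 60
iterations); if the component count jumps past the target (tied
distances), the largest merged component is split at its farthest
internal pair until the count is exact. Total pixel mass is conserved and
each master color records the union of its source patterns.

Quantization assigns each pixel to the nearest centroid in the working
space (ties to the lowest index). No lesion masking is applied: the
tiles are pattern crops, not whole-lesion images.

## Co-occurrence texture

For an offset set Δ (default: distance 1 at 0°, 45°, 90°, 135°,
symmetric — the classical choice, and closed under 90° rotation so that
averaged features are invariant to the right-angle rotations used in
augmentation), the co-occurrence matrix P is the normalized count of
index pairs at those displacements. The GLCM bins L\* into 32 uniform
bins over [0, 100]; the CCM uses the palette indices directly, giving a
20 × 20 matrix for the default palette.

The five statistics (homogeneity, mean, variance, correlation, entropy;
natural log, 0·ln 0 ≡ 0) replace the integer bin distance |i − j| by the
perceptual ΔE(C_i, C_j) between palette colors. Interpretation choices
where the printed formulas are ambiguous:

* μ is the marginal mean color Σ C_i p_row(i), a working-space 3-vector
  (the matrix mean equals the image mean color); per-index μ_i would be
  dimensionally incompatible with a scalar σ_i.
* σ_i = √(Σ p_row(i) ΔE(C_i, μ_row)²); the variance feature is exactly
  this quantity squared (equal under the symmetric accumulation used by
  default).
* The correlation denominator is σ_i σ_j (the standard co-occurrence
  normalization); the scale-dependent alternative σ_i²σ_j² is available
  via `denominator="sigma_squared_product"`. When σ_i σ_j = 0 (constant
  image) correlation is defined as 0.
* Because ΔE ≥ 0, this "correlation" is a non-negative co-dispersion
  index, not a signed correlation.

Features are computed per direction and averaged into a single record of
seven scalars (homogeneity, mean₁…₃, variance, correlation, entropy).
For the GLCM the mean is scalar and stored in mean₁.

## Pattern detection and the clinical rule

The detector is a small feed-forward network (7 → 32 → 16 → 7, ReLU
hidden units, sigmoid outputs) trained with binary cross-entropy — the
outputs are seven independent probabilities because patterns co-occur.
Features are standardized with training-set statistics stored in the
model; optimization is Adam (minibatch 32, learning rate 5e-3, ≤ 500
epochs) with early stopping on a 15 % validation split (patience 40),
fully deterministic given the seed. Class imbalance is countered by
per-pattern positive weights (odds of the negative class, clipped to
[1, 20]); this is on by default and configurable. The network is
deliberately small: it consumes seven texture scalars, not images, and
serializes losslessly to JSON.

Detections are p ≥ t per pattern (a tie counts as detected), with
t = 0.5 by default or per-pattern thresholds chosen by maximizing
Youden's J on a validation split.

The clinical rule: the seven patterns comprise six positive criteria
(ulceration, blue-gray ovoid nests, multiple blue-gray globules,
maple-leaf areas, spoke-wheel areas, arborizing telangiectasia) and one
negative criterion (pigment network). In **strict** mode a lesion is BCC
iff at least one positive criterion is detected *and* the pigment network
is absent; **permissive** mode ignores the pigment network and calls BCC
on any positive detection. The two modes differ only when a pigment
network co-occurs with a positive pattern; strict is the default because
it matches the textbook criterion ("absence … together with the
presence"). With no detections at all, both modes return non-BCC.

## Metrics

Sensitivity, specificity, accuracy and PPV come from standard confusion
counts; an empty denominator raises instead of silently returning 0,
because a silent zero would corrupt macro averages over rare patterns.
ROC/AUC is the empirical threshold sweep with tie grouping and
trapezoidal area (equivalent to the Mann–Whitney statistic with ties
counted ½). The multilabel report gives per-pattern rows plus unweighted
macro averages.

## Synthetic data and what the tests show

Annotated BCC-pattern tiles come from private hospital collections, so
the test harness generates lesion-like stand-ins: a skin-toned
background (0.87, 0.71, 0.64) with Gaussian channel noise (σ = 0.02,
clipped to [0, 1]) and one simple geometric motif per pattern, drawn
with per-pattern foreground palettes that follow the qualitative
clinical descriptions — brown reticular grid (pigment network),
red/white patch (ulceration), few large blue-gray ellipses (ovoid
nests), many small blue-gray discs (globules), brown lobed polygons near
the border (maple leaf), radiating lines from a hub (spoke wheel), red
branching curves (telangiectasia). Tiles default to 256 × 256, the size
of the clinical pattern crops. Composites superimpose several motifs on
one background and union the labels; benign tiles are motif-free.

Augmentation quadruples a tile set: each image yields its 0°/90°/180°/
270° rotations, each variant independently flipped horizontally and/or
vertically with probability ½ (1371 tiles → 5484). This is the only
reading consistent with a ×4 count; flips are applied after rotations.
No color jitter is applied — color is the diagnostic signal.

The planted-recovery harness trains on 50 tiles per pattern from one
seed and evaluates on a fresh seed, using 64 × 64 tiles and a 1500
pixel-per-image subsampling cap for the palette stage; these problem
sizes keep the full pipeline (palette → CCM features → detector → rule)
at desk scale while leaving the planted structure intact, and the same
pipeline runs unchanged at 256 × 256. Observed performance (macro AUC
> 0.98, binary sensitivity/specificity ≥ 0.93 across seeds) demonstrates
that the machinery recovers *planted* color–texture structure; it says
nothing about performance on real dermoscopy, where pattern geometry,
illumination and inter-patient variation are far richer than the
generator emulates.

## Known limitations

* The detector operates on seven texture scalars; it is a desk-scale
  stand-in for image-level models and the defined plug-in point for
  them, not a clinical classifier.
* The CAM16 inverse is used only for display; out-of-gamut centroids are
  clipped into sRGB.
* Single-linkage merging can chain perceptually distant colors through
  intermediates when the centroid cloud is dense; the exact-count split
  rule bounds, but does not eliminate, this effect.
* The generator's motifs are geometric idealizations; hair, rulers,
  vignetting, specular highlights and acquisition variation are absent.
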