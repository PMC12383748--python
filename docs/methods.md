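# Methods

## Scope and assumptions

`imginfo` quantifies the information content of a set of co-registered
2-D multi-channel images through a patch-level feature representation. Three
assumptions are made explicit and enforced rather than silently handled:

1. **Registration is a precondition.** Paired modalities must already be
   aligned; the package verifies equal pixel dimensions and refuses
   mismatches. No warping or resampling is ever applied, because
   interpolation changes texture statistics.
2. **Intensities are finite, non-negative, 8- or 16-bit.** Float inputs are
   accepted in memory but files are read/written at their stored unsigned
   integer depth.
3. **Patches are the sampling unit.** All markers are statistics of the
   patches-by-features table; images contribute exactly `rows × cols`
   observations each, in row-major grid order.

## Patch grid

Default 10×10 (100 patches per image), configurable. Patch size is
`floor(H/rows) × floor(W/cols)`; a non-divisible remainder is cropped at the
right/bottom edge and recorded (`crop_offset`). Cropping was chosen over
resizing so that no interpolation artifacts enter the texture features; the
discarded strip is at most `rows−1` / `cols−1` pixels.

## Native feature extractors

Per channel, concatenated with channel-prefixed names:

- **First-order (11 features):** mean, population variance, population
  skewness and excess kurtosis (defined as 0 for a constant patch), min, max,
  10th/50th/90th percentiles, energy (sum of squared min–max-normalised
  intensities; 0 for a constant patch), and histogram entropy in bits over 64
  equal bins spanning the patch's own min–max range. Central moments and the
  min–max-anchored histogram make all but mean/min/max/percentiles invariant
  to intensity shifts.
- **GLCM texture (5 features):** intensities are quantised to 32 equal-width
  levels over the patch min–max range (hence invariance to affine intensity
  rescaling); symmetric, normalised co-occurrence matrices are computed at
  distance 1 for the four standard offsets (0,1), (1,0), (1,1), (1,−1) via
  scikit-image and averaged; features are contrast, correlation (defined as 1
  for a zero-variance patch), energy (angular second moment), homogeneity
  (1/(1+(i−j)²) weighting) and co-occurrence entropy in bits. 32 levels and
  distance-1 offsets are ordinary Haralick practice; both are parameters of
  `ExtractorSpec`.

Deep networks (VGG16, ResNet50, DenseNet121, InceptionV3, MobileNetV2) and
full radiomics suites are supported as **plugins**: a registered callable
receives the `(h, w, c)` patch and must return a deterministic fixed-length
vector; spatial maps should be collapsed with the provided global-average
pooling adapter. Requesting an unregistered plugin raises a capability error
— there is no silent fallback — and no pretrained weights are bundled.
Radiomics shape descriptors are excluded from the native extractor because a
rectangular patch has no meaningful segmentation mask.

## The four markers

Let `X` be the `n × p` feature table.

- **Normalised Shannon entropy.** Each non-constant column is min–max
  normalised to [0, 1]; the 256-bin histogram entropy (bits) of each column
  is divided by `log2(256)` and averaged (`entropy_method="per_feature"`,
  the default). The min–max-anchored bins make the marker invariant to any
  strictly monotone affine rescaling of a column. A pooled variant
  (`"pooled"`: one histogram over all normalised values) is available; it can
  rank a heterogeneous feature space above its parts, which the per-feature
  mean cannot (the mean over a column concatenation is a convex combination
  of the parts' means), but it is only invariant to *increasing* affine maps
  and tends to saturate near 1 on diverse feature sets. Entropy is computed
  on the raw (unstandardised) table. Constant-only matrices score 0.
- **Cumulative variance curve.** PCA (scikit-learn, full SVD) on the z-scored
  table — z-scoring is the default because feature families live on wildly
  different scales, making covariance-PCA meaningless across families;
  constant columns are dropped and recorded. `d = min(n−1, p)` components are
  retained; since centred data have rank ≤ n−1 the retained components carry
  all variance and the curve ends at 1 (pinned against fp residue). The test
  suite cross-checks the curve against an independent dense
  eigendecomposition of the sample covariance to 1e-8.
- **1-AUC.** Trapezoid rule over `y` with component index mapped to [0, 1]
  via `x_k = (k−1)/(d−1)`. Bounds: 0 (rank-1 spectrum) to `(d−1)/(2d)`
  (isotropic). A single-point curve is defined as 0 with a warning.
- **PC95.** Smallest `k` with `y_k ≥ threshold` (default 0.95, `≥` not `>`),
  with a 1e-12 slack so exact analytic crossings survive floating point.
- **Inverse power law.** `IP(n) = a·n^(−b) + c` fitted over `n = 1..d` with
  `scipy.optimize.least_squares` (trf), bounds `c ∈ [0, 1]`, `a, b` free,
  fixed initialisation `a₀ = y₁ − 1, b₀ = 0.5, c₀ = 1`, tolerances 1e-14 —
  deterministic, no randomness. At least 4 points are required; optimiser
  failure returns best-effort parameters with `converged=False` instead of
  raising. Standard errors come from the Gauss–Newton covariance
  `(JᵀJ)⁻¹·rss/(d−3)`. The scalar summary is `M = log₁₀(|a|) − b` by default;
  the printed formula this summarises appears in different typographic forms
  in the literature, so the variant is configurable (`inverse_a`,
  `inverse_b`) and always recorded in provenance.

## Combination modes

"Combined" defaults to **feature concatenation** over spatially corresponding
patches (identical patch ids required; modality-prefixed column names). This
widens the feature space without changing the sampling unit, which is what
the PC95 behaviour of combined datasets indicates in practice. Channel
stacking *before* extraction is available at the image level
(`stack_channels`) — for per-channel native extractors it yields the same
columns as concatenation — and row pooling (`pool_rows`) is available as a
non-default alternative that models "more samples" rather than "wider
representation".

## Synthetic generator

Gaussian random fields synthesised by spectral shaping: white noise is
filtered so frequency amplitudes scale as `f^(−β/2)`; β = 0 is white noise,
larger β is smoother. Channel i of modality B is
`ρ·shared_i + √(1−ρ²)·independent_i` with all fields unit-variance before
mixing, so the pixelwise Pearson correlation of paired channels equals ρ and
pairs are co-registered by construction. All randomness derives from one
integer seed through `numpy.random.SeedSequence`; no global state.

Defaults (chosen once, as the package's study conditions): 300×300 px so a
10×10 grid yields 30×30 patches; 8-bit; a smooth three-channel "HE" modality
(β = 3 per channel, emulating stained brightfield tissue dominated by
low-frequency structure) versus a sharper three-channel "MM" modality
(β = 1.5, 2.0, 2.5 for the vibrational, autofluorescence and collagen
channels); ρ = 0.5.

What the generator does **not** emulate: nuclei/gland morphology, stain
chemistry, detector noise, non-Gaussian intensity distributions. Passing the
end-to-end tests therefore shows that the pipeline measures complexity and
cross-channel dependence as designed, not that it reproduces any particular
tissue dataset's numbers.

## Scale effects when comparing feature spaces of different widths

Two of the four markers are **shape** functionals and two are **extent**
functionals, and this matters when the compared representations have
different dimensionality (as a concatenated combined dataset always does):

- PC95 and the log-law metric respond to the number of independent variance
  directions; concatenating a second modality's features reliably increases
  them (measured: in 20/20 seeded replicates of the default study the
  combined PC95 exceeds both single-modality values, and the combined mean
  log-law metric is distinctly less negative).
- Per-feature entropy is a convex combination under concatenation, and 1-AUC
  on a per-curve-normalised axis compares eigenspectrum *shapes*, which for a
  union of two spectra (plus any positive cross-correlation) lies between or
  below the parts' shapes. Neither can systematically exceed both
  single-modality values in the regime `p ≪ n` (measured: 0/20 replicates
  for both markers under the default study). These markers only reward
  combination when the representation is sample-limited (`p ≳ n`, e.g.
  thousand-dimensional deep features against a comparable number of patches),
  where all curves share an axis capped at `n − 1` and widening the feature
  space genuinely flattens the common-length curve.

Users comparing modalities with the native (48-feature) extractor should
therefore read PC95/log-law as the "extent" signal and entropy/1-AUC as
"shape" diagnostics, and expect combination benefits on all four markers only
with high-dimensional plugin extractors.

## Degenerate inputs and tie-breaks

- Constant feature columns: dropped before PCA (recorded in provenance);
  contribute 0 to entropy; an all-constant table is a validation error for
  PCA and entropy 0 by definition.
- Constant patches: variance/skewness/kurtosis/energy/histogram entropy 0;
  GLCM contrast 0, energy and homogeneity 1, correlation 1.
- Duplicated columns (e.g. a modality combined with an exact copy of itself):
  the standardised duplicates add zero new eigenvalue mass, so PC95 is
  unchanged; duplicate *names* are rejected.
- Radar axes with zero range across modalities map every row to 0.5.
- `FeatureMatrix` values are stored C-contiguous so identical tables produce
  bit-identical curves regardless of the constructor's memory layout; all
  JSON is written with sorted keys so reruns are byte-identical.

## Problem sizes in the shipped checks

The replicated study runs 20 seeded pairs at 300×300 px with the native
extractor (100 patches × 48/96 features per report); the PCA oracle check
uses 50 random matrices up to 200×50; power-law recovery uses 100-point
curves over 20 seeds, noiseless and at additive noise σ = 0.005. The whole
suite and the acceptance script each complete in about a minute on one CPU.

## Known limitations

- No statistical tests between modalities are provided; the markers are
  descriptive.
- Exact parity with any specific radiomics or deep-feature implementation is
  not claimed; the native extractor is a documented, deterministic baseline.
- Whole-slide pyramid formats and stain normalisation are out of scope;
  inputs are plain TIFF/PNG.
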