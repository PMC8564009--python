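# Methods

## Scope and assumptions

The package implements a complete image-to-decision chain for beef-cut
classification from six-band multispectral cubes: reflectance calibration,
region-of-interest selection, feature extraction (band means, CIELAB,
co-occurrence texture), feature-level fusion, and evaluation of three
configured classifiers. Bands are assumed co-registered (as produced by a
filter-wheel snapshot camera) and the dark/reference frames are assumed
acquired under the same illumination as the samples. No radiometric model
beyond the pointwise two-frame calibration is attempted.

## Calibration

`R = (I_raw − I_dark)/(I_ref − I_dark) × ρ_ref` per pixel and band, with
ρ_ref = 0.20 for the 20 % diffuse standard. Choices:

* The result is clipped to [0, 1]. Reflectance slightly above the
  reference scale can occur at specular pixels; clipping keeps the
  downstream uniform quantization of [0, 1] well defined.
* Pixels where `I_ref ≤ I_dark` carry no calibration information; they are
  set to 0 and flagged with a warning rather than producing infinities.
  Calibration fails only if *no* pixel is valid.
* Frames may be 2-D (shared by all bands, broadcast) or 3-D (per band).
* Calibrating an already calibrated cube is an error, not a no-op.

## Region of interest

The source experiment does not describe foreground selection, so the
default is the full frame (appropriate for the synthetic cubes, which are
all tissue). For real images an Otsu threshold on one band (default: the
band nearest 680 nm, the best tissue/background contrast in the generator)
followed by largest-connected-component selection is provided. A constant
band cannot be thresholded; the method falls back to the full frame with a
warning.

## Texture features

Reflectance is quantized uniformly on [0, 1]:
`level = floor(clip(x, 0, 1−ε)·N)`, so x = 1.0 falls in the top level.
Defaults: N = 64 levels (a compromise between gray-scale resolution and
co-occurrence sparsity on 16-bit data), pair distance 1 pixel, the four
canonical directions {0°, 45°, 90°, 135°} with symmetric counting, and the
per-angle normalized matrices averaged into one rotation-robust GLCM per
band. Pixels outside the ROI are excluded from every pair. Angles follow
the convention "0° = right, 45° = up-right" with the origin top-left.

The four statistics are the standard forms: homogeneity
Σ g/(1+(i−j)²), contrast Σ (i−j)² g, energy Σ g² (angular second
moment — the un-squared sum is identically 1 for any normalized matrix and
discriminates nothing), and correlation (Σ i·j·g − μxμy)/(σxσy) with σ the
square roots of the marginal second central moments, which is the only
form bounded in [−1, 1]. Correlation of a zero-variance (constant) region
is reported as 0 — a constant patch carries no linear-dependence
information; the value is configurable. Level indices run 0..N−1.

Per band this yields 4 statistics; 6 bands give the 24-variable texture
set, ordered band-major.

## Spectral features

**MS** is the mean ROI reflectance per band (6 values). **CIELAB** maps
three bands to a linear RGB triple — defaults R←680 nm, G←570 nm,
B←500 nm, the closest available centers to the display primaries — through
the fixed BT.709/D65 RGB→XYZ matrix, then to (L\*, a\*, b\*). The white
point defaults to the matrix's response to the unit white stimulus (its
row sums, ≈ D65), so a perfect white diffuser maps to exactly (100, 0, 0).
Inputs are physical reflectances, so no display gamma is applied before
the linear matrix. The piecewise compression uses knee (24/116)³, slope
841/108 and offset 16/116; both branches agree at the knee to machine
precision. Lab is computed on the ROI-mean band values (three features, as
in the reference design); a per-pixel variant (convert pixelwise, then
average Lab) is available as an option.

## Fusion and normalization

Feature blocks are concatenated column-wise in the fixed order MS,
Texture, CIELAB (subsets keep that order). Columns are z-scored with the
population standard deviation (ddof = 0; configurable), fitted strictly on
training rows — inside each cross-validation fold, or on the calibration
set for held-out prediction — and applied unchanged to test rows.
Constant training columns map to 0 with a warning. Fitting per fold costs
a little accuracy pessimism but guarantees no information leakage; the
alternative (global normalization before splitting) is deliberately not
offered.

## Classifiers and evaluation

* LDA with the singular-value-decomposition solver (robust for
  collinear, high-dimensional features).
* Linear SVM with C = 0.6 and one-vs-one voting (vote ties resolve to the
  lowest class index, deterministically). C = 1 performs comparably and is
  exposed in the config.
* Random forest with 160 trees, √p candidate features per split, minimum
  leaf size 1, seeded. Accuracy saturates from a few tens of trees on;
  the tree count is configurable.

Implementations are delegated to scikit-learn; the package's contract is
the exact hyperparameter set, the stratified fold construction, the
leakage-free per-fold normalization, and the reporting.

The labeled set (defaults: 200 sirloin, 160 flank, 195 shank — note the
counts sum to 555, which a stratified split divides into 445 calibration
and 110 prediction samples) is split once, stratified and seeded. Model
quality is the mean accuracy over stratified 10-fold cross-validation on
the calibration set, plus accuracy, confusion matrix and one-vs-rest
per-class accuracy / precision = TP/(TP+FP) / recall = TP/(TP+FN) (in
percent) on the prediction set. Undefined ratios (empty class) report 0
with an `undefined` flag. All evaluation regenerates bit-identically from
(config, seed).

## Synthetic data generator

The generator stands in for unavailable measured cubes. Its defaults *are*
the study conditions used by the tests and the acceptance script: 555
samples (200/160/195), six bands, 128 × 128 pixels (the native
1290 × 960 is supported; co-occurrence statistics at distance 1 are stable
well below that size and desk-scale runtimes matter more than frame area),
16-bit counts.

Forward model per sample: true reflectance
`profile[b]·(1 + a_b·T(x, y))` with one texture field T shared by all
bands and per-band amplitude `a_b`; raw counts
`gain(x,y)·R·K + dark + ε` with K = 0.85 × full scale per unit
reflectance, dark level 5 % of full scale, Gaussian sensor noise
σ = 600 counts (≈ 1 % of full scale), and a smooth order-2 polynomial
illumination field of ±8 %. The reference frame images the 20 % standard
under the same gain; dark and reference frames are modeled as averages of
100 exposures (standard practice), so their noise is 10× lower than a
single frame's. Calibration then inverts gain and scale exactly up to
noise and 16-bit rounding.

Class structure (chosen to reproduce the qualitative contrasts reported
for real cuts, since no numeric spectra are tabulated):

* **sirloin** — profile (0.26, 0.30, 0.34, 0.48, **0.40**, 0.51): a
  relative dip at 760 nm (water/deoxymyoglobin); faint blob marbling
  (smoothed Poisson discs, amplitude 0.06, ~0.005 blobs/px).
* **flank** — same profile except 0.45 at 760 nm; weak Gaussian
  random-field texture (amplitude 0.05).
* **shank** — brightest profile (0.28 … 0.53); oriented stripes
  (soft-thresholded sinusoid along a 90° orientation, amplitude 0.20,
  period 8–16 px) for white fascia and fiber direction.

Per-sample variability: log-normal overall-brightness jitter (σ = 12 %),
per-band jitter (σ = 3 %), texture amplitude × U(0.3, 1.7), independent
per-band amplitude jitter ± 40 %, stripe orientation ± 20°, randomized
field correlation lengths. These were set so that the two modalities are
*complementary*: brightness variability makes flank/shank overlap
spectrally while stripes identify shank, and the faint
marbling/weak-noise textures overlap while the 760 nm dip identifies
sirloin. Neither modality alone separates all three classes; fusion does —
which is the behavior the package exists to demonstrate, here by
construction rather than as evidence about real beef.
`separation_scale` multiplies all between-class profile differences
(0 ⇒ spectrally identical classes, used by the null-model test).

What the generator does **not** emulate: real meat optics (scattering,
BRDF, specularities), chemically grounded spectra, inter-band
registration error, nonuniform sample shape/background (tissue fills the
frame by default), and temperature/storage effects. Passing tests
therefore validate the correctness and the internal logic of the pipeline
— calibration fidelity, feature definitions, leakage-free evaluation, the
fusion mechanism — not field performance on real beef, and the reference
experiment's exact accuracy tables are not reproduction targets.

## Numerical choices and degenerate inputs

* GLCM normalization tolerance 1e−12; matrices are validated to be square,
  non-negative and normalized before statistics are computed.
* Quantization clips to 1 − ε before scaling so the top of the range never
  overflows the level count.
* An ROI too small to contain any pixel pair at the configured offset is a
  hard error naming the offset.
* Zero-variance columns (z-score) and zero-variance marginals
  (correlation) degrade to 0 with a warning/flag, never to NaN.
* All random streams derive from `numpy.random.SeedSequence`; each sample
  has its own child stream, so generated data do not depend on how many
  samples are consumed.

## Problem sizes

Default experiment: 555 samples at 128 × 128 × 6, features in ~15 s and
the full 6 × 3 grid in ~30 s on one CPU. The test suite runs smaller
configurations (32–64 px frames, reduced class counts) except for the
end-to-end property checks, which use the default dataset.

## Known limitations

* The GLCM quantizes [0, 1] globally, so texture statistics retain some
  dependence on a band's mean brightness (bin occupancy scales with
  level). This is inherent to fixed-range quantization and is part of what
  the texture features measure.
* CIELAB features are a fixed linear-then-nonlinear function of three of
  the six band means, so they add little information beyond MS; they are
  kept for parity with the reference design.
* One-vs-one SVM voting ties are broken deterministically but arbitrarily
  (lowest class index).
* The cube TIFF dialect stores calibrated cubes as float32; round trips
  are bit-exact for integer rasters and float32-exact otherwise.
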