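# msibeef

Classification of beef cuts (sirloin, flank, shank) from six-band
multispectral image cubes, combining spectral and textural features by
feature-level fusion and evaluating three machine-learning classifiers with
stratified cross-validation.

Retail substitution of premium cuts (sirloin) by cheaper ones (shank,
flank) is a common food fraud. Multispectral imaging is a fast,
non-destructive way to detect it: the cuts differ both in composition
(water, myoglobin, lipid — visible as band-wise reflectance differences,
notably a deoxymyoglobin/water absorption dip near 760 nm in sirloin) and
in spatial structure (white fascia stripes in shank, marbling in sirloin).
This package is aimed at researchers in food quality / chemometrics who
want a tested, configurable reference implementation of the full analysis
chain, together with a seeded synthetic-image generator so everything runs
and is testable without access to measured data.

## Method

Raw 16-bit counts are calibrated to relative reflectance against a dark
response and a 20 % diffuse reference, pointwise per pixel and band:

```
R = (I_raw − I_dark) / (I_ref − I_dark) × 0.20
```

From each calibrated cube three feature blocks are extracted over the
region of interest:

* **MS** (6 features) — mean reflectance per band (500, 530, 570, 680,
  760, 808 nm).
* **CIELAB** (3 features) — three bands (defaults: 680→R, 570→G, 500→B)
  form a linear RGB triple, mapped to CIEXYZ by the fixed BT.709/D65
  matrix and then to (L\*, a\*, b\*) with the standard cube-root
  compression `f(t) = t^{1/3}` for `t > (24/116)^3`, linear below.
* **Texture** (24 features) — per band, reflectance is quantized to
  N = 64 gray levels and a symmetric gray-level co-occurrence matrix
  g(i,j) is accumulated at distance 1, averaged over the four canonical
  directions; four statistics summarize it:

```
homogeneity = Σᵢⱼ g(i,j) / (1 + (i−j)²)
contrast    = Σᵢⱼ (i−j)² g(i,j)
energy      = Σᵢⱼ g(i,j)²
correlation = (Σᵢⱼ i·j·g(i,j) − μₓμᵧ) / (σₓσᵧ)
```

Feature blocks are z-scored column-wise (parameters fitted on training
data only, inside every cross-validation fold) and concatenated into
single-modality or fused sets (MS+Texture = 30, CIELAB+Texture = 27,
MS+Texture+CIELAB = 33 features). Each set is fed to three classifiers —
LDA (SVD solver), a linear SVM (C = 0.6, one-vs-one voting), and a random
forest (160 trees, √p features per split, leaf size 1) — evaluated by
stratified 10-fold cross-validation on a 445-sample calibration set and by
prediction on a 110-sample held-out set, with confusion matrices and
per-class precision/recall.

The synthetic generator emulates the reference sampling design (555
samples: 200 sirloin, 160 flank, 195 shank) with a physical forward model:
smooth polynomial illumination, counts proportional to reflectance,
dark level, Gaussian sensor noise, matching dark/reference frames, and
per-sample jitter of every class-template parameter.

## Worked example

Run the full default experiment (generate 555 synthetic cubes, extract
features, evaluate the 6 × 3 grid):

```
msibeef run --seed 1 --out results/
```

`results/cv_accuracy.csv` then holds the mean 10-fold cross-validation
accuracy (%) per feature set and classifier:

```
feature_set,n_features,LDA,LSVM,RF
MS,6,78.23,78.67,72.37
CIELAB,3,46.94,47.63,37.3
Texture,24,84.02,84.02,85.61
MS+Texture,30,95.27,96.18,89.63
CIELAB+Texture,27,84.02,83.56,85.61
MS+Texture+CIELAB,33,95.27,95.95,88.29
```

and `results/prediction_accuracy.csv` the held-out accuracies (the fused
33-feature LDA model reaches 97.27 % here). Reading the table: neither
single modality resolves all three cuts — band means confuse flank with
shank (overall brightness varies between animals), texture confuses
sirloin with flank (both weakly textured) — while their fusion lifts
accuracy by ~11 points over the best single set, for every classifier.
Per-cell confusion matrices are written as CSV and heatmap PNGs, and
`report.json` carries per-class precision/recall, the config snapshot, its
hash and the seed; reruns with the same seed are byte-identical.

The same pipeline runs on measured data: store cubes as multi-page TIFF
with a JSON sidecar plus a `manifest.csv` (sample_id, class) and point the
config's `input_directory` (or `msibeef features --cubes DIR`) at it.

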