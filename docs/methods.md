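# Methods

This note records the models the package implements, the synthetic data
it is validated on, and the choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The estimation problem

Given a 5-band reflectance orthomosaic (blue, green, red, red-edge,
near-infrared; fixed band order everywhere) and a set of ground quadrats
with measured LAI, fit a regression from image features — or raw image
patches — to LAI, evaluate it on held-out quadrats, and render a
scene-wide LAI map. Three estimators are compared under identical
splits: PLSR and a random forest on per-quadrat feature means, and a CNN
on raw 32×32×5 patches.

## Synthetic scenes

The generator emulates a variety-trial wheat field surveyed at ~3.7 cm
ground sampling distance with 234 one-meter quadrats. It is a study
*condition*, not a tuning knob: its defaults define the data regime all
stochastic claims are tested under.

**LAI field.** Gaussian-smoothed white noise (correlation length
`smoothness_px`, default 25 px) plus constant offsets on a rectangular
plot grid (default 80 px plots, offset sd 0.8) models smooth within-plot
gradients and plot-to-plot variety contrast. The field is affinely
rescaled so its extremes hit `lai_range` (default 0.5–6.5) exactly; a
degenerate range yields a constant field. An optional `lai_skew`
compresses the upper tail, mimicking surveys in which dense-canopy
samples are rarer; it defaults to off because no quantitative
distribution was available to calibrate it against.

**Reflectance.** Each band relaxes exponentially from bare-soil
reflectance toward a dense-canopy asymptote:
ρ_b(LAI) = ρ∞_b + (ρ_soil_b − ρ∞_b)·exp(−k_b·LAI). Defaults encode
wheat-like optics (NIR rises 0.25 → 0.50, red falls 0.15 → 0.03;
extinction 0.45–0.65 per band), giving the saturation behaviour real
canopies show at high LAI. Ridge/row texture enters as a sinusoidal
modulation of the *effective* LAI (period 8 px, amplitude 0.25): rows
carry locally more canopy than furrows, so bare soil stays exactly at
soil reflectance, and the texture contrast fades as the canopy closes —
this is what makes texture features genuinely informative about LAI
rather than decorative. I.i.d. Gaussian sensor noise (sd 0.01
reflectance units) is added last; values are clipped to [0, 1]. A
`strongly_saturating` optics preset roughly doubles every extinction
coefficient, pushing most of the LAI range into the saturated regime.

**Quadrats.** Centers sit on a jittered grid (one per cell, jitter
bounded so 32×32 windows never overlap or cross the edge), matching an
"evenly distributed" survey. Measured LAI is the true-field mean over
the window plus Gaussian noise (sd 0.15 LAI units, the scale of indirect
optical instruments); non-positive draws are redrawn.

**What the generator does not emulate**: radiative-transfer physics
(PROSAIL-class models), georeferencing to a real CRS, multi-date
phenology, mixed pixels at plot borders, and spatially correlated sensor
noise. Passing tests therefore demonstrate that the pipeline recovers a
known signal under a plausible noise model — not field-data accuracy.

## Feature engineering

**Vegetation indices.** The registry holds exactly 23 formulas over the
band reflectances and the chromatic coordinates r, g, b (each visible
band over R+G+B). Formulas are implemented as printed in the source
table this library follows, including two entries that differ from
common literature forms: LCI uses denominator NIR+R (a switch
`lci_variant="rededge"` provides the NIR+RE form), and RDVI uses
(NIR+R)^0.5 in the denominator. Bands are bound by *name*, never by
nominal wavelength. Zero-denominator pixels are masked (NaN), not
clipped, and masked pixels are excluded from quadrat means — silent
clipping would bias the features.

**GLCM texture.** Texture is computed from scratch (the usual desktop
implementation is closed-source): per pixel, the gray-level
co-occurrence matrix of its 3×3 reflect-padded window at the 45° offset
(Δrow, Δcol) = (−1, +1), counted symmetrically, yields 8 statistics ×
5 bands = 40 planes named `band_stat` (`red_mean`, `nir_cor`, …).
Definitions (P the normalized GLCM, μ/σ its marginal moments):
mean = μ_i, var = Σ(i−μ_i)²P, hom = ΣP/(1+(i−j)²), con = Σ(i−j)²P,
dis = Σ|i−j|P, ent = −ΣP·lnP, sec = ΣP², cor = cov/(σ_iσ_j) with
cor := 0 at zero marginal variance (constant windows are common in
synthetic scenes). "hom" is homogeneity (inverse difference moment).

Quantization is linear min–max over the whole plane into Q = 32 levels.
Q is configurable; 32 was chosen because a 3×3 window contributes only
8 symmetric pairs, so finer quantization leaves most matrix cells empty
without changing the moment statistics.

The production path never materializes per-pixel Q×Q matrices: all
eight statistics are moments or collision counts of the window's level
pairs, computed vectorized over the scene. For 2K symmetric samples per
window, sec = Σ_a c_a/(2K)² and ent = −(1/2K)Σ_a ln(c_a/2K), where c_a
is the multiplicity of sample a's cell. A direct enumerate-the-pairs
reference path exists alongside it, and the test suite asserts per-pixel
equality between the two, plus agreement with scikit-image's GLCM on
whole-plane matrices.

**Aggregation footprint.** A 1 m quadrat at 3.7 cm GSD is ≈27 px across,
but the CNN consumes 32×32 patches; all per-quadrat feature means use
the same 32×32 window the CNN sees, so the three models compete on the
same information. Windows are half-open, [c−16, c+16), 0-based
row-major — chosen once so index arithmetic is testable.

## Feature optimization

A feature is kept when its random-forest importance weight strictly
exceeds 0.03 **and** its Pearson correlation with measured LAI is
significant at p ≤ 0.01 (two-sided, t distribution with n−2 df). The
correlation *magnitude* is deliberately not thresholded. Open choices,
resolved as follows:

* *Importance flavor*: permutation importance (mean out-of-sample error
  increase under column shuffling), because impurity importance
  dilutes across correlated features — and VI sets are highly
  intercorrelated. Impurity importance remains available
  (`importance="impurity"`). Negative permutation scores are floored at
  zero; weights are normalized to sum to 1 so the 0.03 threshold is
  scale-meaningful.
* *"Extremely significant"*: read as p ≤ 0.01; configurable (0.001 for
  the stricter convention).
* *Candidate pools*: the VI and T regimes select within their own
  feature type; VI+T selects from the joint 63-feature pool.
* Selection runs on the train+validation quadrats only, so the test set
  never influences which features the models see.
* If the strict rule keeps nothing (possible on very noisy scenes), the
  pipeline falls back to the three largest-weight significant features
  so downstream fits remain defined; the selection table still records
  the strict outcome.

## Inversion models

**PLSR** (`PLSRegressorCV`): NIPALS PLS with predictors standardized to
unit variance; the component count minimizes 10-fold cross-validated
RMSE over 1…min(p, n−1), with a parsimony tie-break (fewest components
within numerical tolerance, 1e−6 relative, of the minimum). Note that
with an exactly-linear noise-free target, CV RMSE genuinely decreases to
machine zero at full rank — PLS covariance directions mix finite-sample
noise-feature correlations — so no early tie exists to break; the
parsimony rule matters in the realistic noisy regime, where the CV curve
flattens.

**Random forest**: 1000 trees, mtry = max(1, ⌊p/3⌋) split candidates
(the classical regression default), bootstrap with out-of-bag scoring,
seeded.

**CNN** (`CNNRegressor`): the four-block architecture with 16/32/64/128
3×3 same-padding filters, each block conv → batch-norm → ReLU → 2×2
max-pool (the batch-norm-before-activation order implied by the
published shape table), dropout p = 0.2 on the 128×2×2 activations,
flatten (512) → dense 64 (ReLU) → dense 1. Loss is MSE; the optimizer
is mini-batch SGD with momentum 0.9 at learning rate 0.001, batch size
32. The network is implemented in NumPy (im2col convolutions, explicit
backpropagation) in single precision; training is fully deterministic
given the seed. Per-band standardization constants are fitted on the
training pool and travel with the model. Weights from the
best-validation-MSE epoch are restored after training, with early
stopping (default patience 10). The default budget is 60 epochs;
validation loss plateaus well before that on study-scale synthetic
pools (~1000 patches), and the acceptance suite uses 35 epochs /
patience 8 at its five-scene problem size. All budgets are parameters.

**Splits and augmentation.** All counts are round-half-up, which
reproduces the chain 234 → 164/70 → 984 → 787/197 exactly. The
train+validation pool is expanded sixfold (original, three rotations,
two flips — label-preserving isometries); the test set is never
augmented. The CNN's 80/20 train/validation split is taken *after*
augmentation, as the study design describes, which means augmented
copies of one quadrat can appear on both sides of that split; a
leakage-safe alternative (hold out quadrats before augmenting) can be
had by passing an explicit validation set to `CNNRegressor.fit`.
Provenance ids (`source_ids`) make the leakage auditable either way.
The quadrat-level test set is untouched in both variants.

## Evaluation and mapping

R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², RMSE = √(Σ(y−ŷ)²/n), MAE = Σ|y−ŷ|/n, with y
the measured and ŷ the estimated LAI. (The bare ratio Σ(y−ŷ)²/Σ(y−ȳ)²
is available behind `strict_printed_r2=True` for audit; it equals 1−R²
and is *small* for good fits.) The estimated-on-measured least-squares
line diagnoses attenuation: slopes below 1 indicate overestimation at
low LAI and underestimation at high LAI. Model agreement is the squared
Pearson correlation between two models' predictions plus the fitted
line of one on the other.

Maps: feature models predict per pixel from scene-wide feature planes
(masked pixels stay masked); the CNN predicts one value per 32×32 tile,
non-overlapping by default (stride configurable; overlapping tiles are
averaged). Per-pixel feature predictions at a quadrat center differ
slightly from the per-quadrat prediction because the latter uses
window-mean features; the map tests therefore compare map pixels against
predictions on the same per-pixel features, and separately check that
high-LAI scenes map higher than low-LAI scenes.

## Numerical conventions and degenerate inputs

* All generator outputs are pure functions of (config, seed); per-stage
  RNG streams are derived from the scene seed.
* Constant planes quantize to level 0; constant windows give the
  degenerate Haralick values (con = dis = var = ent = 0,
  hom = sec = 1, cor = 0).
* Constant features report r = 0, p = 1 with a warning rather than
  aborting a selection run; a constant *target* is an error.
* Zero-variance bands make standardization an error (`DegenerateBandError`).
* Masking is contagious: any masked pixel in a texture window or VI
  denominator masks the output pixel; fully-masked quadrat windows are
  errors naming the quadrat id.
* Max-pool gradients split equally among tied maxima (ties are common
  after ReLU zeros).

## Problem sizes

Unit tests run on scenes from 32×32 to 288×224 px with 1–40 quadrats.
The acceptance suite runs five full studies at the default conditions
(480×640 px, 234 quadrats, seeds 1–5), one noise-free study, three
strongly-saturating studies, and 100 repetitions of the
planted-feature selection experiment — sizes chosen so the whole suite
completes in minutes on a single CPU while still exercising the exact
study arithmetic (234/164/70/984/787/197) at full scale.

## Known limitations

* The Beer–Lambert scene model has no bidirectional effects, shadows,
  soil moisture variation, or mixed plot-edge pixels; absolute
  accuracies on synthetic scenes exceed what field data yields.
* The GLCM quantization level and windowing convention of the original
  desktop workflow are not documented anywhere authoritative; ours are
  declared substitutes (Q = 32, scene-wide scaling, reflect padding).
* PLSR component selection is the only hyperparameter search performed;
  forest size and CNN architecture are fixed by design.
* `render_lai_map` with a random forest predicts per pixel and is the
  slowest path on large scenes; stride-32 CNN maps are blocky by
  construction.
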