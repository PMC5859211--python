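# Methods

`beanspec` implements a single-seed hyperspectral chemometrics pipeline:
individual green coffee beans are segmented from short-wave-infrared
(SWIR, 980–2500 nm) hypercubes, each bean is summarized by the unweighted
mean absorbance spectrum of its pixels, PLS1 calibrations predict
moisture and total fat from those spectra, regression-coefficient
thresholding reduces the wavelength set, discriminant/SVM classifiers
separate arabica from robusta beans, and the fitted calibration is
applied back at single-pixel level to map constituent distribution
within each bean. Because no public hypercubes of this kind exist, all
of it is exercised on synthetic scenes whose ground truth is known
exactly; this note records the models, the defaults, and what the
synthetic results do and do not demonstrate.

## Radiometric model and segmentation

A scene is acquired as raw detector counts. Reflectance is computed per
pixel and band as R = (raw − dark)/(white − dark) against averaged dark
and white (PTFE) reference frames, and absorbance as A = log10(1/R),
with R floored at 1e-6 so A never exceeds 6 AU. Spikes are removed by a
per-pixel spectral Hampel filter: a sample is replaced by its running
median (default window 5) when it deviates by more than `z_max = 5`
robust SDs, where the robust SD is 1.4826 × the per-pixel median
absolute deviation from the running median, floored at
`min_scale = 0.01` signal units. The floor is deliberate: on a
noise-free smooth spectrum the MAD collapses toward zero and genuine
absorption-band curvature would otherwise be clipped; with the floor,
only excursions beyond 0.05 AU can ever be touched, which is far above
band curvature at instrument resolution and far below genuine detector
spikes.

Foreground follows the standard dark-stage rule for seeds: a pixel
belongs to a bean when log10(1/R) at 1186 nm is strictly below 1 (beans
reflect well there; the black stage does not). Connected components
(8-connectivity) smaller than `min_pixels = 50` are discarded as spike
residue, and surviving labels are renumbered in raster order of their
first pixel so labelling is deterministic. Touching beans are not split:
the pipeline assumes spatially separated beans on the stage, and no
watershed step is provided. The modelling range is trimmed to
980–2480 nm before calibration, dropping the noisy detector edge.

## Pre-treatments

All steps are strictly row-wise (no cross-spectrum coupling except
through state fitted on the calibration rows), so every step applies to
a single pixel spectrum exactly as to a batch:

* **SNV** — per-spectrum standardization, (x − mean)/sd with the n−1
  denominator; removes additive offsets and multiplicative gain.
* **MSC** — per-spectrum regression x ≈ a + b·ref against a reference
  spectrum (the column mean of the calibration rows, stored at fit);
  corrected spectrum (x − a)/b.
* **Savitzky–Golay derivatives** — 1st derivative with window 9,
  2nd derivative with window 11, both polynomial order 2, derivative
  reported per band step, edges handled by the polynomial fitted on the
  truncated window. The windows are configurable and recorded with the
  model; they were fixed a priori at common chemometric values.
* **detrend** (per-row quadratic removal), **normalize** (unit Euclidean
  norm), **baseline** (per-row minimum subtraction — "baseline" is a
  loosely used term in calibration reports; minimum subtraction is this
  package's documented interpretation), **mean centering** (column means
  learned on the calibration rows and reused at prediction).

Inside cross-validation every chain is refitted on the training rows of
each fold, so held-out predictions never see fold statistics.

## Calibration

The regression core is PLS1 computed by NIPALS with X-deflation. For
column-centered X (n × B) and centered y, component a is

    w_a = X'y/‖X'y‖,  t_a = X w_a,  p_a = X't_a/t_a't_a,  q_a = y't_a/t_a't_a,

after which X ← X − t_a p_a' and y ← y − q_a t_a. The coefficient form
β = W(P'W)⁻¹q (plus intercept ȳ − x̄'β) reproduces factor-form
predictions to numerical precision and is the object that gets
thresholded for wavelength selection and applied per pixel for mapping.
PLS1 components are closed-form; there is no random initialization and
fits are exactly reproducible.

Model assessment follows the standard panel. Rows are split into 10
random segments fixed by a seed (leave-one-out available by flag);
RMSECV is the root mean square of pooled held-out residuals,
sqrt(Σ(ŷᵢ−yᵢ)²/n). The number of latent variables minimizes RMSECV,
ties resolved toward fewer components, and the final model is refitted
on all rows at that complexity. R² is reported as the squared Pearson
correlation of predicted versus measured (the convention of the major
chemometrics packages, under which the calibration slope of predicted
regressed on measured ≈ R²); the 1 − SSE/SST variant is also carried in
the metrics object for transparency. RPD = sd(y, n−1 denominator)/RMSECV,
with RPD > 2 the conventional bar for an excellent calibration. MLR
models (used on reduced band sets) are ordinary least squares with
intercept run through the same CV machinery; a rank-deficient band
subset is an error that names the collinear columns.

Outlier screening flags the union of |studentized y-residual| > 4,
leverage > 6(LV+1)/n, and Hotelling T² in score space above the F-based
limit at a Šidák-adjusted level such that `t2_alpha = 0.01` is the
probability that a *clean* table yields any T² flag at all. These
cutoffs are deliberately conservative — at textbook per-sample levels
(3σ residuals, 3× average leverage, 95 % T²) a perfectly clean
300-sample calibration would be flagged essentially every run, which is
not what removal-then-refit is for. Removal is a single pass (flag,
drop, one refit), never iterative, and is suppressed with a warning if
more than 20 % of rows are flagged.

## Wavelength selection

Bands are ranked by |β| of the parent PLS model at its CV-selected
complexity; the threshold is parameterized by the surviving band count
(presets 42, 22 and 6), with ties resolved toward larger |β| and then
lower wavelength so the subset is deterministic. Reduced MLR models are
fitted on raw log(1/R) only — a filter instrument sampling a handful of
discrete wavelengths cannot form spectral derivatives — while reduced
PLS models may keep any chain whose window fits the subset.

## Classification

LDA/QDA operates after PCA compression (default: smallest number of
components explaining 99 % of variance, capped at n/3) with equal class
priors — linear uses the pooled covariance, quadratic per-class
covariances, ridge-regularized with a warning if singular. The SVM is a
C-SVC with RBF or polynomial kernel; (C, γ) are chosen by exhaustive
grid search under the same fixed 10-segment CV (default grid
C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ in ×4 steps), ties resolved toward smaller C
then smaller γ, and both training and cross-validated accuracy are
reported. Because resubstitution and CV accuracy can differ materially,
the classification report always labels which is which.

## Chemical mapping

The fitted chain + β are applied to every foreground pixel's spectrum
independently; background stays missing. Pixels whose pre-treatment is
undefined (an all-constant spectrum under SNV, possible at bean edges)
become missing values and are counted per bean rather than raised. The
per-bean annotation is the arithmetic mean of that bean's pixel
predictions. For linear chains (none, mean centering, Savitzky–Golay)
this mean equals the prediction of the bean's mean spectrum exactly; for
nonlinear chains (SNV, MSC) the two differ, and the per-object table
keeps both paths computable so the discrepancy is never hidden.

## The synthetic scene generator

The generator is the package's study population, not a toy. Each bean is
an axis-aligned ellipse (jittered radii 10–16 px) placed without overlap
on a dark stage (background reflectance 0.05, hence absorbance ≈ 1.3,
guaranteed to fail the foreground rule). Per-pixel absorbance is a
Beer–Lambert mixture of four synthetic components built from Gaussian
bands at the wavelengths where the corresponding chemistry absorbs:
water (1450, 1940 nm; global maximum at 1940 nm), lipid (1210, 1360,
1725, 1760, 2310, 2345 nm C–H bands), a caffeine/chlorogenic-acid-like
species marker (1475, 1680, 2140 nm), and a broad featureless
carbohydrate/protein matrix. Amplitudes are scaled so a typical bean
sits in 0.1–1.0 AU.

Compositions reproduce the reference statistics of the population this
pipeline models: natural moisture 10.80 ± 0.79 % shared between species;
total fat 16.41 ± 3.10 % dmb overall, or species-split
17.51 ± 2.21 % (arabica) versus 12.63 ± 1.85 % (robusta) in two-species
sets; fat on an "as is" basis is derived as dmb × (1 − moisture/100).
The species marker is drawn at 0.020 ± 0.004 mass fraction for arabica
and 0.040 ± 0.006 for robusta, reflecting the roughly twofold caffeine
and chlorogenic-acid excess of robusta. This marker matters: the two
species' fat distributions overlap enough that fat alone supports only
~89 % discrimination, while real whole-spectrum classification of the
two species is near-perfect — the marker is the generator's model of
that additional chemistry.

Each pixel's mixture absorbance is degraded by the standard scatter
model that SNV/MSC assume — a per-pixel multiplicative gain N(1, 0.07)
and additive offset N(0, 0.03 AU) — plus N(0, 0.005 AU) detector noise
per band, then folded through the camera model: R = 10^(−A), raw counts
= dark + R·(white − dark) with a smooth illumination profile between a
dark level of 120 and a white level of 9000 counts, and reference-frame
noise attenuated by averaging 100 recorded frames. Within each bean,
moisture rises mildly toward the core and fat toward the surface
(relative amplitude 0.08 against the normalized squared elliptical
radius) so chemical maps are non-constant; no measured within-bean
statistics exist for these constituents, and the gradient magnitude is
an arbitrary, documented choice. The per-bean values stored as ground
truth are the exact means over each bean's pixels. One seed drives all
randomness, and scenes are bit-reproducible.

What the generator does *not* emulate: radiative transfer in a 3-D
kernel (specular highlights, edge shading, penetration depth),
wavelength-dependent illumination drift, partial-volume mixing at bean
boundaries, detector nonlinearity beyond 16-bit clipping on disk, or
measured coffee spectra (components are synthetic Gaussians at cited
band positions). Consequently, passing tests demonstrate that the
algorithms are implemented correctly and behave as the theory predicts
under realistic noise and scatter — linear-mixture recovery, scatter
removal, ordering of reduced-band models — but say nothing about
prediction error on physical beans, where published single-bean
calibrations of this kind reach R²cv ≈ 0.86–0.89 and RPD ≈ 2.9–3.2. On
the linear synthetic population the same pipeline is substantially more
accurate (RPD > 10); that gap is the expected signature of real spectra
containing chemistry and physics the generator deliberately omits.

## Numerical choices and degenerate inputs

* "Band at λ nm" means the nearest grid wavelength; ties break to the
  lower wavelength. The foreground threshold is a strict inequality.
* Reflectance is floored at 1e-6 before the log; calibration raises
  (naming the band) if white ≤ dark anywhere.
* SNV/normalize raise on constant/zero rows when used on tables, but at
  pixel level (mapping) such pixels become counted missing values. The
  mapping-level SNV guard uses a relative tolerance (sd > 1e-10 ×
  spectrum magnitude), since a numerically-constant pixel makes the SNV
  scale meaningless without being exactly constant in floating point.
* MSC raises when a spectrum is orthogonal to the reference
  (|b| < 1e-12); cross-validated chains refit the reference per fold.
* `max_lv` is truncated with a warning when it exceeds what the smallest
  training fold can support; NIPALS raises if the X residual becomes
  orthogonal to y before the requested component count.
* ENVI counts are written as little-endian uint16 (14-bit detector
  headroom), calibrated data as float32; the in-memory pipeline is
  float64 throughout, and the exactness guarantees (round-trip identity,
  β-form equivalence) refer to the in-memory path.

## Problem sizes

Tests and the acceptance script scale the study down so the whole suite
runs in minutes on one core: calibration tables of 120–300 beans at 256
bands, scenes of 150 × 180 px with 6–20 beans at 64 bands for
image-level checks (the coarser spectral axis leaves all band positions
resolvable and the radiometric chain unchanged), 10–20 replicates for
median/ordering assertions, and reduced SVM grids (C ∈ {1…10³},
γ ∈ {10⁻³…10⁻¹}) that bracket the optimum found on this data. The
statistical margins (3 SE moment checks, binomial CIs at 99 %) are set
so the suite is deterministic under its fixed seeds and robust to seed
changes.

## Known limitations

Single-response PLS1 only (one model per constituent); no uncertainty
intervals on predictions; no calibration transfer between instruments;
no splitting of touching kernels; dorsal/ventral spectra of the same
bean are treated as separate observations; pixel-level accuracy claims
are confined to synthetic scenes, where ground truth exists.
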