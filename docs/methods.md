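# Methods

`ovospec` implements a complete hyperspectral egg-freshness grading
pipeline — from raw scene cubes to a stacked-ensemble accuracy report — and
a synthetic-data generator that stands in for the original hyperspectral
cubes, which were never publicly deposited.  This note records the models,
the tunable parameters, the design choices that were genuinely open, and
what the synthetic results do and do not show about real eggs.

## Freshness model

Egg freshness is quantified by the Haugh unit,

    HU = 100 · log10(h + 7.57 − 1.7 · w^0.37),

with `h` the thick-albumen height in mm and `w` the egg weight in g.  "lg"
in the source formula is read as log base 10, the standard Haugh
convention.  During room-temperature storage HU declines approximately
linearly; the generator uses

    HU(day) = 85.70 − 1.75 · day + ε,   ε ~ N(0, 4.0²),

for days 1–28.  The noise sd of 4.0 sits inside the weekly HU standard
deviations reported for real cohorts (3.6–5.5).  Grades AA/A/B1/B2 are
*defined as the storage week* (`ceil(day/7)`), not by HU thresholds: the
published weekly HU ranges have gaps between grades (e.g. 72 → 70.5), which
makes threshold-based labelling ambiguous.  Protein height is back-solved
from HU and weight so the `(h, w) → HU` round trip is exact by
construction.  Days beyond 28 (spoiled, grade C) are out of scope and
rejected.

A consequence worth stating plainly: since an egg's spectrum depends on the
day only through its noisy HU, no classifier can label weeks better than
the Bayes rule on HU itself.  With noise sd 4.0 and a 1.75/day slope that
ceiling is ≈ 0.80 accuracy; the synthetic study therefore reproduces the
published *ordering* of acquisition modes, not the published accuracy
levels (see "What the generator shows" below).

## Spectral generator

Each spectrum on the 400–1000 nm axis (256 bands by default, the VNIR
camera range at desk scale) is a three-endmember mixture

    S(λ) = α · S_int(λ; HU) + (1 − α − β) · S_shell(λ) + β · S_src(λ),

phenomenologically encoding how the collected light decomposes into light
scattered through the interior (the only freshness-bearing component),
light reflected off the shell, and raw source bleed-through:

* `S_int` is a smooth base curve plus Gaussian absorption peaks at
  450/550/680/980 nm whose amplitudes are affine in (HU − 60)/30, with
  alternating signs.  The amplitude slopes (~0.02 reflectance units per 30
  HU) set the freshness signal against the 0.01 per-band channel noise so
  that HU readout precision degrades materially as α falls.
* `S_shell` is a smooth ramp (brighter toward the NIR, a pigment dip near
  560 nm) plus a per-spectrum random shell-colour perturbation: a broad
  tilt and a pigment-band component with coefficients ~ N(0,
  `shell_color_sd`²), default 0.12.  Shell colour is informative of
  nothing, so modes dominated by shell light are both weak in signal and
  rich in structured nuisance — the mechanism that makes reflectance-based
  freshness models fragile on real eggs.  At 0.12 the nuisance dominates
  the grade signal beyond mid angles, which makes the accuracy-vs-angle
  ordering a structural property rather than a marginal one.
* `S_src` is flat (normalised source output); glare pixels in rendered
  scenes carry it directly.

Mode mixing fractions: α = 0.9 − 0.01·θ for the fibre source at incident
angle θ (0.9 at 0°, 0.3 at 60°), α = 0.05 for dome reflection, and
α = 0.45 with β = 0.35 for transmission.  Spectra are then distorted by a
global multiplicative factor N(1, 0.10²), a global offset N(0, 0.05²) — the
work MSC/SNV/detrend exist to undo — and per-band noise N(0, 0.01²).
Negative values are clipped at 0 (physical range; clips are rare at the
default noise and logged).  The random stream is consumed identically
whatever the sd values, so a zero-noise config with the same seed
reproduces the same draw positions.

Scenes are rendered as `(lines, samples, bands)` cubes: background at
reflectance 0.15, elliptical egg regions shaded Lambertially in [0.6, 1],
three glare pixels per egg, a wavelength-dependent gain ≥ 1, a constant
dark level, and matching white/dark calibration frames whose noise is 10%
of the raw channel noise (calibration frames are averages of many
acquisitions).  Black/white correction `R = (I0 − Ib)/(Iw − Ib)` then
recovers shading × spectrum up to noise, which the ROI tests verify by
direct substitution against a zero-noise render of the same seed.

## Pipeline

* **Correction** is per-cube and unclipped (glare legitimately exceeds the
  white reference); a pixel where white equals dark raises with the pixel
  named — a corrupted calibration should fail loudly, not propagate NaN.
* **ROI extraction**: pseudo-RGB at 650/550/450 nm (nearest band, ties to
  the lower wavelength), Otsu threshold by default, dilation-then-erosion
  with a 2 px disk, 8-connected components numbered in raster order of
  centroid, per-component ellipse at the centroid with semi-axes half the
  bounding extents inflated by 1.05, unweighted mean spectrum per ellipse.
  The threshold and structuring-element size of the original workflow are
  unreported; these defaults are not calibrated to any real images.
* **Preprocessing**: msc, snv, norm (row min-max), auto, mc, ma, detrend
  (order-2 per-row polynomial baseline), sg, sg-fd, sg-sd.  Column-wise
  methods and MSC carry training statistics only (leak-free fit/transform
  contract).  SG windows are unreported in the source work; defaults are
  window 11, polyorder 2, MA window 5, all exposed.  SG uses polynomial
  edge interpolation (`mode="interp"`), which keeps the band count constant
  and is exact on polynomials up to the fit order at every point.
  "Detrend" is implemented as chemometric polynomial detrending, not
  detrended-fluctuation analysis proper; the two readings cannot be
  distinguished from the published tables.  Standard deviations are sample
  (n−1) throughout.
* **Wavelength selection**: PCA keeps the first 3 PC scores as features
  (the loading-based wavelength reading is exposed as diagnostics only);
  SPA grows minimally-collinear chains from every start band and scores
  lengths 5–30 by 5-fold CV RMSE of a linear regression on the numeric
  grade code; CARS runs 100 Monte-Carlo iterations of 80% subsampling, PLS
  coefficient weighting, an exponential enforced-retention schedule
  r_i = a·e^(−k·i) with a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1) (all p bands
  at run 1, exactly 2 at run N), and adaptive reweighted resampling; the
  survivor set with minimum 5-fold RMSECV wins.  The PLS component count is
  chosen once per CARS call by 5-fold CV on the full training matrix
  (capped at 10 and at the design rank) and reused across runs; a per-run
  inner CV would cost ~10× for no change in the recovered subsets on
  planted-signal data.  The regression target for SPA/CARS is the grade
  code 1–4, since the imaged cohort has no measured HU values.
* **Classifiers**: SVM (RBF, C=1, gamma scaled), KNN (k=5, Euclidean), RF
  (100 trees, seeded), Gaussian NB, DAC (Gaussian discriminant, pooled
  linear covariance by default, quadratic optional, automatic shrinkage on
  a singular covariance), and LDA as Fisher projection + nearest centroid.
  The source work lists "LDA (latent Dirichlet allocation)", which is a
  topic model and cannot consume real-valued spectra; the discriminant
  reading is the only coherent one.  All kinds expose class probabilities.
  The split is stratified 71.43/28.57 (280 → 200/80, 50/20 per grade), so
  every test accuracy is a multiple of 1.25%.
* **Stacking**: the three classifier kinds with the best grid accuracy form
  the first layer; training-row meta-features are out-of-fold class
  probabilities from 5 stratified folds, test-row meta-features the mean of
  the five fold models' probabilities; the second layer is DAC by default.
  Probability meta-features (not hard labels) are the default because
  averaging fold predictions for test rows is only well-defined for
  probabilities; a hard-label mode exists behind a flag.  Leak-freedom is
  verified by label-flip invariance: flipping sample i's label (with the
  fold geometry pinned) cannot change row i of the meta-feature matrix.
* **Best-model selection** mirrors the published tables (max test accuracy,
  ties by training accuracy then lexicographic pipeline id).  Selecting on
  test accuracy is itself a mild leak; it is kept because the report is a
  reproduction of that table structure, and the stacked comparison is run
  on the same split.

## What the generator shows — and what it does not

The acceptance experiment (280 eggs × 9 modes, SNV + PCA scores +
DAC/KNN/RF + stacking per mode, 10 seeds) reproduces the qualitative
structure of the original study: stacked accuracy is maximal for 0°
scattering, decreases with incident angle (negative Spearman correlation),
and dome reflection performs near chance.  The absolute accuracies are
*lower* than the published ones (≈0.75 at 0° rather than 0.96–1.00):
the synthetic cohort's HU noise bounds attainable accuracy at ≈0.80, and
real spectra plausibly carry freshness information beyond HU (air-chamber
geometry, albumen pH) that the generator deliberately omits.  Passing tests
therefore certify the pipeline's mechanics and the direction of the angle
effect, not field-level accuracy on real eggs.

Other simplifications: no radiometric realism (no source spectrum model,
no shell-pigment chemistry), no SWIR range, independent shell draws per
mode for the same egg, and scenes far smaller than real conveyor frames.

## Numerical choices

Ties in nearest-band lookup go to the lower wavelength; SPA breaks
projection-norm ties at the lowest band index and truncates chains whose
residual norm falls below 1e-10 of the column scale; PCA contribution
rates are eigenvalue shares over all components (summing to 100%); the
CARS schedule endpoints are pinned exactly (guarding float round-off);
batched fold regressions add a 1e-10 ridge for stability; degenerate PLS
(zero cross-covariance) returns exactly zero coefficients.  Problem sizes
in the test suite (cohort sizes, seed counts, CARS run counts) match the
study design where stated — 280-egg cohorts, 140-egg calibration fits,
100 Monte-Carlo runs — with smaller cohorts used only in unit tests of
mechanics.
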