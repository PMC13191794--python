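# Methods

## Scope and model

`sonotexture` implements a texture-radiomics analysis of obstetric
ultrasound for predicting postpartum blood loss in pregnancies with
placenta previa or a low-lying placenta. The unit of analysis is a
subject with up to six rectangular 5 × 5 mm regions of interest (ROIs):
three tissues — placenta, placental underlying myometrium (PUM), free
myometrium (FM) — at two gestational windows (20 and 30 weeks). Each
ROI is summarized by 6 first-order and 13 gray-level co-occurrence
(GLCM/Haralick) features, 114 features per complete subject.

Blood loss (mL) is continuous and strictly positive, so effects are
modelled with a Gamma generalized linear model with a log link:
E[y|x] = exp(β₀ + Σⱼ βⱼxⱼ). Exponentiated coefficients are mean ratios
(MRs): the multiplicative change in expected blood loss per unit of a
predictor. Model building runs univariable screening (keep p < 0.05,
unadjusted — the screen is not confirmatory), AIC-based stepwise
search over the screened set starting from the full candidate model,
and Benjamini–Hochberg FDR adjustment of the final model's p-values.
Three models are compared: radiomics-only, clinical-only, and the
integrated union.

## Texture features

Quantization is per-ROI min–max into G = 32 equal-width bins (range
relative, so features are invariant to affine gray-scale shifts; a
constant ROI maps to level 0). The GLCM is accumulated at distance 1
in the four standard directions, symmetrically (each ordered pair
counted both ways), normalized per direction, and averaged; features
are computed on the averaged matrix. Note that only the matrix itself
is linear in the directions: nonlinear descriptors (entropies, the
information measures) of the averaged matrix are not the average of
per-direction descriptors, and the package makes no such claim.

All entropies are Shannon entropies in bits with 0·log 0 := 0. The
information measures of correlation use HX, HY, HXY, HXY1, HXY2 in
bits; by the Gibbs inequality HXY1 ≥ HXY, so imc1 ≤ 0 always, and
imc2 = √(1 − exp(−2 ln 2 · (HXY2 − HXY))) ∈ [0, 1]. Sum variance uses
the corrected modern convention (second moment of the sum distribution
about the sum average); the original-publication variant that centres
on sum entropy is available via `GLCMConfig(sum_variance_mode=
"original")` because published Haralick implementations disagree on
this point. First-order moments use the denominator-n convention and
excess kurtosis.

Degenerate inputs never raise during batch extraction: for a constant
ROI, correlation and imc1 are defined as 0 (flagged), first-order
skewness/kurtosis/entropy as 0, and the variance of a point-mass
difference distribution as 0.

## Feature selection

Order: min–max normalization to [0, 1] (constant columns flagged and
zeroed) → greedy correlation pruning at |r| > 0.9 (the member of an
offending pair with the larger mean absolute correlation is dropped;
lexicographic tie-break) → permutation-importance ranking → top-15
retention. The ranking trains a random-forest regressor (500 trees,
⌈p/3⌉ features per split) inside 10-fold × 3-repeat cross-validation;
a feature's importance is the mean increase in held-out squared error
when its column is permuted, averaged over the 30 resamples.
Permutation importance was chosen over impurity importance because the
latter is biased toward high-cardinality features. Pearson correlation
is the default for pruning (Spearman selectable); all of
trees/folds/repeats are arguments. The composed selector is
deterministic given one integer seed.

## Regression conventions

Fitting is IRLS (via statsmodels) with Gamma variance and log link.
Dispersion φ is the Pearson estimator χ²/(n − p); the Wald covariance
is φ(XᵀWX)⁻¹ with z = 1.96 intervals (CI = exp(β ± 1.96·SE)), matching
symmetric exp-transformed intervals. The log-likelihood and AIC use
the moment plug-in shape k = 1/φ re-evaluated per candidate model,
with AIC = −2ℓ + 2(p + 1) counting the dispersion; only AIC
differences matter for the stepwise search, which stops at a local
minimum and accepts an intercept-only endpoint. The stepwise search
space is exactly the screened candidate set — variables rejected at
screening are never re-admitted.

## Validation

Events are defined by strict inequalities (blood loss > 500 mL,
> 1000 mL). AUC is the Mann–Whitney concordance of predicted blood
loss with ties at 0.5; its variance and the paired two-model test use
DeLong's placement values. Internal validation is bootstrap optimism
correction with the term set held fixed ("refit the same model"):
per resample, optimismᵦ = AUC(fitᵦ on the resample) − AUC(fitᵦ on the
original sample); corrected = apparent − mean optimism; the 95% CI is
the 2.5/97.5 percentile band of the test AUCs. Resamples with a
single outcome class are redrawn and counted. Apparent AUC CIs are
DeLong-based; corrected CIs are percentile-based. The bootstrap is
unstratified.

A caveat measured during development: with many pure-noise predictors
(10 predictors, n = 100) the optimism estimate is itself slightly
optimistic — the corrected AUC retains a residual of roughly 0.04–0.05
above 0.5 on average, with a per-run standard deviation near 0.05.
This is the known behaviour of the estimator (the "test" sample in
each iteration overlaps the training draw), not an implementation
artifact; the test suite therefore checks the residual on the mean
over 60 replicates.

Calibration is the least-squares line of observed on predicted blood
loss on the mL scale (ideal slope 1, intercept 0); since the
calibration operation sees only (observed, predicted) pairs, its bias
correction is the classic bootstrap bias estimate — corrected =
apparent − (mean bootstrap estimate − apparent) — rather than a
model-refitting loop, which lives in the AUC optimism routine where
the model recipe is available.

Reliability uses ICC(2,1) — two-way random effects, absolute
agreement, single measure — from the ANOVA mean squares, with the
F-based confidence interval (Satterthwaite denominator df) and the
Koo–Li bands: poor < 0.50 ≤ moderate < 0.75 ≤ good < 0.90 ≤ excellent.

## Power analysis

The a priori sample-size computation is the generic linear-model
F-test approximation parameterized by Cohen's f²: with u tested
predictors, v = N − u − 1 denominator df and noncentrality
λ = f²(u + v + 1) = f²N, power = P(F(u, v, λ) > F₀.₉₅(u, v)). The two
textbook noncentrality conventions λ = f²(u+v+1) and λ = f²N coincide
under this df convention. Required N is the smallest integer reaching
the target power ("at least N participants"); for f² = 0.15, α = 0.05,
power 0.80 this gives N = 55 for one predictor and N = 103 for seven.

## Synthetic cohorts

No patient data ship with the package; every downstream stage is
exercised on generated cohorts with known ground truth. Texture is a
stationary correlated Gaussian field: white noise smoothed by a
Gaussian kernel of scale `correlation_length` (pixels, toroidal
boundary), re-standardized, optionally passed through the monotone
tilt z ↦ (exp(s·z) − 1)/s whose skewness carries the sign of s (a
plain exponential tilt exp(s·z) is right-skewed for either sign, so
it cannot encode skew direction), then mapped to the target mean/SD
on the 8-bit scale and clipped. Patches are 64 px ≈ 5 mm
(0.078 mm/px).

Planted effects act through per-subject latent z-scores of the
generator parameters: the rendered patch uses base + scale·z while the
outcome's linear predictor uses z itself. Extracted features are
therefore noisy surrogates of the planted signal, and
parameter-recovery tests use tolerance bands rather than equalities.
Blood loss is Gamma(shape k, mean exp(β₀ + Σβx)).

Default emulation (107 subjects): clinical prevalences 16/107
(previous cesarean), 38/107 (previa at enrollment), 85/107
(resolution) with log-mean effects ln 1.96, ln 1.37, ln 0.54; three
texture effects of ±0.20–0.30 per latent SD; k = 3.0 and
β₀ = log 650, chosen once by a coarse grid against the emulation
targets, giving a marginal median ≈ 425 mL and event rates ≈ 0.43
(> 500 mL) and ≈ 0.15 (> 1000 mL). The generator reproduces
second-order texture statistics and outcome structure only: it does
not model ultrasound speckle physics (Rayleigh/K distributions),
attenuation, anatomy, or acquisition variability, so passing tests
demonstrate correctness of the pipeline's statistics, not clinical
performance on real images. All randomness descends from one integer
seed through spawned per-subject streams, so any patch is reproducible
in isolation.

## Problem sizes used in the test suite

Validation studies in the shipped tests use sizes chosen to make the
Monte-Carlo error small relative to the tested bands: 200 cohorts of
n = 300 for Wald coverage; 20 seeds at n = 300 with 31 features for
selection recovery (forest size 200 there, and 150 trees with 5 × 2
cross-validation inside the 20-seed end-to-end comparison, which keeps
the planted-signal recovery well above the tested thresholds); 60
replicates of the n = 100, 10-predictor null for the optimism
residual; B = 100–200 bootstrap draws where a full 1000 would only
polish the third decimal. The library defaults remain 500 trees,
10 × 3 repeats, and B = 1000.

## Known limitations

- The KS normality screen estimates the normal parameters from the
  sample, which makes the nominal p-value conservative (the Lilliefors
  correction is not applied); at n ≲ 200 mild non-normality is often
  not flagged.
- DICOM support covers uncompressed monochrome pixel data only;
  anything else should be exported to PNG first.
- The correlation-pruning order (before importance ranking) means a
  pruned feature can never be ranked, even if it would have scored
  higher than its retained partner.
- Apparent AUCs of the three models are in-sample; only the optimism
  loop provides internally validated estimates.
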