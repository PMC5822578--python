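# Methods

## The model

`hippolcs` implements a two-wave latent change score (LCS) structural
equation model coupling one hippocampal MRI biomarker to three latent
cognitive domains. Let the structural variables for one model be

    eta = (B_lev, B_chg, L_vm, L_wm, L_sp, D_vm, D_wm, D_sp) ~ N(alpha, Psi)

with Psi an unrestricted symmetric positive definite 8x8 covariance.
Wave-3 constructs are defined through fixed unit paths with zero
disturbance,

    level_w3 = level_w2 + change,

so each change variable is exactly the latent difference between occasions.
The biomarker is manifest at both waves: its wave-2 column *is* `B_lev` and
its wave-3 column is exactly `B_lev + B_chg` (no residual), so its change is
a manifest difference score, not an error-free latent. Each cognitive domain
is measured by the same tests at both waves under strong measurement
invariance (equal loadings and equal intercepts across waves); indicator
residual variances are free per wave and uncorrelated across waves.

Identification: the first indicator of each domain is the marker with
loading fixed to 1, cognitive level means are fixed to 0 (indicator
intercepts carry location), and all change means are free. The default
9-test roster gives p = 20 observed variables, 74 free parameters, and
20*21/2 + 20 - 74 = 156 degrees of freedom. An alternative 12-indicator
roster (memory and span subtests entered separately) is supported through
the indicator map; it changes p and df but nothing else.

Interpretation of the structural surface: the 12 biomarker-cognition
entries of corr(Psi) are typed as level-level, cognitive-level ->
biomarker-change, biomarker-level -> cognitive-change, and change-change
correlations; change means are reported both in native units and divided by
the model-implied baseline-level SD ("a change of x baseline SDs").

## Estimation

Parameters are estimated by full-information maximum likelihood (FIML):
rows are grouped by missingness pattern and each pattern contributes the
Gaussian log-density of its observed sub-vector under the corresponding
sub-moments, which is valid when data are missing at random (MAR). The
log-likelihood uses pattern-level sufficient statistics, so cost is
independent of n given the patterns.

Numerical choices:

- The structural covariance is parameterized by a log-Cholesky factor and
  indicator residual variances on the log scale, so every parameter vector
  maps to an admissible covariance; inadmissible/non-finite points return a
  sentinel value that is safe inside a line search.
- Optimization is quasi-Newton (L-BFGS-B) with an analytic score in
  (mu, Sigma) chained through a central-difference Jacobian of the
  (data-free) moment map; convergence at projected gradient < 1e-6 and
  relative log-likelihood change < 1e-10, max 5,000 iterations. The fit
  never returns a point below the starting value.
- Internally, data are rescaled to roughly unit variance per variable (one
  scale per variable, shared across waves, preserving the unit paths and
  invariance constraints); the solution and its covariance are mapped back
  to native units by the exact affine reparameterization. This removes the
  ill-conditioning caused by native units spanning eight orders of
  magnitude (mm^3 vs unitless FA).
- Starting values come from complete-case moments: marker-regression
  loadings, half-variance residuals, and structural covariances at half the
  complete-case covariance of marker level/difference proxies, eigenvalue-
  floored to be admissible.
- ML covariance divisor is n throughout, matching the likelihood.
- Standard errors are observed-information (numerical Hessian of the
  gradient, central differences, step 1e-4 x max(|theta|, 1)); standardized
  estimates and SD-unit change means get delta-method SEs; Wald two-sided
  p-values. A non-positive-definite Hessian falls back to a pseudo-inverse
  with the SEs flagged.
- Rows with every analysis variable missing are dropped and counted.

The saturated reference model (free mu and Sigma) is fitted by EM for the
incomplete multivariate normal (it reduces to sample moments on complete
data); the independence baseline (free means and variances, zero
covariances) is closed form per column. chi-square = 2(ll_sat - ll_model),
floored at zero; RMSEA = sqrt(max(chi2 - df, 0)/(df*n)) with the total
analysis n (not n-1); CFI and TLI from the baseline chi-square, TLI
reported unclamped alongside a [0,1]-clamped companion because conventions
differ.

The Benjamini-Hochberg step-up FDR correction is applied per model to the
family of 12 biomarker-cognition structural correlations; cognitive-
cognitive covariances are excluded from the family (the source analysis
corrects "the structural section of each model separately" without
enumerating the family; the 12-test family is this package's documented
choice).

## Pre-model adjustments

All cognitive scores are oriented so higher = better (choice reaction time,
a latency, is negated; orientation precedes residualization). Every
analysis variable is adjusted for sex and age in days at its own
measurement occasion (scan age for biomarkers, test age for cognition) by
per-column complete-case OLS.

The pipeline's default residualization centers the *predictors* rather than
the outcome: `residual = y - b_sex (sex - mean) - b_age (age - mean)`. This
removes the sex/age variance components while preserving each column's
location. Classical residualization (mean-zero residuals at every wave)
would also zero the wave-3 means and thereby erase the between-wave mean
change that the models are meant to estimate; predictor-centering keeps the
longitudinal signal while leaving all covariances identical to classical
residuals. The classical behaviour remains available via
`keep_location=False`.

## The synthetic cohort generator

No participant-level data accompany the source analysis, so the generator
is the test bed: it emulates the statistical structure the model assumes,
calibrated to the published tables.

- Structural variables are generated in standardized (baseline-SD) units
  and mapped to native units via the published wave-2 SDs; levels have unit
  variance.
- For each biomarker, the change SD and level-change covariance are derived
  in closed form from its published cross-wave stability r and wave SD
  ratio k: `cov = r*k - 1`, `var = k^2 + 1 - 2*r*k`, which reproduces both
  the stability and the wave-3/wave-2 variance ratio exactly.
- Cognitive latent change SDs default to 0.5 baseline-SD per domain. The
  published mean-change z-statistics would imply change SDs near 1, but
  that is incompatible with the published test-level stabilities (an
  indicator cannot be more stable than its factor); 0.5 is consistent with
  the stabilities and the wave SD ratios, and the z-statistics are not
  recovery targets.
- Indicator reliabilities are set as test stability divided by latent
  stability; loadings are sqrt(reliability) x wave-2 SD, wave-3 residuals
  absorb the published wave-3 SDs.
- The biomarker-cognition cross-correlations are the published standardized
  path table, one column per biomarker, kept separate. The five biomarkers
  are drawn conditionally independent given the 6-variable cognitive block
  by Gaussian conditioning, which reproduces each model-relevant 8x8
  structural block exactly; implied biomarker-biomarker correlations are a
  by-product and are *not* calibrated (no model uses two biomarkers
  jointly).
- Cognitive cross-domain level correlations (0.58, 0.49, 0.70) were
  estimated once from the published wave-2 inter-test correlation block
  with attenuation correction; own-domain level-change correlations come
  from the published baseline-vs-decline correlations; cross-domain
  level-change correlations default to 0 and change-change correlations to
  0.30 (not published; fixed plausible values).
- Mean changes are calibrated to the published standardized (SD-unit)
  changes. The published wave-3 means are arithmetically inconsistent with
  those SD-unit changes (complete-case vs full-sample reporting), so
  generated wave-3 means follow the SD-unit changes, not the printed wave-3
  means.
- Attrition: each participant returns at wave 3 with probability
  `logistic(a + 0.5 g)`, where g is the *observed* standardized baseline
  cognitive composite (mean of oriented z-scored tests) — strictly MAR
  given model variables. The intercept is solved numerically so expected
  returners equal the target n (655 -> 469 by default). Attrition blanks
  all wave-3 measurement columns and never alters wave-2 values.
- Ages: wave-2 test age ~ N(72.50, 0.71) years in days; inter-wave gap 3.74
  years with 30-day jitter; scan ages offset from test ages by the
  published test-scan gaps. Sex effects on measures default to zero (the
  source residualizes them out rather than reporting them); a configurable
  shift exists for testing the residualizer.
- MMSE: per-person trait N(28.5, 2.1) correlated 0.6 with general cognitive
  level, observed with 0.8 wave noise, rounded and censored at 30;
  parameters chosen so the sub-24 rate matches the published 19/1091.

What the generator does *not* emulate: non-normal test-score distributions
(floor/ceiling effects, discreteness), item-level structure, scanner drift
or acquisition artifacts, practice effects, non-random within-wave
missingness (wave-2 missingness beyond attrition is off by default), and
MNAR dropout. Passing recovery tests therefore show that the estimator
recovers the truth under the model's own assumptions plus MAR attrition —
they do not certify behaviour under real-data violations of those
assumptions.

## Study sizes used by the test suite

Recovery studies run the full 20-variable models at the study's design size
(n=655 with attrition to ~469; 20 replicates for calibrated recovery, 50
for the MAR-unbiasedness study). Distributional calibration checks
(chi-square vs df; Wald coverage) use a two-domain sub-model and/or the
null calibration so that 100-200 replicates remain cheap; the sub-model
exercises the same code paths with fewer free parameters. The stability
check uses a single n=10,000 cohort.

## Known limitations

- Strong invariance is imposed, not tested; partial-invariance rosters are
  out of scope.
- No robust (sandwich) or bootstrap SEs, no multiple imputation — FIML is
  the stated mechanism of the source analysis.
- The saturated EM fit assumes enough complete information per variable
  pair; with pathological patterns (a pair never jointly observed) the
  saturated covariance is weakly identified.
- Wald inference on correlations near the +/-1 boundary is unreliable; the
  calibrated values here are well inside the interior.
- The printed df of the source fit table (279) corresponds to a 12-indicator
  roster; with the default 9-test roster the model df is 156, and the fit
  table printed by this package reports that value.
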