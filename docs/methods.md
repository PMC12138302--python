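# Methods

This note documents the statistical model, the numerical choices behind the
implementation, the synthetic-cohort generator, and the known limitations.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

Each user is modelled independently. Daily steps on the offset grid around
the registration date (day 0) follow a linear-Gaussian structural time
series: a local linear trend (latent level plus latent slope, each a
Gaussian random walk), a period-7 seasonal component whose states sum to
zero in expectation over any week, a static linear regression on four daily
weather covariates (mean temperature °C, precipitation mm, sunshine hours,
mean wind speed m/s), and Gaussian observation noise. The pre-period is
exactly offsets −28..−1 (28 days — the device backfill window bounds how
much pre-registration history exists); the registration day itself is used
for neither training nor inference.

Assumptions worth making explicit:

* steps are modelled on the raw count scale, not log-transformed, and the
  counterfactual is *not* truncated at zero — truncation would bias the
  pointwise impact toward positive values;
* the weather coefficients are static (no time variation) — with four
  covariates and 28 observations, a dynamic regression is not identifiable;
* users are exchangeable and independent given their own series; the
  cohort effect is a population mean of per-user effects, not a pooled
  hierarchical estimate.

## Posterior computation

A Gibbs sampler alternates:

1. a joint draw of the state path by forward-filter backward-sampling
   (Carter–Kohn) given the variances and regression coefficients, with the
   Kalman filter skipping missing days (prediction only, no update);
2. conjugate inverse-gamma draws of the observation-noise and three
   state-noise variances from the sampled disturbances;
3. a conjugate Gaussian draw of the regression coefficients (optionally a
   stochastic-search spike-and-slab step with a N(0, slab²)/N(0, spike²)
   mixture and Bernoulli(0.5) prior inclusion).

Sampling happens on a standardized scale: y is centred and scaled by its
pre-period moments, covariates likewise. The centring constant is the
*rounded* mean — under the diffuse level prior any location is equivalent,
and rounding makes integer-valued series (step counts are integers) exactly
invariant to integer level shifts: shifting the data by a constant yields a
bit-identical chain and counterfactual medians shifted by exactly that
constant.

The default chain is 1000 iterations with the first 100 discarded; the
cohort pipeline uses shorter chains (300 iterations, 50 burn-in) because
cohort means average over hundreds of users and are insensitive to
per-user Monte-Carlo error. The acceptance script runs a 300-user cohort
at those settings. All randomness descends from a single seed through
`numpy.random.SeedSequence` spawning (one child per user, one for the
counterfactual forecast), so results are independent of worker count under
`--jobs` parallelism.

### Priors

Variance priors are inverse-gamma, parameterised as an
observations-equivalent weight and a variance guess on the standardized
scale:

| component          | weight | guess (variance) | rationale |
|--------------------|--------|------------------|-----------|
| observation noise  | 0.01   | 0.5              | essentially likelihood-driven; the residual variance is the best-identified parameter |
| level noise        | 32     | 1e-4 (sd 1% of data sd) | keeps the trend smooth on a 28-day window, the counterfactual's main stabiliser |
| slope noise        | 32     | 1e-4             | a wiggly slope extrapolates noise into the forecast |
| seasonal noise     | 32     | 1e-4             | the weekly pattern should be near-static over 8 weeks |

A heavy, tight prior on the *observation* noise instead (weight 32 at a
small guess) was considered and rejected: with 28–200 observations it
drags the residual variance toward the guess and visibly degrades the
frequentist calibration of the σ_ε credible interval on model-simulated
data, which the acceptance suite checks. Putting the informative mass on
the state noises and leaving σ_ε weakly informed matches how reference
counterfactual-impact tools set their defaults and is what the calibration
study supports. All four priors are configurable through `BstsSpec`.

The regression prior is N(0, 1) per standardized coefficient (spike sd
0.01 in spike-and-slab mode). With only four covariates, selection is not
essential, so the Gaussian prior is the default and spike-and-slab an
option.

### Numerics

* Initialization: approximate-diffuse, variance 1e6 per state on the
  standardized scale.
* The backward sampler adds a scale-adaptive jitter before each Cholesky
  factorization, starting at 1e-14 × (largest diagonal) and escalating
  tenfold only on failure. The starting point matters: a jitter sized
  proportionally to the 1e6 diffuse variance (e.g. 1e-9 × scale) injects
  artificial noise into the early-sample state draws, which the conjugate
  variance updates then mistake for state disturbances — in testing this
  inflated the slope and seasonal variance posteriors by an order of
  magnitude and biased σ_ε low. With the small base jitter the sampler's
  state moments match an independent exact smoother and σ_ε is recovered
  without visible bias.
* Counterfactual forecasting propagates each draw's final pre-period state
  through the transition equation, including one silent step across the
  skipped registration day, and adds observation noise (posterior
  predictive intervals).
* Filtering is validated two ways in the test suite: against a brute-force
  joint-Gaussian density built explicitly from the implied n×n covariance,
  and against statsmodels' Kalman filter on the same matrices.

## Preprocessing rules

* Manual pedometer entries are discarded; only device-linked streams are
  analysed.
* Validity: values strictly below 200 or strictly above 50,000 steps/day
  are set missing (exactly 200 and exactly 50,000 are retained). Filtering
  is applied per stream *before* the two streams are merged by maximum, so
  an implausible reading on one device cannot mask a valid one.
* Imputation: a missing day becomes the mean of the non-missing among the
  previous 7 calendar days, processed chronologically so earlier
  imputations feed later ones; a day with no non-missing predecessor stays
  missing. The series starts at offset −35 precisely so day −28 has a full
  7-day history.
* Exclusion cascade, applied sequentially with each user counted at the
  first failing rule: (1) missing sex or birth date; (2) residence outside
  the target prefecture; (3) age (completed years at registration) outside
  20–79; (4) no linkable step data in the window; (5) missingness
  remaining in [−28, +P] after imputation. Users with no imputed values in
  the window form the complete-data subset used for sensitivity analysis.
* Strata: age decades 20-29..70-79; seasons spring=Mar–May, summer=Jun–Aug,
  fall=Sep–Nov, winter=Dec–Feb; Japanese fiscal year April 1–March 31
  labelled by its starting year; baseline bands <2000, 2000–3999, …,
  ≥12000 steps/day as half-open intervals [lo, hi+1).

## Cohort aggregation

The per-user point estimate is the posterior median of the average (or
terminal cumulative) impact — robust to the skew that short pre-periods
induce; the posterior mean is available by flag. The cohort estimate is
the arithmetic mean of per-user point estimates with a 95% CI of
±1.96·SD/√n across users. This treats per-user posterior uncertainty as
absorbed into across-user dispersion; the alternative (pooling posterior
draws across users) is isolated behind `aggregate_cohort` and could be
swapped in. One consequence, visible in the null-calibration tests: users
whose windows overlap in calendar time share weather-forecast errors, so
across-user CIs can be slightly anti-conservative for small cohorts
concentrated in one season.

Per-horizon cohorts (28/56/84/112 post days) are re-selected independently
— longer horizons demand longer linkage, so n is monotonically
non-increasing in the horizon by construction.

## Synthetic cohorts

The generator emulates what the analysis assumes about real data: per-user
baselines drawn from a moment-matched lognormal (default mean 5900,
SD 4100 steps/day — right-skewed, like real step data with median near
5000 and IQR roughly 3100–7200), a weekday/weekend cycle (weekends −800
steps/day by default), a linear weather response (temperature +15/°C,
precipitation −20/mm, sunshine +40/h, wind −30/(m/s) — magnitudes chosen
once as plausible for a temperate Japanese city), iid daily Gaussian noise
(default SD 1500 steps/day), and a post-registration level shift (default
360 steps/day, the magnitude the pipeline is designed to detect; an
optional exponentially decaying mode emulates attenuation over longer
follow-up). Demography defaults to a prefecture-scale Japanese app cohort:
38.5% men, age N(51.6, 13.2) truncated to 20–79, registrations weighted
toward spring and fiscal year 2020. Weather is an annual temperature
sinusoid (Osaka-like mean 17 °C, amplitude 11 °C, peak in early August)
with wet-day precipitation, truncated sunshine and wind.

Data pathologies are injected at configurable rates: whole missing days,
implausible values (<200 or >50,000) hitting both streams of a day, users
whose device never links, manual entries, and dual-stream disagreement (one
stream carries the true value, the other a nonnegatively perturbed copy,
so the max-merge recovers the truth whenever both survive filtering —
and the merge rule is actually exercised).

What the generator does *not* emulate — and hence what passing tests do
not establish about real cohorts: behavioural dynamics (engagement decay,
goal-seeking around step targets, reactivity to feedback), autocorrelated
or heteroscedastic daily noise, informative missingness (real users stop
carrying their phone on low-activity days), device-specific measurement
bias, and seasonal confounding between registration time and motivation.
Recovery of an injected effect on synthetic cohorts demonstrates that the
estimator is consistent and approximately calibrated under its own
assumptions, not that those assumptions hold for any particular app.

## Problem sizes used by the checks

The test suite and acceptance script scale the Monte-Carlo studies to
desk-scale sizes chosen as the smallest that leave the checks' tolerances
meaningful: 100 random parameter sets for the exact-filtering oracle;
50 replicates × 200 days × 2000 draws for σ_ε calibration; one 300-user
cohort (injected 500 steps/day) for end-to-end recovery plus 20 replicate
60-user cohorts for null CI coverage; 300 users at 300 draws for the
acceptance script's headline run.

## Known limitations

* With 28 pre-period days, per-user effects are very noisy (the local
  linear trend must be extrapolated 28 days); the design relies on
  cohort-scale averaging.
* The across-user CI ignores shared-weather correlation between users
  registering in the same week (see above).
* No hierarchical pooling: a user with a pathological pre-period gets a
  pathological counterfactual rather than shrinkage toward the cohort.
* The spike-and-slab step uses a fixed spike width rather than a
  point-mass prior; inclusion probabilities are interpretable but the
  coefficient draws are never exactly zero.
* Exact zero-variance posteriors (degenerate deterministic models) are
  supported in the forecasting path but the Gibbs sampler always keeps
  variances strictly positive through the inverse-gamma draws.
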