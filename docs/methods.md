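# Methods

## The scientific problem

Short-term exposure to fine particulate matter (PM2.5) raises the risk of
severe respiratory illness, but the effect is neither linear in concentration
nor confined to the day of exposure: an episode of haze can push a
susceptible person into intensive care several days later. The canonical
framework for this is the distributed lag non-linear model (DLNM), which
describes the outcome's dependence on an exposure jointly along two
dimensions — the exposure's value and the time elapsed since it occurred.
This package implements that analysis for daily ICU admissions for
pneumonia: a Poisson time-series regression of daily counts on a PM2.5
cross-basis, adjusted for temperature and day of week, together with the
companion admission-level logistic models at fixed single lags and the
descriptive cohort layer. Because no admission-level data are public, a
synthetic generator reproduces the study's statistical structure with a
known, planted exposure-lag-response surface, so every estimator can be
validated by parameter recovery.

## Model

### Bases and the cross-basis

Two one-dimensional families are provided:

* **Centred polynomials.** With centre `c` and `df` columns the basis is
  `(x − c), (x − c)², …, (x − c)^df`. Centring the exposure basis at the
  reference concentration makes RR(reference, lag) = 1 hold exactly by
  construction and conditions the design matrix.
* **Natural cubic splines.** Truncated-power construction with the natural
  constraints (zero second derivative at the boundary knots, linear beyond
  them); `df` columns correspond to `df − 1` interior knots. Knots are
  placed at equally spaced empirical quantiles with boundary knots at the
  data range — the standard convention in the distributed-lag literature,
  fully determined by data + df so runs are reproducible.

The cross-basis for an exposure series `x_t` with value-basis columns `R_j`
and lag-basis columns `C_k` evaluated at integer lags `l = 0..L` has entries

    W_t,(j,k) = Σ_{l=0}^{L} R_j(x_{t−l}) · C_k(l)

with value-major column order. Lag bases carry an explicit intercept column:
the constant lag column is what lets same-day (lag-0) effects exist, and
without it the model would force RR(x, 0) ≡ 1 for every concentration. The
first `L` days of the series have incomplete lag history; they are emitted
as NaN rows and excluded from every fit rather than imputed.

### The count model

Daily pneumonia counts are modelled as

    Y_t ~ Poisson(μ_t),
    log μ_t = α + Σ_{j,k} β_{jk} W^{pm25}_t,(j,k) + Σ_{j,k} γ_{jk} W^{temp}_t,(j,k) + δ_{dow(t)}

Defaults mirror the analysis being reproduced: PM2.5 uses degree-2
polynomials in both value (centred at 30 µg/m³) and lag (plus the lag
intercept, so 2 × 3 = 6 columns); temperature uses natural cubic splines
with df 3 in the value dimension and df 3 plus intercept in the lag
dimension (3 × 4 = 12 columns); maximum lag L = 7 days; day-of-week dummies
with Monday as reference, no lag. Plain Poisson likelihood is used; a
quasi-likelihood scale adjustment is deliberately not applied by default.

### The logistic layer

Each admission is scored pneumonia (1) vs any other primary reason (0) and
regressed on PM2.5, PM10, SO2, CO, O3 and mean temperature taken a fixed
number of days (0, 4 or 7) before the admission date, plus day-of-week
dummies (Monday reference) and season dummies (fall reference — the season
with the fewest pneumonia admissions). Admissions sharing a date share that
day's exposure. NO2 is excluded from the default predictor set, mirroring
the reported model; an `include_no2` flag restores it.

### Fitting

Both families are fitted by iteratively reweighted least squares with the
canonical link. Convergence is declared when the relative deviance change
falls below 1e−8 (at most 100 iterations); a non-converged fit is returned
flagged, never silently. The covariance is the inverse expected information
at the optimum. Rank-deficient designs raise an error naming the collinear
columns (QR with column pivoting); a binomial coefficient exceeding 15 in
magnitude triggers a separation warning, since the MLE then likely does not
exist. The IRLS path is cross-checked in the test suite against a generic
BFGS optimiser of the log-likelihood and against an independent GLM
implementation.

### Relative-risk surfaces

For cross-basis coefficients β with covariance Σ, the log relative risk of
concentration `x` versus the reference `x₀` at lag `l` is the linear
contrast

    log RR(x, l) = Σ_{j,k} β_{jk} [R_j(x) − R_j(x₀)] C_k(l)

with variance `cᵀΣc` (delta method on the log scale) and Wald 95% intervals
`exp(log RR ± 1.96 SE)`. The cumulative relative risk over the lag window
sums the per-lag contrasts, so it equals the product of per-lag RRs and its
interval uses the summed contrast's variance. At the reference the contrast
is identically zero, so RR = 1 with a zero-width interval — reported
explicitly rather than omitted. Concentrations outside the training
exposure range are computed but flagged as extrapolation (the 200 µg/m³
probe typically exceeds all but a handful of observed days). The exact
interval method for this class of tables is a convention choice; Wald on
the log scale is used throughout.

## The synthetic generator

The generator emulates a three-year (1096-day) single-centre study in a
subtropical Chinese city. What it reproduces, and what it does not:

* **Temperature** — annual sinusoid (mean 17.5 °C, amplitude 11 °C, coldest
  mid-January) plus AR(1) noise (φ = 0.6, innovation sd 2 °C). Matches the
  cohort's day-of-admission mean/sd (≈18 ± 8.6 °C).
* **Pollutants** — log-normal AR(1) (shared φ = 0.7) with a winter-high
  seasonal mean shift (summer-high for ozone) and cross-correlated
  innovations (PM2.5–PM10 r ≈ 0.9, negative with O3). Log-scale means/sds
  are matched to the cohort's daily summaries, e.g. PM2.5 ≈ 55 ± 29 µg/m³.
  Log-normality guarantees positivity and right skew; it does not reproduce
  episodic multi-day haze plumes beyond what AR(1) persistence gives.
* **Counts** — Poisson from a planted surface `f(x, l)` plus a
  lag-distributed linear temperature term and day-of-week effects (weekend
  log-effects ≈ +0.75 to +0.94, taken from the reported odds ratios). The
  default planted surface is separable quadratic × quadratic, scaled so
  RR(200 µg/m³, lag 3) = 1.40 with a mild same-day effect (≈1.06) and decay
  by lag 7 — the shape the fitted model family can represent exactly, so
  recovery is unbiased in expectation. A hinge-threshold surface with
  exponential lag decay (`ThresholdSurface`) is provided for
  misspecification robustness checks, and `NullSurface` for null recovery.
  The planted temperature effect is deliberately inside the fitted
  temperature cross-basis span (linear in value, constant across lags
  0..7), so PM2.5 recovery tests are not confounded by temperature model
  misspecification. Baseline log-rate −1.72 yields ≈0.36 pneumonia
  admissions/day (the cohort's 391/1096); non-pneumonia admissions are
  Poisson with mean 6.47/day.
* **Admission attributes** — truncated normals for age and severity scores,
  log-normal length of stay, categorical source/discharge/gender, with
  per-group parameters matched to the cohort's published group summaries.
  Only the published mean/sd and margins are available, so joint
  dependencies between attributes (e.g. age × severity) are not modelled;
  the descriptive layer's tests exercise machinery, not clinical realism.

All randomness flows through numpy Generators derived from a single seed
(deterministically split per stage), so identical config + seed gives
bitwise-identical tables.

**What passing tests show.** Parameter-recovery and coverage results
demonstrate the estimator chain is correct and calibrated *under the
generator's assumptions* (correct model family, stationary series, no
measurement error, no overdispersion). They do not show that the original
epidemiological estimates are right: real admission data carry unmeasured
confounding, exposure measurement error from spatial averaging, and
possible overdispersion that the plain Poisson model ignores.

## Descriptive layer

Seasons follow lunar-calendar boundaries: winter, spring, summer and fall
begin on November 7, February 4, May 5 and August 7 (start-date inclusive);
the four intervals tile every calendar year including leap years.
Continuous variables are compared with Welch's unequal-variance t-test —
preferred over the pooled variant because the group sizes are wildly
unequal (hundreds vs thousands); a pooled option exists. Categoricals use
the chi-square test without continuity correction. The seasonal count test
is a chi-square goodness of fit (df = 3) whose null expectation is
proportional to days-per-season in the observed range (the seasons are 89
to 94 days long, so a flat 25% null would be slightly biased); a uniform
null is available as an option. Length of stay is compared by t-test even
though it is extremely skewed, with that caveat attached to the output
rather than substituting a different test.

## Numerical and design choices

* Lags are the integers 0..7 inclusive (8 lag points): a 7-day maximum lag
  with same-day effects included.
* "2 degrees of freedom" polynomials are read as degree 2 (linear +
  quadratic columns).
* Column order of every cross-basis is fixed, value-major, and persisted in
  the fit bundle (JSON) together with knots, centre and max lag, so
  predictions are reproducible without the training data.
* IRLS initialisation: μ₀ = y + 0.5 (Poisson) or (y + ½)/2 (binomial);
  weights are floored at 1e−10 and the linear predictor clipped to ±30 to
  survive separation-degenerate iterations.
* The probe grid {10, 50, 100, 150, 200} µg/m³ × lags 0..7 is the default
  export, making the headline table directly comparable in shape to the
  published one.
* Degenerate inputs fail loudly: non-PSD pollutant correlation matrices,
  constant series offered to spline knot placement, series shorter than the
  lag window, misaligned dates, uncovered lagged admission dates.

## Problem sizes

Recovery and calibration checks use 3000-day simulations with 200
replicates (the planted-cell coverage band 92–98% is the exact binomial
±2σ band around 0.95 at 200 replicates). The worked analysis under
`analysis/` uses the study-period length of 1096 days. Cross-basis oracle
checks use ≥100 randomized series of length ≤60.

## Known limitations

* No overdispersion or autocorrelation-robust standard errors (matching the
  reported analysis); a quasi-Poisson scale option would be the first
  extension.
* No penalised splines, non-integer lag grids, or distributed-lag penalties.
* No attributable-fraction machinery; the harvesting phenomenon is
  representable by the planted surface's late-lag sign change but is not
  decomposed.
* The generator does not simulate multiple monitoring sites (the consumed
  series is already the city-wide average) or humidity.
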