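# pm25-dlnm

Distributed lag non-linear modelling of ambient PM2.5 and ICU admissions
for pneumonia.

Severe air-pollution episodes can precipitate pneumonia requiring intensive
care days after the exposure itself. This package implements the full
analysis chain for that question on daily data: a **distributed lag
non-linear model (DLNM)** — a Poisson regression of daily pneumonia
admission counts on a tensor-product *cross-basis* that captures the effect
of PM2.5 jointly over concentration and lag (0–7 days), adjusted for
temperature (natural cubic spline cross-basis) and day of week — plus the
companion admission-level logistic models at fixed lags, reference-centred
relative-risk surfaces with delta-method confidence intervals, and the
descriptive cohort statistics (Welch/chi-square comparisons, lunar-calendar
season tagging, seasonal count test).

The model, in brief: with value-basis columns `R_j` and lag-basis columns
`C_k`,

    log μ_t = α + Σ_{j,k} β_{jk} Σ_{l=0}^{7} R_j(pm25_{t−l}) C_k(l)
            + temperature cross-basis + day-of-week,   Y_t ~ Poisson(μ_t)

and the relative risk of concentration `x` versus the 30 µg/m³ reference at
lag `l` is `exp(Σ β_{jk} [R_j(x) − R_j(30)] C_k(l))`, with Wald intervals
from the contrast variance `cᵀΣc`.

Because admission-level hospital records are not public, the package ships
a first-class synthetic generator (`pm25_dlnm.synthetic_data`) that
emulates the study's structure — seasonal temperature, correlated
log-normal AR(1) pollutant series, Poisson counts from a *known planted*
exposure-lag-response surface, and admission records with realistic group
attributes — so every estimator is validated by parameter recovery and
interval-coverage simulation. See `docs/methods.md` for the full model and
generator account.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
simulated 1096-day (2014–2016) cohort and write their tables under
`results/`:

```sh
python analysis/01_simulate.py      # generate the synthetic study
python analysis/02_descriptives.py  # cohort table + seasonal test
python analysis/03_logistic_lags.py # logistic models at lags 0/4/7
python analysis/04_dlnm_surface.py  # DLNM fit + RR surface
```

`04_dlnm_surface.py` prints (abridged):

```
Poisson DLNM on 1089 days, deviance 954.8, 25 coefficients, converged=True

RR of ICU pneumonia admission vs 30 mcg/m3 reference (95% CI):
                  lag_0             lag_2             lag_3             lag_5             lag_7
pm25
50.0   1.02 (0.94,1.11)  1.06 (1.02,1.10)  1.06 (1.01,1.11)  1.04 (1.00,1.08)  0.99 (0.91,1.08)
100.0  1.01 (0.82,1.24)  1.20 (1.10,1.32)  1.24 (1.11,1.38)  1.15 (1.06,1.25)  0.91 (0.73,1.12)
200.0  0.73 (0.43,1.25)  1.52 (1.24,1.86)  1.74 (1.34,2.24)  1.41 (1.14,1.74)  0.61 (0.34,1.10)

planted RR at (200 mcg/m3, lag 3): 1.40; fitted 1.74 (1.34,2.24)
```

Read it as: at low concentrations there is no excess risk; at high
concentrations the relative risk of an ICU pneumonia admission rises, peaks
3–4 days after exposure, and returns to baseline by a week — the fitted
surface's confidence interval at the probed cell covers the planted truth
(1.40) for this realisation, and the calibration of those intervals is
verified over 200 replicates in the test suite. Equivalently from a shell,
`pm25-dlnm run --config <run.yaml>` executes the same pipeline
(simulate/load → descriptives → logistic fits → DLNM → surface export) with
a run manifest for provenance.

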