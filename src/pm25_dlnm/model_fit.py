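"""GLM fitting for the two regression layers of the analysis.

* ``fit_glm`` — iteratively reweighted least squares (IRLS) for canonical-link
  Poisson and binomial models, returning coefficients with the full
  expected-information covariance.
* ``fit_dlnm`` — the daily count model: pneumonia counts regressed on a PM2.5
  cross-basis (centred polynomials, degree 2, in both value and lag), a
  temperature cross-basis (natural cubic splines in both dimensions) and
  day-of-week dummies (Monday reference, no lag).
* ``fit_lagged_logistic`` — the admission-level model: pneumonia vs other ICU
  admission regressed on air quality taken a fixed number of days before
  admission, plus day-of-week and season dummies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .basis_functions import (
    NATURAL_CUBIC_SPLINE,
    POLYNOMIAL,
    BasisConfig,
)
from .cross_basis import CrossBasis, build_cross_basis
from .cohort_stats import season_of_series

__all__ = [
    "FitResult",
    "DlnmSpec",
    "SeparationWarning",
    "fit_glm",
    "fit_dlnm",
    "fit_lagged_logistic",
    "POISSON_LOG",
    "BINOMIAL_LOGIT",
]

POISSON_LOG = "poisson_log"
BINOMIAL_LOGIT = "binomial_logit"

_WEEKDAYS = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]
#: Logistic-model pollutant set; NO2 is omitted by default (include via flag).
LOGISTIC_PREDICTORS = ["pm25", "pm10", "so2", "co", "o3", "temperature"]


class SeparationWarning(UserWarning):
    """Raised (as a warning) when a logistic fit shows signs of complete separation."""


@dataclass
class FitResult:
    """Coefficients, covariance and diagnostics of a fitted GLM."""

    coefficients: np.ndarray
    covariance: np.ndarray
    deviance: float
    n_obs: int
    converged: bool
    family: str
    column_names: list[str]
    n_iter: int = 0
    deviance_path: list[float] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def summary_frame(self, z: float = 1.959963984540054) -> pd.DataFrame:
        """Human-readable table: term, estimate, exp(estimate), Wald 95% CI, p."""
        from scipy import stats

        se = self.se()
        est = self.coefficients
        zval = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
        return pd.DataFrame(
            {
                "term": self.column_names,
                "estimate": est,
                "exp_estimate": np.exp(est),
                "ci_low": np.exp(est - z * se),
                "ci_high": np.exp(est + z * se),
                "p": 2 * stats.norm.sf(np.abs(zval)),
            }
        )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = diag < tol
    if bad.any():
        cols = [names[piv[i]] for i in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {cols}")


def _deviance(y: np.ndarray, mu: np.ndarray, family: str, w: np.ndarray) -> float:
    if family == POISSON_LOG:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(w * (term - (y - mu))))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t0 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t0)))


def fit_glm(
    design: np.ndarray,
    response: np.ndarray,
    family: str,
    weights: np.ndarray | None = None,
    column_names: list[str] | None = None,
    max_iter: int = 100,
    rtol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood GLM fit by IRLS with the canonical link.

    Convergence is declared when the relative change in deviance drops below
    ``rtol`` (default 1e-8) within ``max_iter`` iterations; otherwise the
    result is returned with ``converged=False``, never silently. The
    covariance is the inverse expected information at the optimum. A binomial
    coefficient exceeding 15 in magnitude triggers a ``SeparationWarning``.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if family not in (POISSON_LOG, BINOMIAL_LOGIT):
        raise ValueError(f"unknown family {family!r}")
    if family == POISSON_LOG and (np.any(y < 0) or np.any(y != np.round(y))):
        raise ValueError("poisson response must be non-negative integers")
    if family == BINOMIAL_LOGIT and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial response must be 0/1")
    names = column_names or [f"x{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("column_names length does not match design width")
    _check_rank(X, names)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    if family == POISSON_LOG:
        mu = y + 0.5
        eta = np.log(mu)
    else:
        mu = (y + 0.5) / 2.0
        eta = np.log(mu / (1 - mu))

    beta = np.zeros(X.shape[1])
    dev = _deviance(y, mu, family, w)
    path: list[float] = []  # per-iteration deviances (initialisation excluded)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = w * (mu if family == POISSON_LOG else mu * (1 - mu))
        W = np.clip(W, 1e-10, None)
        z = eta + (y - mu) / W
        sw = np.sqrt(W)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta) if family == POISSON_LOG else 1.0 / (1.0 + np.exp(-eta))
        new_dev = _deviance(y, mu, family, w)
        path.append(new_dev)
        if abs(new_dev - dev) < rtol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev

    if family == BINOMIAL_LOGIT and np.max(np.abs(beta)) > 15:
        warnings.warn(
            "coefficient magnitude exceeds 15; the data are likely completely "
            "separated and the MLE does not exist",
            SeparationWarning,
        )

    W = w * (mu if family == POISSON_LOG else mu * (1 - mu))
    info = (X * W[:, None]).T @ X
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    return FitResult(
        coefficients=beta,
        covariance=cov,
        deviance=dev,
        n_obs=len(y),
        converged=converged,
        family=family,
        column_names=list(names),
        n_iter=it,
        deviance_path=path,
    )


@dataclass(frozen=True)
class DlnmSpec:
    """Model specification for the daily-count DLNM.

    Defaults mirror the analysis this package reproduces: PM2.5 modelled by
    degree-2 polynomials in value (centred at the 30 mcg/m^3 reference) and in
    lag (with a constant lag column carrying same-day effects); temperature by
    natural cubic splines (df 3) in both dimensions; maximum lag 7 days;
    day of week without lag.
    """

    max_lag: int = 7
    reference: float = 30.0
    pm25_value: BasisConfig = BasisConfig(POLYNOMIAL, df=2, center=30.0)
    pm25_lag: BasisConfig = BasisConfig(POLYNOMIAL, df=2, center=0.0, intercept=True)
    temp_value: BasisConfig = BasisConfig(NATURAL_CUBIC_SPLINE, df=3)
    temp_lag: BasisConfig = BasisConfig(NATURAL_CUBIC_SPLINE, df=3, intercept=True)


def dow_dummies(dates: pd.Series) -> pd.DataFrame:
    """Day-of-week indicator columns, Monday as the reference level."""
    wd = pd.DatetimeIndex(dates).weekday
    return pd.DataFrame(
        {f"dow:{_WEEKDAYS[d]}": (wd == d).astype(float) for d in range(1, 7)},
        index=range(len(wd)),
    )


def season_dummies(dates: pd.Series) -> pd.DataFrame:
    """Season indicator columns tagged by the lunar-calendar dates, fall reference."""
    seas = season_of_series(dates)
    return pd.DataFrame(
        {f"season:{s}": (seas == s).astype(float).to_numpy() for s in ("spring", "summer", "winter")},
        index=range(len(seas)),
    )


def fit_dlnm(
    env: pd.DataFrame,
    counts: pd.DataFrame,
    spec: DlnmSpec | None = None,
) -> tuple[FitResult, list[CrossBasis]]:
    """Fit the Poisson DLNM of daily pneumonia counts.

    ``env`` must carry columns ``date``, ``pm25``, ``temperature``; ``counts``
    carries ``date`` and ``count`` (NaN where lag history is incomplete).
    Dates of the two tables must align one-to-one. Returns the fit together
    with the PM2.5 and temperature cross-bases for later prediction.
    """
    spec = spec or DlnmSpec()
    env = env.reset_index(drop=True)
    counts = counts.reset_index(drop=True)
    d_env = pd.to_datetime(env["date"]).reset_index(drop=True)
    d_cnt = pd.to_datetime(counts["date"]).reset_index(drop=True)
    if len(d_env) != len(d_cnt) or not d_env.equals(d_cnt):
        n = min(len(d_env), len(d_cnt))
        mism = next(
            (i for i in range(n) if d_env.iloc[i] != d_cnt.iloc[i]), n
        )
        which = d_env.iloc[mism] if mism < len(d_env) else d_cnt.iloc[mism]
        raise ValueError(
            f"environment and count dates are misaligned at {which.date()}"
        )
    if len(env) < spec.max_lag + 2:
        raise ValueError("need at least max_lag + 2 days of data")

    cb_pm = build_cross_basis(
        env["pm25"].to_numpy(), spec.pm25_value, spec.pm25_lag,
        spec.max_lag, exposure_name="pm25", dates=env["date"].tolist(),
    )
    cb_temp = build_cross_basis(
        env["temperature"].to_numpy(), spec.temp_value, spec.temp_lag,
        spec.max_lag, exposure_name="temperature", dates=env["date"].tolist(),
    )
    dow = dow_dummies(env["date"])

    y = counts["count"].to_numpy(dtype=float)
    valid = np.isfinite(y)
    valid[: spec.max_lag] = False

    design = np.column_stack(
        [np.ones(len(env)), cb_pm.matrix, cb_temp.matrix, dow.to_numpy()]
    )
    names = ["intercept", *cb_pm.column_names, *cb_temp.column_names, *dow.columns]
    fit = fit_glm(design[valid], y[valid], POISSON_LOG, column_names=names)
    return fit, [cb_pm, cb_temp]


def fit_lagged_logistic(
    admissions: pd.DataFrame,
    env: pd.DataFrame,
    lag_days: int,
    include_no2: bool = False,
) -> FitResult:
    """Admission-level logistic model of pneumonia vs other ICU admission.

    Each admission is linked to the air quality ``lag_days`` before its
    admission date (admissions sharing a date share that day's exposure).
    Predictors: PM2.5, PM10, SO2, CO, O3 and temperature at the lagged date,
    day-of-week dummies of the admission date (Monday reference) and season
    dummies (fall reference).
    """
    adm = admissions.reset_index(drop=True)
    env = env.reset_index(drop=True)
    env_dates = pd.to_datetime(env["date"])
    lookup = env.set_index(env_dates)

    target = pd.to_datetime(adm["admit_date"]) - pd.Timedelta(days=lag_days)
    missing = ~target.isin(env_dates)
    if missing.any():
        miss_dates = sorted({d.date() for d in pd.to_datetime(adm.loc[missing, "admit_date"])})
        shown = ", ".join(str(d) for d in miss_dates[:10])
        raise ValueError(
            f"{missing.sum()} admissions lack environmental coverage at lag "
            f"{lag_days}; earliest uncovered admission dates: {shown}"
        )

    predictors = LOGISTIC_PREDICTORS + (["no2"] if include_no2 else [])
    Xenv = lookup.loc[target, predictors].to_numpy(dtype=float)
    dow = dow_dummies(adm["admit_date"])
    seas = season_dummies(adm["admit_date"])

    design = np.column_stack([np.ones(len(adm)), Xenv, dow.to_numpy(), seas.to_numpy()])
    names = ["intercept", *predictors, *dow.columns, *seas.columns]
    y = (adm["group"] == "pneumonia").to_numpy(dtype=float)
    return fit_glm(design, y, BINOMIAL_LOGIT, column_names=names)
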