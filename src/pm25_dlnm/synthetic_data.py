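"""Synthetic daily environmental series and ICU admission records.

The generator emulates the structure of a three-year single-centre study of
ambient air quality and ICU admissions in a subtropical Chinese city:

* daily mean temperature as an annual sinusoid (coldest mid-January) plus
  AR(1) noise;
* six pollutant series (PM2.5, PM10, SO2, NO2, O3, CO) as log-normal AR(1)
  processes with a winter-high seasonal mean shift (summer-high for ozone)
  and cross-correlated innovations — log-normality guarantees positivity and
  right skew;
* daily pneumonia admission counts drawn Poisson from a known (planted)
  exposure-lag-response surface for PM2.5, a lag-distributed linear
  temperature term and day-of-week effects — the count model the downstream
  DLNM inverts;
* admission-level records (age, gender, severity scores, admission source,
  discharge outcome, length of stay) with configurable per-group
  distributions.

Default parameter values are matched once to the published cohort's summary
statistics (pollutant means/sds, group attribute moments, ~0.36 pneumonia and
~6.5 other admissions per day over 1096 days) and are not tuning knobs.

All randomness flows through numpy Generators derived deterministically from
``SimulationConfig.seed``; identical config + seed gives bitwise-identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "GroupAttributeConfig",
    "QuadraticSurface",
    "NullSurface",
    "ThresholdSurface",
    "surface_from_dict",
    "simulate_environment",
    "simulate_counts",
    "simulate_admissions",
    "simulate_study",
    "POLLUTANTS",
    "ENV_COLUMNS",
    "ADM_COLUMNS",
]

POLLUTANTS = ["pm25", "pm10", "so2", "no2", "o3", "co"]
ENV_COLUMNS = ["date", "pm25", "pm10", "so2", "no2", "o3", "co", "temperature"]
ADM_COLUMNS = [
    "date", "group", "age", "gender", "apache2", "mpm2", "source", "discharge", "los_hours",
]
SOURCES = ["emergency", "emergency_surgery", "icu", "outpatient", "postoperation", "ward"]
DISCHARGES = ["aad", "die", "discharge", "other_hospital", "to_ward"]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# planted exposure-lag-response surfaces


@dataclass(frozen=True)
class QuadraticSurface:
    """Separable quadratic x quadratic log-RR surface, centred at the reference.

    ``f(x, l) = g(x) * h(l)`` with ``g`` quadratic in the centred exposure
    (zero at the reference) and ``h`` quadratic in lag, normalised so that
    ``f(peak_value, peak_lag) = log(peak_rr)``. The default shape rises from a
    mild same-day effect to its maximum near lag 3-4 and decays by lag 7,
    with RR 1.40 at 200 mcg/m^3 and lag 3.

    Because both factors lie inside the span of a degree-2 polynomial
    cross-basis (with a constant lag column), a correctly specified fit
    recovers this surface exactly in expectation.
    """

    reference: float = 30.0
    peak_value: float = 200.0
    peak_lag: int = 3
    peak_rr: float = 1.40
    value_curvature: float = 0.3
    lag_coefs: tuple[float, float, float] = (0.2, 0.55, -0.08)
    max_lag: int = 7

    def __call__(self, x, l):
        x = np.asarray(x, dtype=float)
        z = (x - self.reference) / (self.peak_value - self.reference)
        q = self.value_curvature
        g = (z + q * z**2) / (1.0 + q)
        c0, c1, c2 = self.lag_coefs
        h = (c0 + c1 * l + c2 * l**2) / (c0 + c1 * self.peak_lag + c2 * self.peak_lag**2)
        return math.log(self.peak_rr) * g * h

    def to_dict(self) -> dict:
        return {
            "type": "quadratic",
            "reference": self.reference,
            "peak_value": self.peak_value,
            "peak_lag": self.peak_lag,
            "peak_rr": self.peak_rr,
            "value_curvature": self.value_curvature,
            "lag_coefs": list(self.lag_coefs),
            "max_lag": self.max_lag,
        }


@dataclass(frozen=True)
class NullSurface:
    """No exposure effect at any value or lag."""

    reference: float = 30.0
    max_lag: int = 7

    def __call__(self, x, l):
        return np.zeros_like(np.asarray(x, dtype=float))

    def to_dict(self) -> dict:
        return {"type": "null", "reference": self.reference, "max_lag": self.max_lag}


@dataclass(frozen=True)
class ThresholdSurface:
    """Hinge-linear surface with exponential lag decay.

    Deliberately outside the quadratic x quadratic model span — used in
    robustness tests of fits under surface misspecification.
    """

    reference: float = 30.0
    threshold: float = 75.0
    slope_per_100: float = 0.25
    decay: float = 0.4
    max_lag: int = 7

    def __call__(self, x, l):
        x = np.asarray(x, dtype=float)
        excess = np.clip(x - self.threshold, 0.0, None) - max(self.reference - self.threshold, 0.0)
        return self.slope_per_100 * excess / 100.0 * np.exp(-self.decay * l)

    def to_dict(self) -> dict:
        return {
            "type": "threshold",
            "reference": self.reference,
            "threshold": self.threshold,
            "slope_per_100": self.slope_per_100,
            "decay": self.decay,
            "max_lag": self.max_lag,
        }


def surface_from_dict(d: dict):
    kind = d.get("type", "quadratic")
    params = {k: v for k, v in d.items() if k != "type"}
    if "lag_coefs" in params:
        params["lag_coefs"] = tuple(params["lag_coefs"])
    cls = {"quadratic": QuadraticSurface, "null": NullSurface, "threshold": ThresholdSurface}[kind]
    return cls(**params)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GroupAttributeConfig:
    """Per-group attribute distributions for admission records.

    Ages and severity scores are truncated normals; length of stay is
    log-normal (the cohort's sds exceed its means, so a symmetric model would
    be absurd); gender/source/discharge are categorical.
    """

    age_mean: float
    age_sd: float
    male_prop: float
    apache2_mean: float
    apache2_sd: float
    mpm2_mean: float
    mpm2_sd: float
    source_probs: dict
    discharge_probs: dict
    los_log_mean: float
    los_log_sd: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


#: Defaults matched to the published cohort's per-group summaries.
DEFAULT_ATTRIBUTES = {
    "pneumonia": GroupAttributeConfig(
        age_mean=68.2, age_sd=15.4, male_prop=0.685,
        apache2_mean=21.4, apache2_sd=9.3, mpm2_mean=29.6, mpm2_sd=19.4,
        source_probs={"emergency": 0.660, "emergency_surgery": 0.0, "icu": 0.041,
                      "outpatient": 0.005, "postoperation": 0.003, "ward": 0.292},
        discharge_probs={"aad": 0.207, "die": 0.087, "discharge": 0.036,
                         "other_hospital": 0.107, "to_ward": 0.555},
        los_log_mean=5.386, los_log_sd=1.292,
    ),
    "non_pneumonia": GroupAttributeConfig(
        age_mean=60.3, age_sd=16.2, male_prop=0.617,
        apache2_mean=15.0, apache2_sd=8.6, mpm2_mean=21.4, mpm2_sd=18.9,
        source_probs={"emergency": 0.376, "emergency_surgery": 0.092, "icu": 0.016,
                      "outpatient": 0.009, "postoperation": 0.354, "ward": 0.153},
        discharge_probs={"aad": 0.079, "die": 0.023, "discharge": 0.022,
                         "other_hospital": 0.025, "to_ward": 0.845},
        los_log_mean=3.756, los_log_sd=1.545,
    ),
}

#: (log_mean, innovation_sd, seasonal_amplitude on the log scale) per pollutant,
#: chosen so the stationary moments approximate the cohort's daily means/sds.
#: Ozone's negative amplitude makes it summer-high.
DEFAULT_POLLUTANT_PARAMS = {
    "pm25": (3.89, 0.33, 0.25),
    "pm10": (4.34, 0.31, 0.25),
    "so2": (2.65, 0.34, 0.25),
    "no2": (3.78, 0.23, 0.20),
    "o3": (4.59, 0.30, -0.35),
    "co": (-0.13, 0.14, 0.15),
}

_DEFAULT_CORR = np.array(
    #        pm25  pm10  so2   no2   o3    co
    [
        [1.00, 0.90, 0.60, 0.60, -0.10, 0.70],
        [0.90, 1.00, 0.60, 0.60, -0.05, 0.65],
        [0.60, 0.60, 1.00, 0.50, -0.10, 0.50],
        [0.60, 0.60, 0.50, 1.00, -0.30, 0.60],
        [-0.10, -0.05, -0.10, -0.30, 1.00, -0.20],
        [0.70, 0.65, 0.50, 0.60, -0.20, 1.00],
    ]
)

#: Day-of-week multiplicative effects on the log scale, Monday first; weekend
#: admissions run roughly 2-2.5x the Monday rate in the cohort emulated here.
DEFAULT_DOW_LOG_EFFECTS = (0.0, 0.247, 0.365, 0.385, 0.425, 0.936, 0.751)


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic study.

    See the module docstring for what each block emulates. ``baseline_log_rate``
    is the log expected pneumonia count per day before exposure, temperature
    and day-of-week contributions (default exp(-1.72) ~ 0.18, yielding ~0.36
    admissions/day once those contributions are included).
    """

    n_days: int = 1096
    start_date: date = date(2014, 1, 1)
    temp_mean_annual: float = 17.5
    temp_amplitude: float = 11.0
    temp_ar_coefficient: float = 0.6
    temp_noise_sd: float = 2.0
    pm25_log_mean: float = 3.89
    pm25_log_sd: float = 0.33
    pm25_ar_coefficient: float = 0.7
    pm25_seasonal_amplitude: float = 0.25
    pollutant_correlations: np.ndarray = field(default_factory=_DEFAULT_CORR.copy)
    pollutant_params: dict = field(default_factory=lambda: dict(DEFAULT_POLLUTANT_PARAMS))
    baseline_log_rate: float = -1.72
    true_surface: object = field(default_factory=QuadraticSurface)
    temp_log_effect_per_lag: float = -0.003
    temp_effect_center: float = 18.0
    dow_log_effects: tuple = DEFAULT_DOW_LOG_EFFECTS
    nonpneumonia_daily_mean: float = 6.47
    attributes: dict = field(default_factory=lambda: dict(DEFAULT_ATTRIBUTES))
    deterministic_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigError("n_days must be positive")
        for name in ("temp_ar_coefficient", "pm25_ar_coefficient"):
            if not abs(getattr(self, name)) < 1:
                raise ConfigError(f"|{name}| must be < 1 for stationarity")
        R = np.asarray(self.pollutant_correlations, dtype=float)
        if R.shape != (len(POLLUTANTS), len(POLLUTANTS)):
            raise ConfigError("pollutant_correlations must be 6x6")
        if not np.allclose(R, R.T, atol=1e-12) or not np.allclose(np.diag(R), 1.0):
            raise ConfigError(
                f"pollutant_correlations must be symmetric with unit diagonal:\n{R}"
            )
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigError(
                f"pollutant_correlations is not positive semi-definite:\n{R}"
            )
        object.__setattr__(self, "pollutant_correlations", R)
        if len(self.dow_log_effects) != 7:
            raise ConfigError("dow_log_effects must have 7 entries, Monday first")
        f = self.true_surface
        ref = getattr(f, "reference", 30.0)
        for l in range(getattr(f, "max_lag", 7) + 1):
            if abs(float(np.asarray(f(ref, l)))) > 1e-10:
                raise ConfigError("true_surface must satisfy f(reference, l) = 0")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "n_days": self.n_days,
            "start_date": self.start_date.isoformat(),
            "temp_mean_annual": self.temp_mean_annual,
            "temp_amplitude": self.temp_amplitude,
            "temp_ar_coefficient": self.temp_ar_coefficient,
            "temp_noise_sd": self.temp_noise_sd,
            "pm25_log_mean": self.pm25_log_mean,
            "pm25_log_sd": self.pm25_log_sd,
            "pm25_ar_coefficient": self.pm25_ar_coefficient,
            "pm25_seasonal_amplitude": self.pm25_seasonal_amplitude,
            "pollutant_correlations": self.pollutant_correlations.tolist(),
            "pollutant_params": {k: list(v) for k, v in self.pollutant_params.items()},
            "baseline_log_rate": self.baseline_log_rate,
            "true_surface": self.true_surface.to_dict(),
            "temp_log_effect_per_lag": self.temp_log_effect_per_lag,
            "temp_effect_center": self.temp_effect_center,
            "dow_log_effects": list(self.dow_log_effects),
            "nonpneumonia_daily_mean": self.nonpneumonia_daily_mean,
            "attributes": {g: a.to_dict() for g, a in self.attributes.items()},
            "deterministic_counts": self.deterministic_counts,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = date.fromisoformat(d["start_date"])
        if "pollutant_correlations" in d:
            d["pollutant_correlations"] = np.asarray(d["pollutant_correlations"], dtype=float)
        if "pollutant_params" in d:
            d["pollutant_params"] = {k: tuple(v) for k, v in d["pollutant_params"].items()}
        if "true_surface" in d and isinstance(d["true_surface"], dict):
            d["true_surface"] = surface_from_dict(d["true_surface"])
        if "dow_log_effects" in d:
            d["dow_log_effects"] = tuple(d["dow_log_effects"])
        if "attributes" in d:
            d["attributes"] = {
                g: a if isinstance(a, GroupAttributeConfig) else GroupAttributeConfig(**a)
                for g, a in d["attributes"].items()
            }
        return cls(**d)


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one root seed, deterministically split per pipeline stage
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# generators


def _winter_signal(dates: pd.DatetimeIndex) -> np.ndarray:
    """Annual cosine peaking in mid-January (day-of-year 15)."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    return np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)


def _ar1(innovations: np.ndarray, phi: float) -> np.ndarray:
    """AR(1) path from standardised innovations, started at stationarity."""
    n = len(innovations)
    out = np.empty(n)
    scale0 = 1.0 / math.sqrt(1.0 - phi**2) if abs(phi) > 0 else 1.0
    out[0] = innovations[0] * scale0
    for t in range(1, n):
        out[t] = phi * out[t - 1] + innovations[t]
    return out


def simulate_environment(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the daily environmental table (one row per calendar day)."""
    rng = rng or _stage_rng(config, 0)
    n = config.n_days
    dates = pd.date_range(pd.Timestamp(config.start_date), periods=n, freq="D")
    w = _winter_signal(dates)

    eps = rng.normal(0.0, 1.0, size=n) * config.temp_noise_sd
    temp_noise = _ar1(eps, config.temp_ar_coefficient) if config.temp_noise_sd > 0 else np.zeros(n)
    temperature = config.temp_mean_annual - config.temp_amplitude * w + temp_noise

    R = config.pollutant_correlations
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(len(POLLUTANTS)))
    z = rng.normal(0.0, 1.0, size=(n, len(POLLUTANTS))) @ chol.T

    params = dict(config.pollutant_params)
    params["pm25"] = (config.pm25_log_mean, config.pm25_log_sd, config.pm25_seasonal_amplitude)
    phi = config.pm25_ar_coefficient
    cols = {"date": dates}
    for i, p in enumerate(POLLUTANTS):
        mu, innov_sd, amp = params[p]
        u = _ar1(z[:, i] * innov_sd, phi) if innov_sd > 0 else np.zeros(n)
        cols[p] = np.exp(mu + amp * w + u)
    cols["temperature"] = temperature
    return pd.DataFrame(cols)[ENV_COLUMNS]


def simulate_counts(
    env: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily pneumonia counts from the planted log-linear Poisson model.

    For day ``t`` at or beyond the lag window ``L``:

        log mu_t = baseline + sum_l f(pm25_{t-l}, l)
                   + sum_l tau * (temp_{t-l} - temp_center)
                   + dow_effect[weekday(t)]

    and ``count_t ~ Poisson(mu_t)`` (or ``round(mu_t)`` in deterministic
    mode). The first ``L`` days carry NaN counts: they lack full lag history.
    """
    rng = rng or _stage_rng(config, 1)
    f = config.true_surface
    L = getattr(f, "max_lag", 7)
    n = len(env)
    if n <= L:
        raise ValueError(f"environment series ({n} days) does not exceed the lag window L={L}")
    pm25 = env["pm25"].to_numpy(dtype=float)
    temp = env["temperature"].to_numpy(dtype=float)
    dates = pd.to_datetime(env["date"])

    eta = np.full(n, config.baseline_log_rate)
    for l in range(L + 1):
        eta[L:] += f(pm25[L - l : n - l], l)
        eta[L:] += config.temp_log_effect_per_lag * (temp[L - l : n - l] - config.temp_effect_center)
    wd = pd.DatetimeIndex(dates).weekday.to_numpy()
    eta += np.asarray(config.dow_log_effects)[wd]

    mu = np.exp(eta)
    if config.deterministic_counts:
        counts = np.round(mu)
    else:
        counts = rng.poisson(mu).astype(float)
    counts[:L] = np.nan
    return pd.DataFrame({"date": dates, "count": counts})


def _draw_records(
    day: pd.Timestamp, group: str, k: int, attrs: GroupAttributeConfig, rng: np.random.Generator
) -> dict:
    src_names = list(attrs.source_probs)
    src_p = np.asarray([attrs.source_probs[s] for s in src_names], dtype=float)
    dis_names = list(attrs.discharge_probs)
    dis_p = np.asarray([attrs.discharge_probs[s] for s in dis_names], dtype=float)
    return {
        "date": [day] * k,
        "group": [group] * k,
        "age": np.clip(rng.normal(attrs.age_mean, attrs.age_sd, k), 1.0, None),
        "gender": np.where(rng.random(k) < attrs.male_prop, "M", "F"),
        "apache2": np.clip(rng.normal(attrs.apache2_mean, attrs.apache2_sd, k), 0.0, None),
        "mpm2": np.clip(rng.normal(attrs.mpm2_mean, attrs.mpm2_sd, k), 0.0, None),
        "source": rng.choice(src_names, size=k, p=src_p / src_p.sum()),
        "discharge": rng.choice(dis_names, size=k, p=dis_p / dis_p.sum()),
        "los_hours": np.exp(rng.normal(attrs.los_log_mean, attrs.los_log_sd, k)),
    }


def simulate_admissions(
    counts: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Admission-level records consistent with the simulated daily counts.

    Every day with a finite pneumonia count contributes exactly that many
    pneumonia records; every day additionally contributes
    ``Poisson(nonpneumonia_daily_mean)`` non-pneumonia records. Attributes are
    drawn from the per-group configured distributions.
    """
    rng = rng or _stage_rng(config, 2)
    frames = []
    for day, c in zip(pd.to_datetime(counts["date"]), counts["count"].to_numpy(dtype=float)):
        day = pd.Timestamp(day)
        if np.isfinite(c) and c > 0:
            frames.append(_draw_records(day, "pneumonia", int(c), config.attributes["pneumonia"], rng))
        k_np = int(rng.poisson(config.nonpneumonia_daily_mean))
        if k_np > 0:
            frames.append(_draw_records(day, "non_pneumonia", k_np, config.attributes["non_pneumonia"], rng))
    if not frames:
        return pd.DataFrame(columns=ADM_COLUMNS).rename(columns={"date": "admit_date"})
    df = pd.concat([pd.DataFrame(f) for f in frames], ignore_index=True)
    df = df.rename(columns={"date": "admit_date"})
    return df


def simulate_study(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: environment, daily counts, admissions."""
    env = simulate_environment(config)
    counts = simulate_counts(env, config)
    admissions = simulate_admissions(counts, config)
    return env, counts, admissions
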