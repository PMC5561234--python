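"""Descriptive cohort statistics and season handling.

Seasons follow the Chinese lunar-calendar convention: winter, spring, summer
and fall begin on November 7, February 4, May 5 and August 7 respectively,
with start dates inclusive. Group comparisons use Welch's t-test for
continuous variables (a pooled-variance option exists) and the chi-square
test for categoricals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SEASONS",
    "GroupComparison",
    "season_of",
    "season_of_series",
    "aggregate_daily_counts",
    "compare_groups",
    "seasonal_count_test",
    "table_frame",
]

SEASONS = ("winter", "spring", "summer", "fall")
# (month, day) season start boundaries, start-inclusive
_BOUNDARIES = [((2, 4), "spring"), ((5, 5), "summer"), ((8, 7), "fall"), ((11, 7), "winter")]

CONTINUOUS_VARS = ["age", "mpm2", "apache2", "los_hours"]
CATEGORICAL_VARS = ["gender", "source", "discharge"]
ENV_VARS = ["pm25", "pm10", "so2", "co", "no2", "o3", "temperature"]


def season_of(date) -> str:
    """Season of a calendar date under the lunar-calendar boundaries."""
    d = pd.Timestamp(date)
    md = (d.month, d.day)
    if md < (2, 4) or md >= (11, 7):
        return "winter"
    if md < (5, 5):
        return "spring"
    if md < (8, 7):
        return "summer"
    return "fall"


def season_of_series(dates: Sequence) -> pd.Series:
    idx = pd.DatetimeIndex(pd.to_datetime(dates))
    md = idx.month * 100 + idx.day
    out = np.select(
        [md < 204, md < 505, md < 807, md < 1107],
        ["winter", "spring", "summer", "fall"],
        default="winter",
    )
    return pd.Series(out, index=range(len(idx)))


@dataclass
class GroupComparison:
    """One row of a group-comparison table."""

    variable: str
    group_summaries: dict
    statistic: float
    p_value: float
    test: str
    df: float | None = None


def aggregate_daily_counts(
    admissions: pd.DataFrame,
    group: str,
    date_range: tuple | None = None,
) -> pd.DataFrame:
    """Daily admission counts for one diagnosis group, zero-filled over the range.

    ``date_range`` defaults to the span of the admission dates; pass the
    environmental series range to align with it.
    """
    dates = pd.to_datetime(admissions["admit_date"]) if len(admissions) else pd.Series(dtype="datetime64[ns]")
    if date_range is None:
        if not len(dates):
            raise ValueError("empty admissions and no date_range declared")
        date_range = (dates.min(), dates.max())
    full = pd.date_range(pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1]), freq="D")
    sel = admissions.loc[admissions["group"] == group] if len(admissions) else admissions
    counts = (
        pd.to_datetime(sel["admit_date"]).value_counts().reindex(full, fill_value=0)
        if len(sel)
        else pd.Series(0, index=full)
    )
    return pd.DataFrame({"date": full, "count": counts.to_numpy(dtype=float)})


def _welch(a: np.ndarray, b: np.ndarray, pooled: bool) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    admissions: pd.DataFrame,
    env: pd.DataFrame | None = None,
    pooled_variance: bool = False,
) -> list[GroupComparison]:
    """Compare pneumonia vs non-pneumonia admissions variable by variable.

    Continuous variables (age, severity scores, length of stay, and — when an
    environmental table is supplied — the day-of-admission pollutant levels
    and temperature) are compared with Welch's t-test; categoricals (gender,
    admission source, discharge outcome, season of admission) with the
    chi-square test. Identical groups yield t = 0, p = 1.
    """
    adm = admissions.copy().reset_index(drop=True)
    adm["season"] = season_of_series(adm["admit_date"]).to_numpy()
    if env is not None:
        envi = env.set_index(pd.to_datetime(env["date"]))
        linked = envi.reindex(pd.to_datetime(adm["admit_date"]))
        for v in ENV_VARS:
            if v in linked.columns:
                adm[v] = linked[v].to_numpy()

    grp = adm["group"]
    groups = {g: adm.loc[grp == g] for g in ("non_pneumonia", "pneumonia")}
    out: list[GroupComparison] = []

    env_cont = [v for v in ENV_VARS if v in adm.columns]
    for var in CONTINUOUS_VARS + env_cont:
        if var not in adm.columns:
            continue
        samples = {g: df[var].dropna().to_numpy(dtype=float) for g, df in groups.items()}
        summ = {
            g: (float(np.mean(s)) if len(s) else np.nan, float(np.std(s, ddof=1)) if len(s) > 1 else np.nan)
            for g, s in samples.items()
        }
        if any(len(s) < 2 for s in samples.values()):
            logger.warning("skipping t-test for %s: a group has fewer than 2 observations", var)
            continue
        t, p = _welch(samples["pneumonia"], samples["non_pneumonia"], pooled_variance)
        out.append(GroupComparison(var, summ, t, p, "pooled_t" if pooled_variance else "welch_t"))

    for var in CATEGORICAL_VARS + ["season"]:
        if var not in adm.columns:
            continue
        tab = pd.crosstab(adm[var], grp)
        summ = {
            g: {lvl: (int(c), float(c / len(groups[g]))) for lvl, c in tab[g].items()}
            for g in tab.columns
        }
        nonzero = tab.loc[tab.sum(axis=1) > 0]
        if nonzero.shape[0] < 2 or nonzero.shape[1] < 2:
            logger.warning("skipping chi-square for %s: fewer than 2 levels observed", var)
            continue
        chi2, p, dof, _ = stats.chi2_contingency(nonzero.to_numpy(), correction=False)
        out.append(GroupComparison(var, summ, float(chi2), float(p), "chi_square", df=float(dof)))
    return out


def seasonal_count_test(
    daily_counts: pd.DataFrame, null: str = "season_length"
) -> GroupComparison:
    """Chi-square goodness-of-fit of daily counts against seasonal expectation.

    Expected totals are proportional to days per season in the observed range
    (``null="season_length"``) or flat across the four seasons
    (``null="uniform"``); df = 3. Requires the counts to span at least a full
    year so every season is represented.
    """
    dates = pd.to_datetime(daily_counts["date"])
    span = (dates.max() - dates.min()).days
    if span < 364:
        raise ValueError(f"counts span only {span + 1} days; a full year is required")
    seas = season_of_series(dates).to_numpy()
    counts = daily_counts["count"].to_numpy(dtype=float)
    observed = np.array([counts[seas == s].sum() for s in SEASONS])
    if null == "season_length":
        days = np.array([(seas == s).sum() for s in SEASONS], dtype=float)
        expected = observed.sum() * days / days.sum()
    elif null == "uniform":
        expected = np.full(4, observed.sum() / 4.0)
    else:
        raise ValueError(f"unknown null {null!r}")
    chi2, p = stats.chisquare(observed, expected)
    return GroupComparison(
        variable="seasonal_counts",
        group_summaries={s: float(o) for s, o in zip(SEASONS, observed)},
        statistic=float(chi2),
        p_value=float(p),
        test="chi_square",
        df=3.0,
    )


def table_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons into a cohort-characteristics CSV table."""
    rows = []
    for c in comparisons:
        if c.test in ("welch_t", "pooled_t"):
            s = c.group_summaries
            rows.append(
                {
                    "variable": c.variable,
                    "non_pneumonia": f"{s['non_pneumonia'][0]:.1f} ({s['non_pneumonia'][1]:.1f})",
                    "pneumonia": f"{s['pneumonia'][0]:.1f} ({s['pneumonia'][1]:.1f})",
                    "statistic": c.statistic,
                    "test": c.test,
                    "p": c.p_value,
                }
            )
        else:
            for lvl in sorted(
                {k for g in c.group_summaries.values() for k in g}
            ):
                get = lambda g: c.group_summaries.get(g, {}).get(lvl, (0, 0.0))
                rows.append(
                    {
                        "variable": f"{c.variable}:{lvl}",
                        "non_pneumonia": f"{get('non_pneumonia')[0]} ({get('non_pneumonia')[1]:.3f})",
                        "pneumonia": f"{get('pneumonia')[0]} ({get('pneumonia')[1]:.3f})",
                        "statistic": c.statistic,
                        "test": c.test,
                        "p": c.p_value,
                    }
                )
    return pd.DataFrame(rows)
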