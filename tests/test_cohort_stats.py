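"""Season tagging, daily aggregation and group-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pm25_dlnm import (
    aggregate_daily_counts,
    compare_groups,
    season_of,
    seasonal_count_test,
)
from pm25_dlnm.cohort_stats import season_of_series
from pm25_dlnm.published import TABLE1_COUNTS, reconstruct_cohort


class TestSeasons:
    @pytest.mark.parametrize(
        "day,expected",
        [
            ("2014-11-07", "winter"),
            ("2015-02-03", "winter"),
            ("2015-02-04", "spring"),
            ("2015-05-04", "spring"),
            ("2015-05-05", "summer"),
            ("2015-08-06", "summer"),
            ("2015-08-07", "fall"),
            ("2015-11-06", "fall"),
            ("2015-01-01", "winter"),
        ],
    )
    def test_boundaries_are_start_inclusive(self, day, expected):
        assert season_of(day) == expected

    @pytest.mark.parametrize("year", [2014, 2015, 2016])
    def test_four_intervals_tile_each_year(self, year):
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        seasons = season_of_series(days)
        assert set(seasons) == {"winter", "spring", "summer", "fall"}
        # every date maps to exactly one season, and the non-winter blocks are
        # contiguous (winter wraps the year end)
        assert len(seasons) == len(days)  # total function: no gaps
        for s in ("spring", "summer", "fall"):
            idx = np.flatnonzero(seasons.to_numpy() == s)
            assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))

    def test_vectorised_matches_scalar(self):
        days = pd.date_range("2016-01-01", "2016-12-31", freq="D")  # leap year
        vec = season_of_series(days)
        assert list(vec) == [season_of(d) for d in days]


class TestAggregation:
    def test_zero_filled_over_declared_range(self):
        empty = pd.DataFrame(columns=["admit_date", "group"])
        out = aggregate_daily_counts(empty, "pneumonia", ("2014-01-01", "2014-01-10"))
        assert len(out) == 10 and (out["count"] == 0).all()

    def test_counts_and_conservation(self):
        adm = pd.DataFrame(
            {
                "admit_date": pd.to_datetime(
                    ["2014-01-02"] * 3 + ["2014-01-04", "2014-01-04", "2014-01-05"]
                ),
                "group": ["pneumonia"] * 3 + ["non_pneumonia"] * 2 + ["pneumonia"],
            }
        )
        out = aggregate_daily_counts(adm, "pneumonia", ("2014-01-01", "2014-01-06"))
        assert out.loc[out["date"] == "2014-01-02", "count"].item() == 3
        assert out["count"].sum() == (adm["group"] == "pneumonia").sum()


class TestCompareGroups:
    def test_published_margin_proportions(self):
        # worked example: proportions recomputed from the published counts
        cohort = reconstruct_cohort()
        rows = {c.variable: c for c in compare_groups(cohort)}
        discharge = rows["discharge"].group_summaries
        assert discharge["pneumonia"]["die"] == (34, pytest.approx(34 / 391))
        assert round(discharge["pneumonia"]["die"][1], 3) == 0.087
        assert round(discharge["non_pneumonia"]["die"][1], 3) == 0.023
        assert round(discharge["pneumonia"]["aad"][1], 3) == 0.207
        assert round(discharge["non_pneumonia"]["aad"][1], 3) == 0.079
        gender = rows["gender"].group_summaries
        assert round(gender["pneumonia"]["M"][1], 3) == 0.685
        for var in ("gender", "source", "discharge"):
            for g, summ in rows[var].group_summaries.items():
                total = sum(p for _, p in summ.values())
                assert total == pytest.approx(1.0)

    def test_identical_groups_give_null_t(self):
        half = pd.DataFrame(
            {
                "admit_date": pd.Timestamp("2014-06-01"),
                "group": "pneumonia",
                "age": np.arange(20.0, 60.0),
            }
        )
        other = half.assign(group="non_pneumonia")
        rows = {c.variable: c for c in compare_groups(pd.concat([half, other]))}
        assert rows["age"].statistic == pytest.approx(0.0, abs=1e-12)
        assert rows["age"].p_value == pytest.approx(1.0)

    def test_chi_square_matches_formula_oracle(self, rng):
        # direct sum((O-E)^2 / E) on a hand-built 2x4 table
        table = np.array([[30, 45, 25, 10], [60, 40, 35, 15]])
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        chi2_direct = ((table - expected) ** 2 / expected).sum()
        sources = ["emergency", "icu", "ward", "outpatient"]
        rows = []
        for g, counts in zip(("pneumonia", "non_pneumonia"), table):
            for s, k in zip(sources, counts):
                rows.extend([(g, s)] * k)
        adm = pd.DataFrame(rows, columns=["group", "source"])
        adm["admit_date"] = pd.Timestamp("2014-06-01")
        out = {c.variable: c for c in compare_groups(adm)}
        assert out["source"].statistic == pytest.approx(chi2_direct, rel=1e-12)
        assert out["source"].df == 3

    def test_welch_agrees_with_pooled_on_balanced_equal_variance(self, rng):
        a = rng.normal(0.0, 1.0, 300)
        b = rng.normal(0.2, 1.0, 300)
        welch = stats.ttest_ind(a, b, equal_var=False)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        assert welch.statistic == pytest.approx(pooled.statistic, abs=1e-6)
        assert welch.pvalue == pytest.approx(pooled.pvalue, abs=1e-6)

    def test_day_of_admission_exposures_compared_when_env_given(self, small_env):
        dates = pd.to_datetime(small_env["date"]).iloc[:100]
        adm = pd.DataFrame(
            {
                "admit_date": list(dates) * 2,
                "group": ["pneumonia"] * 100 + ["non_pneumonia"] * 100,
            }
        )
        rows = {c.variable for c in compare_groups(adm, small_env)}
        assert {"pm25", "temperature"} <= rows


class TestSeasonalCountTest:
    def test_uniform_daily_counts_give_null_statistic(self):
        days = pd.date_range("2014-01-01", "2014-12-31", freq="D")
        counts = pd.DataFrame({"date": days, "count": 2.0})
        res = seasonal_count_test(counts)  # expectation follows season lengths
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.df == 3

    def test_uniform_null_oracle(self):
        # direct sum((O-E)^2/E) with E = 75: totals (100,100,50,50) -> 33.33
        days = pd.date_range("2014-01-01", "2015-01-10", freq="D")
        seasons = season_of_series(days).to_numpy()
        counts = np.zeros(len(days))
        for s, total in zip(("winter", "spring", "summer", "fall"), (100, 100, 50, 50)):
            first = np.flatnonzero(seasons == s)[0]
            counts[first] = total
        res = seasonal_count_test(
            pd.DataFrame({"date": days, "count": counts}), null="uniform"
        )
        assert res.statistic == pytest.approx(100 / 3, rel=1e-12)
        assert res.df == 3

    def test_short_span_rejected(self):
        days = pd.date_range("2014-01-01", periods=200, freq="D")
        with pytest.raises(ValueError, match="full year"):
            seasonal_count_test(pd.DataFrame({"date": days, "count": 1.0}))
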