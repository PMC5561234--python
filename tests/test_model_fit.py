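"""IRLS GLM fits against closed forms, generic optimizers and planted truths."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pm25_dlnm import (
    NullSurface,
    QuadraticSurface,
    SeparationWarning,
    SimulationConfig,
    fit_dlnm,
    fit_glm,
    fit_lagged_logistic,
    simulate_counts,
    simulate_environment,
)
from pm25_dlnm.model_fit import BINOMIAL_LOGIT, POISSON_LOG


def _loglik(beta, X, y, family):
    eta = X @ beta
    if family == POISSON_LOG:
        return float(np.sum(y * eta - np.exp(eta)))
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


class TestFitGlm:
    def test_poisson_intercept_only_is_log_mean(self, rng):
        y = rng.poisson(3.0, size=200)
        fit = fit_glm(np.ones((200, 1)), y, POISSON_LOG)
        assert fit.coefficients[0] == pytest.approx(math.log(y.mean()), abs=1e-8)
        assert fit.converged

    def test_logistic_slope_is_contingency_cross_ratio(self):
        # closed-form oracle: a 2x2 table's log odds ratio. Cells are the
        # published cohort's death-by-group split.
        a, b, c, d = 34, 357, 160, 6936
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_glm(X, y, BINOMIAL_LOGIT)
        assert fit.coefficients[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(math.log(c / d), abs=1e-8)

    @pytest.mark.parametrize("family", [POISSON_LOG, BINOMIAL_LOGIT])
    def test_matches_generic_likelihood_optimizer(self, family, rng):
        n, p = 120, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta_true = np.array([0.3, 0.5, -0.4])
        eta = X @ beta_true
        y = (
            rng.poisson(np.exp(eta))
            if family == POISSON_LOG
            else (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        )
        fit = fit_glm(X, y, family)
        res = optimize.minimize(
            lambda b: -_loglik(b, X, y, family),
            np.zeros(p),
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-6)

    def test_matches_statsmodels_covariance(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.2 + 0.4 * X[:, 1]))
        fit = fit_glm(X, y, POISSON_LOG)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.covariance, ref.cov_params(), rtol=1e-5)

    def test_deviance_decreases_monotonically(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.poisson(np.exp(0.5 + 0.3 * X[:, 1] - 0.2 * X[:, 2]))
        fit = fit_glm(X, y, POISSON_LOG)
        path = np.asarray(fit.deviance_path)
        assert np.all(np.diff(path) <= 1e-8 * (np.abs(path[:-1]) + 0.1))

    def test_wald_interval_coverage_is_nominal(self, rng):
        # Monte-Carlo harness: 95% intervals for a known Poisson slope
        beta = np.array([0.0, 0.3])
        hits = 0
        reps = 200
        for _ in range(reps):
            X = np.column_stack([np.ones(250), rng.normal(size=250)])
            y = rng.poisson(np.exp(X @ beta))
            fit = fit_glm(X, y, POISSON_LOG)
            se = fit.se()[1]
            hits += abs(fit.coefficients[1] - beta[1]) < 1.959964 * se
        assert 0.91 <= hits / reps <= 0.99

    def test_rank_deficiency_names_collinear_columns(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2.0 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(X, rng.poisson(1.0, 50), POISSON_LOG,
                    column_names=["intercept", "x", "doubled"])

    def test_complete_separation_warns(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        X = np.column_stack([np.ones(40), x])
        with pytest.warns(SeparationWarning):
            fit_glm(X, y, BINOMIAL_LOGIT)

    def test_invalid_responses_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_glm(X, np.array([1.0, -2.0, 0.0, 3.0]), POISSON_LOG)
        with pytest.raises(ValueError, match="0/1"):
            fit_glm(X, np.array([0.0, 0.5, 1.0, 1.0]), BINOMIAL_LOGIT)


class TestFitDlnm:
    def test_null_surface_coefficients_near_zero(self):
        cfg = SimulationConfig(n_days=2000, seed=21, true_surface=NullSurface())
        env = simulate_environment(cfg)
        counts = simulate_counts(env, cfg)
        fit, (cb_pm, _) = fit_dlnm(env, counts)
        idx = [fit.column_names.index(n) for n in cb_pm.column_names]
        z = fit.coefficients[idx] / fit.se()[idx]
        assert np.max(np.abs(z)) < 4.0

    def test_planted_saturday_effect_recovered(self):
        dow = [0.0] * 7
        dow[5] = 0.9
        cfg = SimulationConfig(
            n_days=3000, seed=22, true_surface=NullSurface(), dow_log_effects=tuple(dow)
        )
        env = simulate_environment(cfg)
        counts = simulate_counts(env, cfg)
        fit, _ = fit_dlnm(env, counts)
        i = fit.column_names.index("dow:Saturday")
        assert abs(fit.coefficients[i] - 0.9) < 4.0 * fit.se()[i]

    def test_date_misalignment_reports_first_mismatch(self, small_env, small_counts):
        shifted = small_counts.copy()
        shifted["date"] = pd.to_datetime(shifted["date"]) + pd.Timedelta(days=1)
        with pytest.raises(ValueError, match="misaligned at 2014-01-01"):
            fit_dlnm(small_env, shifted)


class TestLaggedLogistic:
    @staticmethod
    def _logistic_cohort(n_days=1100, per_day=7, slope=0.01, seed=31):
        cfg = SimulationConfig(n_days=n_days, seed=seed)
        env = simulate_environment(cfg)
        rng = np.random.default_rng(seed + 1)
        dates = pd.to_datetime(env["date"]).repeat(per_day).reset_index(drop=True)
        pm = env["pm25"].repeat(per_day).reset_index(drop=True).to_numpy()
        p = 1.0 / (1.0 + np.exp(-(-3.0 + slope * pm)))
        group = np.where(rng.random(len(p)) < p, "pneumonia", "non_pneumonia")
        adm = pd.DataFrame({"admit_date": dates, "group": group})
        return env, adm

    def test_same_day_pm25_slope_recovered(self):
        env, adm = self._logistic_cohort()
        fit = fit_lagged_logistic(adm, env, lag_days=0)
        i = fit.column_names.index("pm25")
        assert abs(fit.coefficients[i] - 0.01) < 4.0 * fit.se()[i]
        assert 0.995 < math.exp(fit.coefficients[i]) < 1.025

    def test_no2_excluded_by_default_and_included_on_request(self):
        env, adm = self._logistic_cohort(n_days=800)
        fit = fit_lagged_logistic(adm, env, lag_days=0)
        assert "no2" not in fit.column_names
        fit2 = fit_lagged_logistic(adm, env, lag_days=0, include_no2=True)
        assert "no2" in fit2.column_names

    def test_uncovered_lagged_dates_reported(self):
        env, adm = self._logistic_cohort(n_days=400)
        with pytest.raises(ValueError, match="2014-01-0"):
            fit_lagged_logistic(adm, env, lag_days=7)

    def test_degenerate_single_group_outcome_warns_of_separation(self):
        env, adm = self._logistic_cohort(n_days=400)
        adm = adm.assign(group="pneumonia")
        with pytest.warns(SeparationWarning):
            fit_lagged_logistic(adm.iloc[7:], env, lag_days=0)
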