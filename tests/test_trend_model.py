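"""Binomial GLM fitting, analysis of deviance, intervals, co-occurrence."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2

from gridocc.ebd_io import zero_fill
from gridocc.trend_model import (
    DegenerateResponseError,
    IntervalEstimate,
    OccupancyTrendGLM,
    annual_growth,
    confidence_interval,
    cooccurrence_rates,
    fit_occupancy_glm,
    likelihood_ratio_test,
    overdispersion_test,
    TrendFit,
)

from conftest import make_checklists, make_observations


def _table(rng, n_cells=30, n_years=6, base=-1.0, slope=0.3):
    """Small random cell-year table with a known generating trend."""
    rows = []
    for cell in range(n_cells):
        for t in range(n_years):
            p = expit(base + slope * t)
            rows.append(
                {
                    "cell_col": cell,
                    "cell_row": 0,
                    "year": 2003 + t,
                    "n_checklists": 1,
                    "effort_hours": float(rng.uniform(0.5, 8.0)),
                    "occupied_sp": bool(rng.random() < p),
                }
            )
    return pd.DataFrame(rows)


class TestFit:
    def test_all_unoccupied_is_degenerate(self):
        table = pd.DataFrame(
            {"year": [2003, 2004, 2005], "effort_hours": 1.0, "occupied_sp": False}
        )
        fit = fit_occupancy_glm(table, "sp")
        assert fit.degenerate and not fit.converged
        assert fit.params is None

    def test_empty_table_rejected(self):
        table = pd.DataFrame(columns=["year", "effort_hours", "occupied_sp"])
        with pytest.raises(ValueError):
            fit_occupancy_glm(table, "sp")

    def test_single_year_rejected(self):
        table = pd.DataFrame(
            {"year": [2003, 2003], "effort_hours": 1.0, "occupied_sp": [True, False]}
        )
        with pytest.raises(ValueError, match="distinct years"):
            fit_occupancy_glm(table, "sp")

    def test_matches_statsmodels_glm(self, rng):
        """Independent cross-check against a reference GLM implementation."""
        import statsmodels.api as sm

        table = _table(rng)
        fit = fit_occupancy_glm(table, "sp", predictors=("year", "effort"))
        year_c = table["year"] - table["year"].mean()
        X = sm.add_constant(
            np.column_stack([year_c, table["effort_hours"]])
        )
        ref = sm.GLM(
            table["occupied_sp"].astype(float), X, family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.params, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.deviance, ref.deviance, rtol=1e-8)
        np.testing.assert_allclose(
            fit.pearson_chi2, ref.pearson_chi2, rtol=1e-6
        )
        assert fit.df_residual == ref.df_resid

    def test_loglik_matches_direct_numeric_maximization(self, rng):
        table = _table(rng, n_cells=5, n_years=4)
        fit = fit_occupancy_glm(table, "sp")
        y = table["occupied_sp"].to_numpy(float)
        year_c = (table["year"] - table["year"].mean()).to_numpy()

        def negloglik(beta):
            eta = beta[0] + beta[1] * year_c
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        best = optimize.minimize(negloglik, [0.0, 0.0], method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.loglik == pytest.approx(-best.fun, abs=1e-6)

    def test_year_shift_changes_intercept_only(self, rng):
        table = _table(rng)
        fit_a = fit_occupancy_glm(table, "sp")
        shifted = table.assign(year=table["year"] + 7)
        fit_b = fit_occupancy_glm(shifted, "sp")
        assert fit_b.coef("year") == pytest.approx(fit_a.coef("year"), abs=1e-10)

    def test_complete_separation_flagged(self):
        table = pd.DataFrame(
            {
                "year": [2003, 2004, 2005, 2006, 2007, 2008],
                "effort_hours": 1.0,
                "occupied_sp": [False, False, False, True, True, True],
            }
        )
        fit = fit_occupancy_glm(table, "sp")
        assert fit.separation and not fit.converged

    def test_estimator_sklearn_interface(self, rng):
        from sklearn.base import clone

        table = _table(rng)
        model = OccupancyTrendGLM(predictors=("year",))
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        model.fit(table.rename(columns={"effort_hours": "effort"}), table["occupied_sp"])
        proba = model.predict_proba(table.rename(columns={"effort_hours": "effort"}))
        assert proba.shape == (len(table), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert model.converged_

    def test_recovers_generating_slope_at_moderate_size(self, rng):
        table = _table(rng, n_cells=300, n_years=14, base=-2.0, slope=0.20)
        fit = fit_occupancy_glm(table, "sp")
        assert fit.coef("year") == pytest.approx(0.20, abs=0.05)


class TestAnalysisOfDeviance:
    def test_identical_models_give_zero_statistic(self, rng):
        table = _table(rng)
        fit = fit_occupancy_glm(table, "sp")
        result = likelihood_ratio_test(fit, fit)
        assert result.statistic == 0.0 and result.df == 0 and result.p == 1.0

    def test_year_vs_year_effort_has_one_df(self, rng):
        table = _table(rng)
        null_fit = fit_occupancy_glm(table, "sp")
        full_fit = fit_occupancy_glm(table, "sp", predictors=("year", "effort"))
        result = likelihood_ratio_test(null_fit, full_fit)
        assert result.df == 1
        assert 0.0 <= result.p <= 1.0

    def test_statistic_equals_per_row_likelihood_recomputation(self, rng):
        table = _table(rng)
        null_fit = fit_occupancy_glm(table, "sp")
        full_fit = fit_occupancy_glm(table, "sp", predictors=("year", "effort"))
        result = likelihood_ratio_test(null_fit, full_fit)

        def deviance(fit):
            mu = expit(fit._X @ fit.params)
            y = fit._y
            return -2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

        assert result.statistic == pytest.approx(
            deviance(null_fit) - deviance(full_fit), abs=1e-8
        )

    def test_different_row_counts_rejected(self, rng):
        table = _table(rng)
        fit_a = fit_occupancy_glm(table, "sp")
        fit_b = fit_occupancy_glm(table.iloc[:-5], "sp")
        with pytest.raises(ValueError):
            likelihood_ratio_test(fit_b, fit_a)


class TestOverdispersion:
    def test_statistic_matches_hand_computation(self, rng):
        table = _table(rng, n_cells=10, n_years=3)
        fit = fit_occupancy_glm(table, "sp")
        mu = expit(fit._X @ fit.params)
        y = fit._y
        manual = float(np.sum((y - mu) ** 2 / (mu * (1 - mu))))
        result = overdispersion_test(fit)
        assert result.statistic == pytest.approx(manual, abs=1e-10)
        assert result.ratio == pytest.approx(manual / fit.df_residual, abs=1e-10)
        assert result.p == pytest.approx(chi2.sf(manual, fit.df_residual), abs=1e-12)

    def test_simulated_binomial_data_has_ratio_near_one(self, rng):
        """Under the fitted model the Pearson ratio averages ~1 (200 reps)."""
        years = np.tile(np.arange(10), 40)
        p = expit(-0.5 + 0.15 * (years - years.mean()))
        ratios = []
        for _ in range(200):
            table = pd.DataFrame(
                {
                    "year": 2003 + years,
                    "effort_hours": 1.0,
                    "occupied_sp": rng.random(len(years)) < p,
                }
            )
            fit = fit_occupancy_glm(table, "sp")
            ratios.append(overdispersion_test(fit).ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_no_residual_df_rejected(self):
        fit = TrendFit(
            names=("intercept", "year"), params=np.zeros(2), cov=np.eye(2),
            deviance=0.0, null_deviance=0.0, df_residual=0, pearson_chi2=0.0,
            n_obs=2, converged=True,
        )
        with pytest.raises(ValueError):
            overdispersion_test(fit)


class TestGrowthSummary:
    @pytest.mark.parametrize(
        "b,pct,odds",
        [(0.0, 0.0, 1.0), (0.18, 18.0, np.exp(0.18)), (np.log(2), 100 * np.log(2), 2.0)],
    )
    def test_both_conventions_reported(self, b, pct, odds):
        fit = TrendFit(
            names=("intercept", "year"), params=np.array([0.0, b]), cov=np.eye(2),
            deviance=1.0, null_deviance=1.0, df_residual=10, pearson_chi2=1.0,
            n_obs=12, converged=True,
        )
        growth = annual_growth(fit)
        assert growth["percent_per_year_log_odds"] == pytest.approx(pct)
        assert growth["odds_ratio"] == pytest.approx(odds)
        assert growth["percent_odds_change_per_year"] == pytest.approx(100 * (odds - 1))


class TestConfidenceIntervals:
    def test_wald_interval_symmetric(self, rng):
        table = _table(rng)
        fit = fit_occupancy_glm(table, "sp")
        interval = confidence_interval(fit, "year", method="wald")
        assert interval.upper - interval.point == pytest.approx(
            interval.point - interval.lower, abs=1e-12
        )

    def test_profile_matches_independent_deviance_scan(self, rng):
        """Profile endpoints vs scipy-optimized deviance root-finding."""
        table = _table(rng, n_cells=10, n_years=3)
        fit = fit_occupancy_glm(table, "sp")
        interval = confidence_interval(fit, "year", method="profile")
        y = fit._y
        year_c = fit._X[:, 1]

        # profile deviance(b) = 2 * min_a nll(a, b) up to the saturated term,
        # which cancels in the crossing equation below
        def crossing(b):
            def nll(a):
                eta = a + b * year_c
                return -np.sum(y * eta - np.log1p(np.exp(eta)))

            best = optimize.minimize_scalar(nll, bounds=(-30, 30), method="bounded",
                                            options={"xatol": 1e-12})
            return 2 * best.fun - (fit.deviance + chi2.ppf(0.95, 1))

        lower = optimize.brentq(crossing, interval.point - 10, interval.point, xtol=1e-8)
        upper = optimize.brentq(crossing, interval.point, interval.point + 10, xtol=1e-8)
        assert interval.lower == pytest.approx(lower, abs=1e-4)
        assert interval.upper == pytest.approx(upper, abs=1e-4)

    def test_degenerate_fit_rejected(self):
        fit = TrendFit(
            names=(), params=None, cov=None, deviance=np.nan, null_deviance=np.nan,
            df_residual=5, pearson_chi2=np.nan, n_obs=6, converged=False, degenerate=True,
        )
        with pytest.raises(DegenerateResponseError):
            confidence_interval(fit, "year")

    def test_zero_variance_rejected(self):
        fit = TrendFit(
            names=("intercept", "year"), params=np.array([0.0, 0.1]),
            cov=np.zeros((2, 2)), deviance=1.0, null_deviance=1.0,
            df_residual=10, pearson_chi2=1.0, n_obs=12, converged=True,
        )
        with pytest.raises(ValueError, match="variance"):
            confidence_interval(fit, "year")

    def test_interval_must_contain_point(self):
        with pytest.raises(ValueError):
            IntervalEstimate(point=1.0, lower=2.0, upper=3.0, level=0.95, method="wald")


class TestCooccurrence:
    def _detections(self, pairs):
        checklists = make_checklists(
            [{"checklist_id": f"S{i}"} for i in range(6)]
        )
        return zero_fill(checklists, make_observations(pairs), ["a", "b"])

    def test_disjoint_sets_give_zero(self):
        detections = self._detections([("S0", "a", 1), ("S1", "b", 1)])
        result = cooccurrence_rates(detections, "a", "b")
        assert result.pct_a_with_b == 0.0 and result.pct_b_with_a == 0.0

    def test_identical_sets_give_hundred(self):
        detections = self._detections(
            [("S0", "a", 1), ("S0", "b", 1), ("S1", "a", 1), ("S1", "b", 1)]
        )
        result = cooccurrence_rates(detections, "a", "b")
        assert result.pct_a_with_b == 100.0 and result.pct_b_with_a == 100.0

    def test_random_fixture_matches_brute_force(self, rng):
        pairs = []
        seen = set()
        for _ in range(15):
            cid = f"S{rng.integers(6)}"
            sp = ["a", "b"][rng.integers(2)]
            if (cid, sp) not in seen:
                seen.add((cid, sp))
                pairs.append((cid, sp, 1))
        detections = self._detections(pairs)
        result = cooccurrence_rates(detections, "a", "b")
        with_a = {cid for cid, sp, _ in pairs if sp == "a"}
        with_b = {cid for cid, sp, _ in pairs if sp == "b"}
        both = len(with_a & with_b)
        if with_a:
            assert result.pct_a_with_b == round(100 * both / len(with_a), 1)
        else:
            assert result.pct_a_with_b is None

    def test_zero_presence_direction_undefined(self):
        detections = self._detections([("S0", "a", 1)])
        result = cooccurrence_rates(detections, "a", "b")
        assert result.pct_b_with_a is None
        assert result.pct_a_with_b == 0.0

    def test_missing_species_rejected(self):
        detections = self._detections([("S0", "a", 1)])
        with pytest.raises(KeyError):
            cooccurrence_rates(detections, "a", "zzz")
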