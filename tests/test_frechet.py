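"""Global Fréchet regression: weight identities, degeneracies, pipeline sanity."""

import numpy as np
import pandas as pd
import pytest

from lifespanfda.distributions import default_prob_grid, empirical_quantile, wasserstein_distance
from lifespanfda.frechet import (
    CohortCell,
    DegenerateDesignError,
    GlobalFrechetRegression,
    RemainingLifetimeFrechet,
    activity_median_split,
    diet_indicators,
    remaining_lifetime_cohorts,
)
from lifespanfda.simulate import CohortSpec, gen_lifespans
from conftest import make_point_mass_curves


class TestWeights:
    @pytest.fixture
    def scalar_fit(self):
        grid = default_prob_grid(11)
        X = np.array([0.0, 1.0, 2.0])
        Q = make_point_mass_curves([1.0, 2.0, 3.0], grid)
        return GlobalFrechetRegression(X, Q, grid).fit()

    def test_weights_at_mean_are_one(self, scalar_fit):
        np.testing.assert_allclose(scalar_fit.weights(1.0), np.ones(3), atol=1e-12)

    def test_mean_weight_is_one(self, scalar_fit, rng):
        for x in rng.normal(0, 5, 10):
            assert scalar_fit.weights(x).mean() == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_weights(self, scalar_fit):
        # Xbar = 1, Sigma = 2/3, x = 2: s_i = 1 + (X_i - 1) * (3/2)
        np.testing.assert_allclose(scalar_fit.weights(2.0), [-0.5, 1.0, 2.5], atol=1e-12)

    def test_singular_design_refused(self):
        grid = default_prob_grid(11)
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        Q = make_point_mass_curves([1.0, 2.0, 3.0], grid)
        with pytest.raises(DegenerateDesignError):
            GlobalFrechetRegression(X, Q, grid).fit()


class TestPredict:
    def test_identical_responses(self, rng):
        grid = default_prob_grid(51)
        q = np.sort(rng.exponential(2.0, grid.size))
        Q = np.tile(q, (6, 1))
        fit = GlobalFrechetRegression(np.arange(6.0), Q, grid).fit()
        for x in (-3.0, 0.0, 10.0):
            np.testing.assert_allclose(fit.predict(x).quantiles, q, atol=1e-10)

    def test_barycenter_at_mean(self, rng):
        grid = default_prob_grid(51)
        Q = np.sort(rng.exponential(2.0, (8, grid.size)), axis=1)
        X = rng.normal(0, 1, 8)
        fit = GlobalFrechetRegression(X, Q, grid).fit()
        np.testing.assert_allclose(
            fit.predict(X.mean()).quantiles, Q.mean(axis=0), atol=1e-10
        )

    def test_location_model_matches_ols(self):
        """Point masses at 2 + 3 X_i: prediction at x=5 is the OLS value 17."""
        grid = default_prob_grid(21)
        X = np.arange(10.0)
        Q = make_point_mass_curves(2.0 + 3.0 * X, grid)
        fit = GlobalFrechetRegression(X, Q, grid).fit()
        pred = fit.predict(5.0).quantiles
        np.testing.assert_allclose(pred, 17.0, atol=1e-6)

    def test_scalar_embedding_equals_multiple_regression(self, rng):
        """Point-mass responses reproduce multiple-linear-regression fits."""
        n, p = 40, 3
        X = rng.normal(0, 1, (n, p))
        beta = np.array([1.0, -2.0, 0.5])
        y = 4.0 + X @ beta + rng.normal(0, 0.3, n)
        grid = default_prob_grid(21)
        fit = GlobalFrechetRegression(X, make_point_mass_curves(y, grid), grid).fit()
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(X)).fit()
        for x in rng.normal(0, 1, (5, p)):
            pred = fit.predict(x).quantiles
            expected = ols.predict(np.concatenate(([1.0], x)))[0]
            np.testing.assert_allclose(pred, expected, atol=1e-8)

    def test_isotonic_projection_is_minimiser(self, rng):
        """The projected prediction beats any monotone candidate curve."""
        grid = default_prob_grid(41)
        w = np.gradient(grid)
        Q = np.sort(rng.normal(5, 2, (12, grid.size)), axis=1)
        X = rng.normal(0, 1, 12)
        fit = GlobalFrechetRegression(X, Q, grid).fit()
        x = 2.5
        s = fit.weights(x)
        pred = fit.predict(x).quantiles

        def criterion(v):
            return float(np.sum(s[:, None] * (Q - v[None]) ** 2 @ w))

        base = criterion(pred)
        g = (s @ Q) / s.sum()
        candidates = [np.sort(g), np.maximum.accumulate(g)]
        for _ in range(20):
            candidates.append(pred + np.cumsum(rng.uniform(0, 0.05, grid.size)) - 0.5)
        for cand in candidates:
            assert base <= criterion(cand) + 1e-9


class TestCohorts:
    def test_hand_filter(self):
        ls = pd.DataFrame(
            {"fly_id": ["a", "b", "c"], "diet": "C10", "age_at_death": [5.0, 10.0, 20.0]}
        )
        cells = remaining_lifetime_cohorts(ls, [7.0], min_cell_size=1)
        assert len(cells) == 1
        np.testing.assert_allclose(np.sort(cells[0].remaining), [3.0, 13.0])

    def test_zero_age_full_lifespans(self, small_lifespans):
        cells = remaining_lifetime_cohorts(small_lifespans, [0.0], min_cell_size=1)
        np.testing.assert_allclose(
            np.sort(cells[0].remaining), np.sort(small_lifespans["age_at_death"])
        )

    def test_cells_partition_survivors(self, small_lifespans):
        a = 20.0
        cov = diet_indicators(small_lifespans)
        cells = remaining_lifetime_cohorts(small_lifespans, [a], cov, min_cell_size=1)
        n_alive = (small_lifespans["age_at_death"] > a).sum()
        assert sum(c.size for c in cells) == n_alive

    def test_small_cells_dropped(self, small_lifespans):
        cells = remaining_lifetime_cohorts(small_lifespans, [89.0], min_cell_size=5)
        assert cells == []

    def test_nonpositive_remaining_rejected(self):
        with pytest.raises(ValueError):
            CohortCell(5.0, (), np.array([3.0, -1.0]))


class TestMedianSplit:
    def _activity(self, totals):
        rows = []
        for i, tot in enumerate(totals):
            rows.append({"fly_id": f"f{i}", "day": 1.0, "hour": 0.0, "count": tot})
        return pd.DataFrame(rows)

    def _lifespans(self, n):
        return pd.DataFrame(
            {"fly_id": [f"f{i}" for i in range(n)], "diet": "C20",
             "age_at_death": [50.0] * n}
        )

    def test_hand_median(self):
        ind = activity_median_split(self._activity([10, 20, 30]), self._lifespans(3), 5.0)
        assert ind.to_dict() == {"f0": 0.0, "f1": 0.0, "f2": 1.0}

    def test_all_ties_low(self):
        ind = activity_median_split(self._activity([7, 7, 7, 7]), self._lifespans(4), 5.0)
        assert (ind == 0.0).all()

    def test_order_invariance(self):
        act = self._activity([3, 9, 1, 7])
        ls = self._lifespans(4)
        a = activity_median_split(act, ls, 5.0)
        b = activity_median_split(act.iloc[::-1].reset_index(drop=True), ls, 5.0)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


class TestRemainingLifetimePipeline:
    def test_mean_remaining_decreases_with_age(self, small_lifespans):
        res = RemainingLifetimeFrechet(
            small_lifespans, covariates=diet_indicators(small_lifespans)
        ).fit()
        m1 = res.predict_quantile(1.0, (0.0, 0.0)).mean()
        m30 = res.predict_quantile(30.0, (0.0, 0.0)).mean()
        assert m30 < m1

    def test_null_diet_effect_exchangeable(self):
        """Diet-independent hazard: the between-diet distance of predicted
        distributions is no larger than under random diet relabellings."""
        alpha = {d: 0.0003 for d in ("C10", "C20", "C50")}
        ls = gen_lifespans(CohortSpec(n_flies=96, gompertz_alpha_per_diet=alpha, seed=0))

        def diet_gap(table):
            res = RemainingLifetimeFrechet(table, covariates=diet_indicators(table)).fit()
            gaps = []
            for a in (5.0, 15.0, 25.0):
                q10 = res.predict_quantile(a, (0.0, 0.0))
                gaps.append(wasserstein_distance(q10, res.predict_quantile(a, (1.0, 0.0))))
                gaps.append(wasserstein_distance(q10, res.predict_quantile(a, (0.0, 1.0))))
            return max(gaps)

        observed = diet_gap(ls)
        rng = np.random.default_rng(1)
        null_gaps = []
        for _ in range(19):
            perm = ls.copy()
            perm["diet"] = rng.permutation(perm["diet"].to_numpy())
            null_gaps.append(diet_gap(perm))
        # under exchangeability the observed gap is a typical draw from the
        # permutation distribution (and stays on the few-day sampling scale)
        assert observed <= np.quantile(null_gaps, 0.95) + 1e-9
        assert observed < 5.0

    def test_smooth_in_age(self, small_lifespans):
        """Predictions move smoothly as the current age alive varies."""
        res = RemainingLifetimeFrechet(
            small_lifespans, covariates=diet_indicators(small_lifespans)
        ).fit()
        grid = res.model.prob_grid
        preds = [res.predict_quantile(float(a), (0.0, 0.0)) for a in range(1, 31)]
        consec = [
            wasserstein_distance(preds[i], preds[i + 1]) for i in range(len(preds) - 1)
        ]
        cells = [c for c in res.cells if c.covariates == (0.0, 0.0)]
        cell_q = {c.age: empirical_quantile(c.remaining, grid) for c in cells}
        ages = sorted(cell_q)
        cell_d = [
            wasserstein_distance(cell_q[a], cell_q[b]) for a, b in zip(ages, ages[1:])
        ]
        assert max(consec) <= 3.0 * np.mean(cell_d)

    def test_activity_adjusted_fit(self, small_lifespans, recovery_activity_truth):
        """High/low activity indicator enters the fit as a covariate."""
        from lifespanfda.simulate import gen_activity

        c20 = small_lifespans[small_lifespans["diet"] == "C20"]
        act = gen_activity(c20, recovery_activity_truth, seed=8)
        split = activity_median_split(act, c20, a=10.0)
        cov = split.to_frame()
        res = RemainingLifetimeFrechet(
            c20, ages=range(5, 26), covariates=cov, min_cell_size=3
        ).fit()
        q_low = res.predict_quantile(10.0, (0.0,))
        q_high = res.predict_quantile(10.0, (1.0,))
        assert np.all(np.isfinite(q_low.quantiles))
        assert wasserstein_distance(q_low, q_high) >= 0.0

    def test_training_point_exactness_linear_responses(self):
        """Exact at training x when responses are linear in quantile space."""
        grid = default_prob_grid(31)
        X = np.linspace(0, 9, 10)
        base = np.sort(np.random.default_rng(1).exponential(1.0, grid.size))
        Q = base[None] + 2.0 * X[:, None]
        fit = GlobalFrechetRegression(X, Q, grid).fit()
        for i in (0, 4, 9):
            np.testing.assert_allclose(fit.predict(X[i]).quantiles, Q[i], atol=1e-8)
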