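"""Cox point-process regression: event handling, decomposition, link recovery."""

import numpy as np
import pandas as pd
import pytest

from lifespanfda.cox import (
    CoxPointProcessRegression,
    EventProcessRecord,
    IntensityEstimate,
    counts_to_events,
    estimate_intensity,
)
from lifespanfda.distributions import DensityCurve, QuantileCurve, default_prob_grid
from lifespanfda.simulate import CohortSpec, EggGroundTruth, gen_egg_counts, gen_lifespans


class TestCountsToEvents:
    def test_three_events_first_day(self):
        eggs = pd.DataFrame({"fly_id": ["a"], "day": [1], "eggs": [3]})
        (rec,) = counts_to_events(eggs, jitter_seed=0)
        assert rec.m == 3
        assert np.all((rec.event_times > 0) & (rec.event_times <= 1))

    def test_conservation_and_rebinning(self, egg_cohort):
        _, _, eggs = egg_cohort
        sub = eggs[eggs["fly_id"].isin(eggs["fly_id"].unique()[:20])]
        records = counts_to_events(sub, jitter_seed=1)
        horizon_counts = sub[sub["day"] <= 35].groupby("fly_id")["eggs"].sum()
        for rec in records:
            assert rec.m == horizon_counts[rec.fly_id]
            rebinned = np.histogram(rec.event_times, bins=np.arange(0, 36))[0]
            original = (
                sub[(sub["fly_id"] == rec.fly_id) & (sub["day"] <= 35)]
                .set_index("day")["eggs"]
                .reindex(range(1, 36), fill_value=0)
                .to_numpy()
            )
            np.testing.assert_array_equal(rebinned, original)

    def test_negative_counts_rejected(self):
        eggs = pd.DataFrame({"fly_id": ["a"], "day": [1], "eggs": [-1]})
        with pytest.raises(ValueError):
            counts_to_events(eggs, jitter_seed=0)


class TestEstimateIntensity:
    def test_tau_equals_event_count(self, rng):
        rec = EventProcessRecord("a", rng.uniform(0, 35, 57), 35.0)
        est = estimate_intensity(rec)
        assert est.tau == 57.0

    def test_below_threshold_excluded(self):
        rec = EventProcessRecord("a", [1.0, 2.0], 35.0)
        assert estimate_intensity(rec, m_min=10) is None

    def test_single_day_peak(self):
        rec = EventProcessRecord("a", np.full(50, 20.0) + np.linspace(-0.4, 0.4, 50), 35.0)
        est = estimate_intensity(rec)
        peak = est.density.age_grid[np.argmax(est.density.density)]
        assert abs(peak - 20.0) < 1.0

    def test_homogeneous_poisson(self, rng):
        """Rate-2 Poisson on [0,35]: tau ~ 70 and f ~ uniform.

        With ~70 events the kernel estimate's pointwise relative sd is about
        sqrt(R(K) / (n h f^-1)) ~ 0.2, so the interior sup error is checked
        at the level that variance bound implies rather than tighter.
        """
        taus, sup_errs = [], []
        for _ in range(60):
            m = rng.poisson(70)
            rec = EventProcessRecord("a", np.sort(rng.uniform(0, 35, m)), 35.0)
            est = estimate_intensity(rec)
            taus.append(est.tau)
            interior = (est.density.age_grid > 3) & (est.density.age_grid < 32)
            sup_errs.append(np.max(np.abs(est.density.density[interior] - 1 / 35)) * 35)
        se = np.std(taus, ddof=1) / np.sqrt(len(taus))
        assert abs(np.mean(taus) - 70.0) < 3 * se
        assert np.median(sup_errs) < 0.40
        # averaging the per-realization densities removes the kernel noise
        grids = np.linspace(0, 35, 141)
        avg = np.mean(
            [estimate_intensity(
                EventProcessRecord("a", np.sort(rng.uniform(0, 35, rng.poisson(70))), 35.0)
            ).density.density for _ in range(100)],
            axis=0,
        )
        interior = (grids > 3) & (grids < 32)
        assert np.max(np.abs(avg[interior] - 1 / 35)) * 35 < 0.15


def _constant_intensity(tau, grid):
    dens = np.ones_like(grid) / np.trapezoid(np.ones_like(grid), grid)
    return IntensityEstimate(tau, DensityCurve(grid, dens))


class TestFit:
    def test_identical_intensities_constant_prediction(self, rng):
        grid = np.linspace(0, 35, 71)
        x = rng.uniform(36, 80, 10)
        intens = [_constant_intensity(50.0, grid) for _ in range(10)]
        res = CoxPointProcessRegression(x, intens).fit()
        for xv in (40.0, 70.0):
            assert res.predict_tau(xv) == pytest.approx(50.0, abs=1e-8)
            g, lam = res.predict_intensity(xv)
            interior = (g > 2) & (g < 33)
            np.testing.assert_allclose(lam[interior], 50.0 / 35.0, rtol=0.05)

    def test_exact_linear_tau_link(self, rng):
        grid = np.linspace(0, 35, 71)
        x = rng.uniform(36, 90, 25)
        intens = [_constant_intensity(100.0 - 0.5 * xi, grid) for xi in x]
        res = CoxPointProcessRegression(x, intens).fit()
        assert res.tau_slope == pytest.approx(-0.5, abs=1e-8)
        assert res.tau_intercept == pytest.approx(100.0, abs=1e-6)

    def test_conservation_of_total_events(self, egg_cohort):
        """Mean predicted tau over training ages equals mean observed count."""
        ls, _, eggs = egg_cohort
        model = CoxPointProcessRegression.from_tables(eggs, ls, jitter_seed=3)
        res = model.fit()
        predicted = np.mean([res.predict_tau(xi) for xi in model.x])
        observed = res.taus.mean()
        assert abs(predicted - observed) / observed < 0.02

    def test_drifting_peak_sign_recovery(self, egg_cohort):
        """Later peaks for long-lived flies appear in the fitted densities."""
        ls, _, eggs = egg_cohort
        res = CoxPointProcessRegression.from_tables(eggs, ls, jitter_seed=3).fit()
        mean_small = res.predict_density_quantile(40.0).mean()
        mean_large = res.predict_density_quantile(85.0).mean()
        assert mean_large > mean_small


class TestPredictIntensity:
    def test_intensity_integrates_to_tau(self, egg_cohort):
        ls, _, eggs = egg_cohort
        res = CoxPointProcessRegression.from_tables(eggs, ls, jitter_seed=3).fit()
        for x in (40.0, 60.0, 85.0):
            grid, lam = res.predict_intensity(x)
            assert np.trapezoid(lam, grid) == pytest.approx(res.predict_tau(x), abs=1e-3)

    def test_null_link_flat_in_x(self):
        """No association between eggs and lifespan: intensity constant in x."""
        ls = gen_lifespans(CohortSpec(n_flies=300, min_age=36.0, seed=2))
        truth = EggGroundTruth.from_lifespans(
            ls, seed=3,
            link={"tau_slope": 0.0, "peak_slope": 0.0, "spread_slope": 0.0},
        )
        eggs = gen_egg_counts(ls, truth, seed=4)
        res = CoxPointProcessRegression.from_tables(eggs, ls, jitter_seed=5).fit()
        g1, lam1 = res.predict_intensity(40.0)
        _, lam2 = res.predict_intensity(85.0)
        assert np.max(np.abs(lam1 - lam2)) < 0.10 * lam1.max()

    def test_cost_of_reproduction_pattern(self, egg_cohort):
        """Early intensity decreases and late intensity increases with
        age-at-death, the qualitative cost-of-reproduction signature."""
        ls, _, eggs = egg_cohort
        res = CoxPointProcessRegression.from_tables(eggs, ls, jitter_seed=3).fit()
        early, late = [], []
        for x in (40.0, 60.0, 85.0):
            grid, lam = res.predict_intensity(x)
            early.append(np.trapezoid(lam[grid <= 15], grid[grid <= 15]))
            late.append(np.trapezoid(lam[grid > 30], grid[grid > 30]))
        assert early[0] > early[1] > early[2]
        assert late[0] < late[1] < late[2]


class TestDecomposition:
    def test_separated_fit_minimises_product_criterion(self, rng):
        """Brute-force candidate search cannot beat the separated fit."""
        grid = default_prob_grid(41)
        n = 5
        x = np.linspace(37, 80, n)
        intens = []
        for i, xi in enumerate(x):
            dens_grid = np.linspace(0, 35, 71)
            center = 10 + 0.1 * xi + rng.normal(0, 1)
            dens = np.exp(-0.5 * ((dens_grid - center) / 5) ** 2)
            dens /= np.trapezoid(dens, dens_grid)
            intens.append(IntensityEstimate(80 - 0.4 * xi + rng.normal(0, 2),
                                            DensityCurve(dens_grid, dens)))
        model = CoxPointProcessRegression(x, intens, prob_grid=grid)
        res = model.fit()
        for x0 in (45.0, 70.0):
            tau_hat = res.predict_tau(x0)
            q_hat = res.predict_density_quantile(x0)
            base = res.criterion(x0, tau_hat, q_hat)
            # tau candidates on a coarse grid, f candidates from the observed
            # quantile curves, their barycenter and monotone perturbations
            quantiles = [QuantileCurve(grid, row) for row in model.fit().density_fit.model.Q]
            f_cands = quantiles + [q_hat]
            mean_q = np.mean([q.quantiles for q in quantiles], axis=0)
            f_cands.append(QuantileCurve(grid, mean_q))
            for _ in range(10):
                bump = np.cumsum(rng.uniform(0, 0.2, grid.size))
                f_cands.append(QuantileCurve(grid, q_hat.quantiles + bump - bump.mean()))
            for tau_c in np.linspace(max(tau_hat - 10, 0), tau_hat + 10, 21):
                for f_c in f_cands:
                    assert base <= res.criterion(x0, float(tau_c), f_c) + 1e-9

    def test_overdispersion_of_generator_counts(self, egg_cohort):
        """Cox (doubly stochastic) structure: daily count variance > mean."""
        _, _, eggs = egg_cohort
        daily = eggs[eggs["day"] <= 35].pivot_table(
            index="fly_id", columns="day", values="eggs"
        )
        ratio = (daily.var() / daily.mean()).median()
        assert ratio > 1.0
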