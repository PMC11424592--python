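"""Synthetic cohort generators: determinism, moments, ground-truth round-trips."""

import numpy as np
import pandas as pd
import pytest

from lifespanfda import io as lio
from lifespanfda.simulate import (
    ActivityGroundTruth,
    BehaviorGroundTruth,
    CohortSpec,
    EggGroundTruth,
    gen_activity,
    gen_activity_surfaces,
    gen_behavior,
    gen_behavior_trajectories,
    gen_egg_counts,
    gen_lifespans,
)
from lifespanfda._utils import trapezoid_weights


class TestLifespans:
    def test_seeded_determinism(self):
        spec = CohortSpec(n_flies=50, seed=11)
        pd.testing.assert_frame_equal(gen_lifespans(spec), gen_lifespans(spec))

    def test_exponential_limit_mean(self):
        """beta = 0 reduces to an exponential lifetime law with mean 1/alpha."""
        spec = CohortSpec(
            n_flies=2000,
            gompertz_alpha_per_diet={d: 0.05 for d in ("C10", "C20", "C50")},
            gompertz_beta=0.0,
            max_age=1e9,
            seed=3,
        )
        ages = gen_lifespans(spec)["age_at_death"]
        se = 20.0 / np.sqrt(2000)
        assert abs(ages.mean() - 20.0) < 3 * se

    def test_huge_alpha_short_lives(self):
        spec = CohortSpec(
            n_flies=100,
            gompertz_alpha_per_diet={d: 1e3 for d in ("C10", "C20", "C50")},
            seed=0,
        )
        assert (gen_lifespans(spec)["age_at_death"] < 1.0).all()

    def test_min_age_conditioning(self):
        ls = gen_lifespans(CohortSpec(n_flies=200, min_age=35.0, seed=5))
        assert (ls["age_at_death"] > 35.0).all()
        assert len(ls) == 200

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_flies": 0},
            {"max_age": -1.0},
            {"min_age": 95.0},
            {"gompertz_alpha_per_diet": {"C10": -1.0, "C20": 1.0, "C50": 1.0}},
        ],
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)


class TestActivity:
    def test_truth_orthonormality_enforced(self, recovery_activity_truth):
        t = recovery_activity_truth
        w = trapezoid_weights(t.hour_grid)
        gram = (t.hour_eigenfunctions * w) @ t.hour_eigenfunctions.T
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-6)

    def test_zero_variance_no_noise_gives_mean(self, small_lifespans):
        truth = ActivityGroundTruth.default(score_variances=[[0.0, 0.0], [0.0, 0.0]])
        _, surfaces, _ = gen_activity_surfaces(
            small_lifespans.head(5), truth, seed=1, noise="none", link="identity"
        )
        expected = np.broadcast_to(truth.mean_surface, surfaces.shape)
        np.testing.assert_allclose(surfaces, expected, atol=1e-12)

    def test_counts_are_nonnegative_integers(self, small_lifespans, recovery_activity_truth):
        act = gen_activity(small_lifespans.head(10), recovery_activity_truth, seed=2)
        assert (act["count"] >= 0).all()
        np.testing.assert_array_equal(act["count"], np.round(act["count"]))

    def test_no_records_after_death(self, small_lifespans, recovery_activity_truth):
        act = gen_activity(small_lifespans, recovery_activity_truth, seed=2)
        merged = act.merge(small_lifespans, on="fly_id")
        assert (merged["day"] <= merged["age_at_death"]).all()

    def test_covariance_recovery(self, recovery_activity_truth):
        """Sample covariance of noise-free draws matches the generating model."""
        truth = recovery_activity_truth
        ls = gen_lifespans(CohortSpec(n_flies=200, min_age=33, seed=0))
        _, surfaces, _ = gen_activity_surfaces(ls, truth, seed=0, noise="none")
        flat = surfaces.reshape(200, -1)
        emp = np.cov(flat.T, bias=True)
        model = truth.covariance_surface()
        rel = np.linalg.norm(emp - model) / np.linalg.norm(model)
        assert rel < 0.15

    def test_grid_mismatch_raises(self, small_lifespans, recovery_activity_truth):
        from lifespanfda.fpca import ActivityPanel

        t = recovery_activity_truth
        _, surfaces, _ = gen_activity_surfaces(small_lifespans.head(4), t, seed=1)
        with pytest.raises(ValueError):
            ActivityPanel(np.arange(4), t.day_grid[:-1], t.hour_grid, surfaces)


class TestEggs:
    def test_zero_tau_zero_counts(self, small_lifespans):
        truth = EggGroundTruth.from_lifespans(
            small_lifespans, seed=1,
            link={"tau0": 0.0, "tau_slope": 0.0, "tau_sd": 0.0, "tau_min": 0.0},
        )
        eggs = gen_egg_counts(small_lifespans, truth, seed=2)
        assert (eggs["eggs"] == 0).all()

    def test_expected_total_equals_tau(self):
        """Mean total eggs over replicates matches the intensity factor."""
        ls = gen_lifespans(CohortSpec(n_flies=8, min_age=41.0, seed=3))
        truth = EggGroundTruth.from_lifespans(ls, seed=4)
        totals = np.zeros(8)
        reps = 400
        for r in range(reps):
            eggs = gen_egg_counts(ls, truth, seed=100 + r)
            totals += eggs.groupby("fly_id", sort=True)["eggs"].sum().to_numpy()
        mean_tot = totals / reps
        se = np.sqrt(truth.tau / reps)  # Poisson variance = tau
        assert np.all(np.abs(mean_tot - truth.tau) < 3 * se)

    def test_cost_of_reproduction_correlation(self, egg_cohort):
        """Longer-lived flies lay fewer eggs before day 15."""
        ls, _, eggs = egg_cohort
        early = eggs[eggs["day"] <= 15].groupby("fly_id")["eggs"].sum()
        merged = ls.set_index("fly_id").join(early.rename("early"))
        assert merged["age_at_death"].corr(merged["early"]) < 0

    def test_invalid_horizon(self, small_lifespans):
        truth = EggGroundTruth.from_lifespans(small_lifespans, seed=1)
        with pytest.raises(ValueError):
            gen_egg_counts(small_lifespans, truth, seed=2, n_days=0)


class TestBehavior:
    def test_multinomial_closure(self, small_lifespans, behavior_truth):
        beh = gen_behavior(small_lifespans.head(10), behavior_truth, seed=1)
        totals = beh[["n_fly", "n_walk", "n_rest"]].sum(axis=1)
        assert (totals == 12).all()

    def test_seed_reproducibility(self, small_lifespans, behavior_truth):
        a = gen_behavior(small_lifespans.head(5), behavior_truth, seed=9)
        b = gen_behavior(small_lifespans.head(5), behavior_truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_law_of_large_numbers(self):
        """Zero tangent variance: proportions converge to the mean curve."""
        truth = BehaviorGroundTruth.default(score_variances=(0.0, 0.0, 0.0))
        ls = gen_lifespans(CohortSpec(n_flies=3, min_age=42.0, seed=2))
        beh = gen_behavior(ls, truth, seed=3, n_daily_obs=10_000)
        props = beh[["n_fly", "n_walk", "n_rest"]].to_numpy() / 10_000
        expected = np.vstack([truth.mean_composition] * 3)
        assert np.max(np.abs(props - expected)) < 0.03

    def test_trajectories_on_sphere(self, small_lifespans, behavior_truth):
        _, traj, _ = gen_behavior_trajectories(small_lifespans.head(20), behavior_truth, seed=4)
        norms = np.linalg.norm(traj, axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        assert (traj >= 0).all()


class TestGroundTruthIO:
    @pytest.mark.parametrize("which", ["activity", "egg", "behavior"])
    def test_json_roundtrip_lossless(self, tmp_path, which, small_lifespans):
        if which == "activity":
            truth = ActivityGroundTruth.default()
        elif which == "egg":
            truth = EggGroundTruth.from_lifespans(small_lifespans, seed=1)
        else:
            truth = BehaviorGroundTruth.default()
        path = tmp_path / "truth.json"
        lio.truth_to_json(truth, path)
        back = lio.truth_from_json(path)
        import dataclasses

        for f in dataclasses.fields(truth):
            a, b = getattr(truth, f.name), getattr(back, f.name)
            if isinstance(a, np.ndarray) and a.dtype.kind == "f":
                np.testing.assert_allclose(a, b, atol=1e-12, rtol=0)
            elif isinstance(a, np.ndarray):
                np.testing.assert_array_equal(a, b)
            else:
                assert a == b

    def test_csv_schema_roundtrip(self, tmp_path, small_lifespans):
        path = tmp_path / "ls.csv"
        lio.write_lifespans(small_lifespans, path)
        back = lio.read_lifespans(path)
        pd.testing.assert_frame_equal(back, small_lifespans)

    def test_schema_validation(self, tmp_path):
        bad = pd.DataFrame({"fly_id": ["a"], "diet": ["C10"], "age_at_death": [-2.0]})
        with pytest.raises(ValueError):
            lio.write_lifespans(bad, tmp_path / "bad.csv")
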