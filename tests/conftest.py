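import numpy as np
import pandas as pd
import pytest

from lifespanfda.simulate import (
    ActivityGroundTruth,
    BehaviorGroundTruth,
    CohortSpec,
    EggGroundTruth,
    gen_egg_counts,
    gen_lifespans,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_lifespans():
    """96-fly diet cohort with default Gompertz mortality."""
    return gen_lifespans(CohortSpec(n_flies=96, seed=0))


@pytest.fixture(scope="session")
def egg_cohort():
    """Egg-laying cohort of survivors past day 36 with its ground truth and counts."""
    ls = gen_lifespans(CohortSpec(n_flies=473, min_age=36.0, seed=0))
    truth = EggGroundTruth.from_lifespans(ls, seed=1)
    eggs = gen_egg_counts(ls, truth, seed=2)
    return ls, truth, eggs


@pytest.fixture(scope="session")
def recovery_activity_truth():
    """Low-rank activity truth with the variances used in recovery checks."""
    return ActivityGroundTruth.default(score_variances=[[4.0, 2.0], [1.0, 0.5]])


@pytest.fixture(scope="session")
def behavior_truth():
    return BehaviorGroundTruth.default()


def make_point_mass_curves(values, prob_grid):
    """Embed scalars as point-mass quantile curves (constant rows)."""
    values = np.asarray(values, dtype=float)
    return np.tile(values[:, None], (1, len(prob_grid)))
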