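"""Global Fréchet regression with distributional responses in Wasserstein space.

For responses that are probability distributions on a bounded interval and
Euclidean predictors X, global Fréchet regression generalises linear
regression by replacing the conditional mean with the conditional Fréchet
mean under the 2-Wasserstein metric:

    m(x) = argmin_v E[ d_W^2(F, v) | X = x ].

The sample estimator weights each observed distribution F_i by

    s(X_i, x) = 1 + (X_i - Xbar)' Sigma^{-1} (x - Xbar),

with Xbar the predictor mean and Sigma the predictor covariance computed
with divisor n. Because d_W is the L2 distance between quantile functions,
the weighted Fréchet mean is the weighted average of the response quantile
functions, projected onto the cone of non-decreasing curves (weights may be
negative, which can break monotonicity); the isotonic projection under the
probability-grid quadrature metric is the exact constrained minimiser.

The remaining-lifetime pipeline applies this machinery with one empirical
remaining-lifetime distribution per (current age alive a, covariate) cohort
cell as the unit of observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from ._utils import trapezoid_weights
from .distributions import (
    DensityCurve,
    HazardCurve,
    QuantileCurve,
    default_prob_grid,
    density_to_hazard,
    empirical_quantile,
    quantile_to_density,
)

__all__ = [
    "DegenerateDesignError",
    "GlobalFrechetRegression",
    "GlobalFrechetResults",
    "CohortCell",
    "remaining_lifetime_cohorts",
    "activity_median_split",
    "diet_indicators",
    "RemainingLifetimeFrechet",
    "RemainingLifetimeResults",
]

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """Raised when the predictor design is rank deficient."""


class GlobalFrechetRegression:
    """Global Fréchet regression model for quantile-represented distributions.

    Parameters
    ----------
    X : array_like, shape (n, p) or (n,)
        Euclidean predictors.
    responses : sequence of QuantileCurve or array, shape (n, m)
        Response distributions; arrays are interpreted as quantile values on
        ``prob_grid``.
    prob_grid : array_like, optional
        Common probability grid (default: 201 equispaced levels in [0, 1]).
    t_max : float, optional
        Upper support bound; predictions are clipped to [0, t_max].
    """

    def __init__(self, X, responses, prob_grid=None, t_max: float | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if prob_grid is None:
            prob_grid = default_prob_grid()
        prob_grid = np.asarray(prob_grid, dtype=float)
        if isinstance(responses, np.ndarray) and responses.ndim == 2:
            Q = np.asarray(responses, dtype=float)
        else:
            curves = [
                r if isinstance(r, QuantileCurve) else QuantileCurve(prob_grid, r)
                for r in responses
            ]
            Q = np.stack([c.resample(prob_grid).quantiles for c in curves])
        if Q.shape[0] != X.shape[0]:
            raise ValueError("number of responses must match number of predictor rows")
        if Q.shape[1] != prob_grid.size:
            raise ValueError("response quantile grid does not match prob_grid")
        if X.shape[0] < X.shape[1] + 1:
            raise DegenerateDesignError("need at least p + 1 observations")
        self.X = X
        self.Q = Q
        self.prob_grid = prob_grid
        self.t_max = t_max

    def fit(self) -> "GlobalFrechetResults":
        n = self.X.shape[0]
        xbar = self.X.mean(axis=0)
        xc = self.X - xbar
        sigma = (xc.T @ xc) / n  # divisor n
        eig = np.linalg.eigvalsh(sigma)
        if eig[0] <= 1e-12 * max(eig[-1], 1.0):
            raise DegenerateDesignError(
                "predictor covariance is singular (rank-deficient design)"
            )
        return GlobalFrechetResults(self, xbar, sigma, np.linalg.inv(sigma))


@dataclass
class GlobalFrechetResults:
    """Fitted global Fréchet regression; prediction is closed form."""

    model: GlobalFrechetRegression
    xbar: np.ndarray
    sigma: np.ndarray
    sigma_inv: np.ndarray

    def weights(self, x) -> np.ndarray:
        """Regression weights s(X_i, x); they average to one and may be negative."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xc = self.model.X - self.xbar
        return 1.0 + xc @ self.sigma_inv @ (x - self.xbar)

    def predict(self, x) -> QuantileCurve:
        """Conditional Wasserstein Fréchet mean at predictor value x.

        The weighted quantile average is projected onto non-decreasing
        curves by weighted isotonic regression (pool-adjacent-violators)
        under the trapezoid quadrature weights of the probability grid —
        the exact minimiser of the weighted criterion over valid quantile
        functions — then clipped to the support.
        """
        s = self.weights(x)
        g = (s @ self.model.Q) / s.sum()
        w = trapezoid_weights(self.model.prob_grid)
        q = isotonic_regression(g, weights=w, increasing=True).x
        if self.model.t_max is not None:
            q = np.clip(q, 0.0, self.model.t_max)
        return QuantileCurve(self.model.prob_grid, q)

    def fitted(self) -> list[QuantileCurve]:
        return [self.predict(x) for x in self.model.X]

    def summary(self) -> str:
        n, p = self.model.X.shape
        lines = [
            "Global Fréchet Regression (Wasserstein responses)",
            "=" * 50,
            f"n observations: {n}",
            f"n predictors:   {p}",
            f"prob grid size: {self.model.prob_grid.size}",
            f"predictor mean: {np.array2string(self.xbar, precision=4)}",
            "predictor covariance (divisor n):",
            np.array2string(self.sigma, precision=4),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# remaining-lifetime pipeline


@dataclass(frozen=True)
class CohortCell:
    """Remaining lifetimes of flies alive at age a sharing covariate values."""

    age: float
    covariates: tuple = ()
    remaining: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        rem = np.asarray(self.remaining, dtype=float)
        if np.any(rem <= 0):
            raise ValueError("remaining lifetimes must be positive")
        object.__setattr__(self, "remaining", rem)

    @property
    def size(self) -> int:
        return self.remaining.size

    @property
    def predictor(self) -> np.ndarray:
        return np.concatenate(([self.age], np.asarray(self.covariates, dtype=float)))


def diet_indicators(lifespans: pd.DataFrame, baseline: str = "C10") -> pd.DataFrame:
    """Per-fly 0/1 indicator columns for every diet except the baseline."""
    diets = [d for d in sorted(lifespans["diet"].unique()) if d != baseline]
    out = pd.DataFrame(index=lifespans["fly_id"])
    for d in diets:
        out[d] = (lifespans.set_index("fly_id")["diet"] == d).astype(float)
    return out


def remaining_lifetime_cohorts(
    lifespans: pd.DataFrame,
    ages,
    covariates: pd.DataFrame | None = None,
    min_cell_size: int = 5,
) -> list[CohortCell]:
    """Build (age alive, covariate combination) cells of remaining lifetimes.

    ``covariates`` is a per-fly frame of numeric (indicator) columns indexed
    by fly_id; cells smaller than ``min_cell_size`` are dropped with a
    warning.
    """
    ls = lifespans.set_index("fly_id")["age_at_death"]
    cells = []
    for a in ages:
        alive = ls[ls > a]
        if covariates is None:
            groups = [((), alive.index)]
        else:
            cov = covariates.loc[covariates.index.intersection(alive.index)]
            groups = [
                (tuple(key if isinstance(key, tuple) else (key,)), sub.index)
                for key, sub in cov.groupby(list(cov.columns), sort=True)
            ]
        for key, ids in groups:
            rem = (ls.loc[ids][ls.loc[ids] > a] - a).to_numpy()
            if rem.size < min_cell_size:
                logger.warning(
                    "dropping cell (a=%s, cov=%s): only %d flies", a, key, rem.size
                )
                continue
            cells.append(CohortCell(float(a), key, rem))
    return cells


def activity_median_split(
    activity: pd.DataFrame, lifespans: pd.DataFrame, a: float
) -> pd.Series:
    """High/low activity indicator among flies alive past age a.

    The per-fly total activity count over days [0, a] is compared with the
    within-cohort median; the indicator is 1 only for totals strictly above
    the median (ties count as low), so the split is deterministic.
    """
    ls = lifespans.set_index("fly_id")["age_at_death"]
    alive = ls[ls > a].index
    sub = activity[(activity["day"] <= a) & activity["fly_id"].isin(alive)]
    totals = sub.groupby("fly_id")["count"].sum()
    skipped = set(alive) - set(totals.index)
    for fid in sorted(skipped):
        logger.warning("fly %s has no activity data before a=%s; excluded", fid, a)
    med = totals.median()
    return (totals > med).astype(float).rename("high_activity")


class RemainingLifetimeFrechet:
    """Remaining-lifetime distribution as a function of current age alive.

    Fits one joint global Fréchet regression over all (a, covariate) cohort
    cells, with predictors (a, covariate indicators) and the empirical
    remaining-lifetime distribution of each cell as the response.
    """

    def __init__(
        self,
        lifespans: pd.DataFrame,
        ages=None,
        covariates: pd.DataFrame | None = None,
        prob_grid=None,
        t_max: float = 90.0,
        min_cell_size: int = 5,
    ):
        self.lifespans = lifespans
        self.ages = list(ages) if ages is not None else list(range(1, 31))
        self.covariates = covariates
        self.prob_grid = (
            np.asarray(prob_grid, dtype=float) if prob_grid is not None else default_prob_grid()
        )
        self.t_max = t_max
        self.min_cell_size = min_cell_size

    def fit(self) -> "RemainingLifetimeResults":
        cells = remaining_lifetime_cohorts(
            self.lifespans, self.ages, self.covariates, self.min_cell_size
        )
        if not cells:
            raise ValueError("no cohort cells of sufficient size")
        X = np.stack([c.predictor for c in cells])
        Q = np.stack(
            [empirical_quantile(c.remaining, self.prob_grid).quantiles for c in cells]
        )
        res = GlobalFrechetRegression(X, Q, self.prob_grid, t_max=self.t_max).fit()
        return RemainingLifetimeResults(self, cells, res)


@dataclass
class RemainingLifetimeResults:
    model: RemainingLifetimeFrechet
    cells: list
    frechet: GlobalFrechetResults

    def predict_quantile(self, a: float, covariates=()) -> QuantileCurve:
        x = np.concatenate(([a], np.asarray(covariates, dtype=float)))
        return self.frechet.predict(x)

    def predict_curves(
        self, a: float, covariates=(), age_grid=None, upper_trim: float = 0.95
    ):
        """Quantile, density and hazard of the remaining-lifetime distribution."""
        if age_grid is None:
            age_grid = np.linspace(0.0, self.model.t_max, 181)
        q = self.predict_quantile(a, covariates)
        d = quantile_to_density(q, age_grid)
        h = density_to_hazard(d, upper_trim=upper_trim)
        return q, d, h

    def summary(self) -> str:
        sizes = [c.size for c in self.cells]
        lines = [
            "Remaining-lifetime global Fréchet regression",
            "=" * 50,
            f"cohort cells: {len(self.cells)} "
            f"(sizes {min(sizes)}-{max(sizes)}, median {int(np.median(sizes))})",
            f"ages alive:   {self.model.ages[0]}..{self.model.ages[-1]}",
            f"covariates:   "
            + (", ".join(self.model.covariates.columns) if self.model.covariates is not None else "none"),
            "",
            self.frechet.summary(),
        ]
        return "\n".join(lines)

    def plot_densities(self, covariates=(), ages=None, ax=None):
        """Predicted remaining-lifetime densities across current ages alive."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ages = ages if ages is not None else self.model.ages
        cmap = plt.get_cmap("coolwarm")
        for i, a in enumerate(ages):
            _, d, _ = self.predict_curves(a, covariates)
            ax.plot(d.age_grid, d.density, color=cmap(i / max(len(ages) - 1, 1)), lw=1)
        ax.set_xlabel("remaining lifetime (days)")
        ax.set_ylabel("density")
        return ax
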