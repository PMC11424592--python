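"""Distributions on a bounded age range, represented by quantile functions.

The 2-Wasserstein geometry on distributions with support in [0, T_max] is
linear in quantile space: the distance between two distributions is the
L2([0,1]) distance between their quantile functions, and weighted Fréchet
means are (monotonicity-projected) weighted averages of quantile functions.
Every distributional object in this package is therefore carried as a
:class:`QuantileCurve` on a common probability grid, with conversions to
density and hazard representations for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import (
    as_increasing_grid,
    local_linear_smooth,
    reflected_kde,
    silverman_bandwidth,
    trapezoid_weights,
)

__all__ = [
    "QuantileCurve",
    "DensityCurve",
    "HazardCurve",
    "default_prob_grid",
    "empirical_quantile",
    "wasserstein_distance",
    "quantile_to_density",
    "density_to_quantile",
    "density_to_hazard",
    "lifetable_hazard",
    "raw_lifetable_hazard",
    "InsufficientDataError",
]


def default_prob_grid(n: int = 201) -> np.ndarray:
    """Equispaced probability levels in [0, 1] (default 201 points)."""
    return np.linspace(0.0, 1.0, n)


class InsufficientDataError(ValueError):
    """Raised when an estimator receives too few observations."""


@dataclass(frozen=True)
class QuantileCurve:
    """A distribution represented by its quantile function on a probability grid."""

    prob_grid: np.ndarray
    quantiles: np.ndarray

    def __post_init__(self):
        pg = as_increasing_grid(self.prob_grid, "prob_grid")
        q = np.asarray(self.quantiles, dtype=float)
        if pg[0] < 0 or pg[-1] > 1:
            raise ValueError("prob_grid must lie in [0, 1]")
        if q.shape != pg.shape:
            raise ValueError("quantiles and prob_grid must have equal length")
        if not np.all(np.isfinite(q)):
            raise ValueError("quantiles must be finite")
        if np.any(np.diff(q) < -1e-8 * max(1.0, float(np.ptp(q)))):
            raise ValueError("quantiles must be non-decreasing along prob_grid")
        object.__setattr__(self, "prob_grid", pg)
        object.__setattr__(self, "quantiles", np.maximum.accumulate(q))

    def resample(self, prob_grid: np.ndarray) -> "QuantileCurve":
        """Linear interpolation onto a new probability grid."""
        prob_grid = np.asarray(prob_grid, dtype=float)
        q = np.interp(prob_grid, self.prob_grid, self.quantiles)
        return QuantileCurve(prob_grid, q)

    def mean(self) -> float:
        """Mean of the distribution: integral of the quantile function over [0,1]."""
        return float(np.trapezoid(self.quantiles, self.prob_grid))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """Left-continuous inverse of the quantile curve, evaluated at x."""
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.quantiles, self.prob_grid, left=0.0, right=1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.prob_grid, "value": self.quantiles})

    def save(self, path: str | Path, **metadata) -> None:
        _save_curve(path, self.to_frame(), kind="quantile", **metadata)


@dataclass(frozen=True)
class DensityCurve:
    """A probability density on an age grid (days); integrates to one."""

    age_grid: np.ndarray
    density: np.ndarray
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self):
        g = as_increasing_grid(self.age_grid, "age_grid")
        d = np.asarray(self.density, dtype=float)
        if d.shape != g.shape:
            raise ValueError("density and age_grid must have equal length")
        if np.any(d < -1e-10):
            raise ValueError("density must be nonnegative")
        d = np.clip(d, 0.0, None)
        area = np.trapezoid(d, g)
        if not np.isfinite(area) or abs(area - 1.0) > 1e-3:
            raise ValueError(f"density must integrate to 1 (got {area:.6f})")
        object.__setattr__(self, "age_grid", g)
        object.__setattr__(self, "density", d)

    def cdf(self) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid

        F = cumulative_trapezoid(self.density, self.age_grid, initial=0.0)
        return np.clip(F, 0.0, 1.0)

    def mean(self) -> float:
        return float(np.trapezoid(self.age_grid * self.density, self.age_grid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.age_grid, "value": self.density})

    def save(self, path: str | Path, **metadata) -> None:
        _save_curve(path, self.to_frame(), kind="density", **metadata)


@dataclass(frozen=True)
class HazardCurve:
    """Hazard (force of mortality) on an age grid; right tail masked as NaN."""

    age_grid: np.ndarray
    hazard: np.ndarray
    upper_trim: float = 0.95

    def __post_init__(self):
        g = as_increasing_grid(self.age_grid, "age_grid")
        h = np.asarray(self.hazard, dtype=float)
        if h.shape != g.shape:
            raise ValueError("hazard and age_grid must have equal length")
        if np.any(h[np.isfinite(h)] < -1e-10):
            raise ValueError("hazard must be nonnegative where defined")
        object.__setattr__(self, "age_grid", g)
        object.__setattr__(self, "hazard", np.where(np.isfinite(h), np.clip(h, 0.0, None), h))

    def log_hazard(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.hazard)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.age_grid, "value": self.hazard})

    def save(self, path: str | Path, **metadata) -> None:
        _save_curve(path, self.to_frame(), kind="hazard", upper_trim=self.upper_trim, **metadata)


def _save_curve(path, frame: pd.DataFrame, **metadata) -> None:
    path = Path(path)
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(metadata, indent=2, default=float))


def empirical_quantile(sample, prob_grid=None) -> QuantileCurve:
    """Type-1 (left-continuous inverse CDF) empirical quantile curve.

    Exact for point masses: for a sample of size n the quantile at level u is
    the ceil(u*n)-th order statistic, with the minimum at u = 0.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise InsufficientDataError("empirical_quantile requires a nonempty sample")
    if np.any(sample < 0):
        raise ValueError("durations must be nonnegative")
    if prob_grid is None:
        prob_grid = default_prob_grid()
    prob_grid = np.asarray(prob_grid, dtype=float)
    q = np.quantile(sample, prob_grid, method="inverted_cdf")
    return QuantileCurve(prob_grid, q)


def wasserstein_distance(q1: QuantileCurve, q2: QuantileCurve) -> float:
    """2-Wasserstein distance: L2 distance between quantile functions on [0,1]."""
    if q1.prob_grid.shape != q2.prob_grid.shape or not np.allclose(
        q1.prob_grid, q2.prob_grid
    ):
        q2 = q2.resample(q1.prob_grid)
    diff2 = (q1.quantiles - q2.quantiles) ** 2
    return float(np.sqrt(np.trapezoid(diff2, q1.prob_grid)))


def quantile_to_density(
    q: QuantileCurve,
    age_grid,
    bandwidth: float | None = None,
) -> DensityCurve:
    """Density of the distribution behind a quantile curve.

    The quantile curve evaluated at the probability grid is an importance
    sample of the distribution (point q(u_i) with trapezoid weight du_i); a
    Gaussian kernel estimate with reflection at both ends of ``age_grid``
    smooths it into a density, renormalised to integrate to one. Bandwidth
    defaults to the Silverman rule on the implied weighted sample. A
    degenerate input (all mass at one point) yields a narrow peak with the
    ``degenerate`` flag set.
    """
    age_grid = as_increasing_grid(age_grid, "age_grid")
    pts = q.quantiles
    w = trapezoid_weights(q.prob_grid)
    spread = float(np.ptp(pts))
    degenerate = spread < 1e-10 * max(1.0, float(age_grid[-1]))
    if bandwidth is None:
        if degenerate:
            bandwidth = 1e-3 * (age_grid[-1] - age_grid[0])
        else:
            bandwidth = silverman_bandwidth(pts, w)
    dens = reflected_kde(pts, age_grid, bandwidth=bandwidth,
                         support=(float(age_grid[0]), float(age_grid[-1])), weights=w)
    return DensityCurve(age_grid, dens, degenerate=degenerate)


def density_to_quantile(d: DensityCurve, prob_grid=None) -> QuantileCurve:
    """Invert the CDF implied by a density onto a probability grid."""
    if prob_grid is None:
        prob_grid = default_prob_grid()
    prob_grid = np.asarray(prob_grid, dtype=float)
    F = d.cdf()
    F[-1] = 1.0
    # make strictly increasing for a well-defined interpolation inverse
    F_mono = np.maximum.accumulate(F + np.arange(F.size) * 1e-14)
    q = np.interp(prob_grid * F_mono[-1], F_mono, d.age_grid)
    return QuantileCurve(prob_grid, q)


def density_to_hazard(d: DensityCurve, upper_trim: float = 0.95) -> HazardCurve:
    """Hazard λ(u) = f(u) / (1 - F(u)), masked beyond the upper_trim quantile.

    Beyond the trim level the survival denominator is dominated by estimation
    error in the density tail, so values there are reported as NaN rather
    than pretending to tail accuracy.
    """
    if not (0 < upper_trim <= 1):
        raise ValueError("upper_trim must be in (0, 1]")
    F = d.cdf()
    with np.errstate(divide="ignore", invalid="ignore"):
        h = d.density / (1.0 - F)
    h = np.where(F < upper_trim, h, np.nan)
    return HazardCurve(d.age_grid, h, upper_trim=upper_trim)


def raw_lifetable_hazard(ages_at_death, max_age: float):
    """Unsmoothed lifetable hazard per day.

    Returns (day midpoints, raw hazard, number alive entering each day). Day t
    covers the age interval [t, t+1); its raw hazard is deaths during the
    interval divided by the number alive entering it.
    """
    ages = np.asarray(ages_at_death, dtype=float)
    ages = ages[np.isfinite(ages)]
    if ages.size == 0:
        raise InsufficientDataError("lifetable hazard requires at least one death")
    days = np.arange(0, int(np.ceil(max_age)))
    deaths = np.histogram(ages, bins=np.append(days, max_age))[0]
    alive = ages.size - np.concatenate(([0], np.cumsum(deaths)[:-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(alive > 0, deaths / alive, np.nan)
    return days + 0.5, raw, alive


def lifetable_hazard(
    ages_at_death,
    max_age: float,
    bandwidth: float = 3.0,
    min_alive: int = 5,
) -> HazardCurve:
    """Discrete lifetable hazard, local-linear smoothed.

    The raw hazard on day t is (deaths during day t) / (number alive entering
    day t); days where fewer than ``min_alive`` individuals remain at risk are
    masked before smoothing, mirroring the instability of lifetable tails.
    """
    mid, raw, alive = raw_lifetable_hazard(ages_at_death, max_age)
    raw = np.where(alive >= min_alive, raw, np.nan)
    ok = np.isfinite(raw)
    if ok.sum() < 2:
        return HazardCurve(mid, raw, upper_trim=1.0)
    sm = np.full_like(raw, np.nan, dtype=float)
    sm[ok] = np.clip(local_linear_smooth(mid[ok], raw[ok], mid[ok], bandwidth), 0.0, None)
    return HazardCurve(mid, sm, upper_trim=1.0)
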