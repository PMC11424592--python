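"""Concurrent regression of reproductive-rate change on current egg-laying.

With X(t) the egg count laid on day t, the difference quotient
Y(t) = X(t+1) - X(t) approximates the derivative of the reproductive
trajectory. The varying-coefficient (concurrent) model

    E[Y(t) | X(t)] = beta0(t) + beta1(t) * (X(t) - mu_X(t)),   t in [10, 35],

is fitted by ordinary least squares separately at each day t (the daily
design is dense, so no kernel weighting across t is needed), followed by an
optional local-linear smoothing of the coefficient curves. beta0(t) tracks
the mean derivative of egg-laying; a negative beta1(t) means above-average
layers decline faster than below-average layers — dynamic regression to the
mean. Pointwise confidence bands come from a percentile bootstrap that
resamples flies with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import local_linear_smooth, spawn_rngs

__all__ = [
    "difference_quotients",
    "estimate_mean_curve",
    "ConcurrentRegression",
    "ConcurrentResults",
    "BootstrapBands",
]

logger = logging.getLogger(__name__)


def _wide_counts(eggs: pd.DataFrame, days: np.ndarray) -> pd.DataFrame:
    wide = eggs.pivot_table(index="fly_id", columns="day", values="eggs", aggfunc="sum")
    wide = wide.reindex(columns=days)
    return wide


def difference_quotients(eggs: pd.DataFrame, t_start: int = 10, t_end: int = 35):
    """Per-fly difference quotients Y(t) = X(t+1) - X(t) on the day grid.

    Returns (day_grid, X, Y, fly_ids) with X and Y of shape (n, n_days);
    gaps in a fly's daily record yield NaN at the affected days (logged).
    """
    days = np.arange(t_start, t_end + 2)
    wide = _wide_counts(eggs, days)
    arr = wide.to_numpy(dtype=float)
    n_gaps = int(np.isnan(arr).sum())
    if n_gaps:
        logger.warning("egg table has %d missing fly-days in [%d, %d]", n_gaps, t_start, t_end + 1)
    X = arr[:, :-1]
    Y = arr[:, 1:] - arr[:, :-1]
    return days[:-1].astype(float), X, Y, wide.index.to_numpy()


def estimate_mean_curve(
    eggs: pd.DataFrame, bandwidth: float = 2.5, day_range=None
):
    """Local-linear smoothed cross-sectional mean daily egg count.

    Returns (day_grid, smoothed mean). Bandwidth is in days; the default
    2.5 is a rule-of-thumb for daily data with the observed day-to-day
    noise (logged, configurable).
    """
    if eggs["fly_id"].nunique() < 2:
        raise ValueError("mean curve requires at least 2 flies")
    raw = eggs.groupby("day")["eggs"].mean()
    days = raw.index.to_numpy(dtype=float)
    if day_range is not None:
        keep = (days >= day_range[0]) & (days <= day_range[1])
        days, raw = days[keep], raw.iloc[keep]
    logger.info("mean egg curve smoothed with local-linear bandwidth %.2f days", bandwidth)
    mu = local_linear_smooth(days, raw.to_numpy(dtype=float), days, bandwidth)
    return days, mu


def _pointwise_ols(X: np.ndarray, Y: np.ndarray, min_flies: int):
    """Per-day OLS of Y on centred X. NaN-aware; returns (beta0, beta1).

    Days with fewer than ``min_flies`` complete pairs or zero cross-sectional
    variance are masked (NaN).
    """
    ok = np.isfinite(X) & np.isfinite(Y)
    Xm = np.where(ok, X, 0.0)
    Ym = np.where(ok, Y, 0.0)
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = Xm.sum(axis=0) / n
        ybar = Ym.sum(axis=0) / n
        xc = np.where(ok, X - xbar, 0.0)
        yc = np.where(ok, Y - ybar, 0.0)
        sxx = (xc**2).sum(axis=0)
        sxy = (xc * yc).sum(axis=0)
        beta1 = sxy / sxx
        beta0 = ybar
    bad = (n < min_flies) | ~np.isfinite(beta1) | (sxx <= 0)
    beta0 = np.where(n >= min_flies, beta0, np.nan)
    beta1 = np.where(bad, np.nan, beta1)
    return beta0, beta1


class ConcurrentRegression:
    """Concurrent regression model built from a daily egg-count table.

    Parameters
    ----------
    eggs : DataFrame with columns (fly_id, day, eggs)
        Daily counts; flies must cover days [t_start, t_end + 1] — the
        cohort is implicitly restricted to flies surviving past t_end + 1,
        so no censoring handling is needed.
    t_start, t_end : int
        Day range of the model (default [10, 35]).
    smooth_bandwidth : float or None
        Local-linear bandwidth (days) applied to the fitted coefficient
        curves; None skips smoothing. Raw curves are always retained.
    min_flies : int
        Minimum complete pairs required per day.
    """

    def __init__(
        self,
        eggs: pd.DataFrame,
        t_start: int = 10,
        t_end: int = 35,
        smooth_bandwidth: float | None = 2.0,
        min_flies: int = 10,
    ):
        self.t_start, self.t_end = t_start, t_end
        self.smooth_bandwidth = smooth_bandwidth
        self.min_flies = min_flies
        self.day_grid, self.X, self.Y, self.fly_ids = difference_quotients(
            eggs, t_start, t_end
        )
        self.eggs = eggs

    @classmethod
    def from_matrix(
        cls,
        counts: np.ndarray,
        t_start: int = 10,
        t_end: int = 35,
        smooth_bandwidth: float | None = 2.0,
        min_flies: int = 10,
    ) -> "ConcurrentRegression":
        """Build the model from a dense count matrix.

        ``counts`` has shape (n_flies, t_end - t_start + 2): columns are the
        daily counts X(t) for t = t_start .. t_end + 1.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.shape[1] != t_end - t_start + 2:
            raise ValueError("counts must cover days t_start .. t_end + 1")
        obj = cls.__new__(cls)
        obj.t_start, obj.t_end = t_start, t_end
        obj.smooth_bandwidth = smooth_bandwidth
        obj.min_flies = min_flies
        obj.day_grid = np.arange(t_start, t_end + 1, dtype=float)
        obj.X = counts[:, :-1]
        obj.Y = counts[:, 1:] - counts[:, :-1]
        obj.fly_ids = np.arange(counts.shape[0])
        obj.eggs = None
        return obj

    def _fit_arrays(self, X, Y):
        b0_raw, b1_raw = _pointwise_ols(X, Y, self.min_flies)
        if self.smooth_bandwidth is None:
            return b0_raw, b1_raw, b0_raw, b1_raw
        b0 = np.full_like(b0_raw, np.nan)
        b1 = np.full_like(b1_raw, np.nan)
        for raw, out in ((b0_raw, b0), (b1_raw, b1)):
            ok = np.isfinite(raw)
            if ok.sum() >= 2:
                out[ok] = local_linear_smooth(
                    self.day_grid[ok], raw[ok], self.day_grid[ok], self.smooth_bandwidth
                )
            else:
                out[:] = raw
        return b0, b1, b0_raw, b1_raw

    def fit(self) -> "ConcurrentResults":
        b0, b1, b0_raw, b1_raw = self._fit_arrays(self.X, self.Y)
        ok = np.isfinite(self.X)
        with np.errstate(invalid="ignore"):
            mu_raw = np.where(ok, self.X, 0.0).sum(axis=0) / ok.sum(axis=0)
        if self.smooth_bandwidth is not None:
            mu = local_linear_smooth(self.day_grid, mu_raw, self.day_grid, 2.5)
        else:
            mu = mu_raw
        return ConcurrentResults(self, b0, b1, b0_raw, b1_raw, mu)


@dataclass
class BootstrapBands:
    """Pointwise percentile bootstrap bands for the coefficient curves."""

    level: float
    n_replicates: int
    beta0_lower: np.ndarray
    beta0_upper: np.ndarray
    beta1_lower: np.ndarray
    beta1_upper: np.ndarray

    def beta1_significant(self) -> np.ndarray:
        """Days where zero lies outside the beta1 band (pointwise)."""
        return (self.beta1_lower > 0) | (self.beta1_upper < 0)


@dataclass
class ConcurrentResults:
    model: ConcurrentRegression
    beta0: np.ndarray
    beta1: np.ndarray
    beta0_raw: np.ndarray
    beta1_raw: np.ndarray
    mean_curve: np.ndarray

    @property
    def day_grid(self) -> np.ndarray:
        return self.model.day_grid

    def bootstrap_bands(
        self, n_replicates: int = 1000, level: float = 0.95, seed: int = 0,
        max_failure_rate: float = 0.1,
    ) -> BootstrapBands:
        """Resample flies with replacement and form percentile envelopes.

        A resample "fails" if every day is masked; more than
        ``max_failure_rate`` failures aborts. Bands are widened, if needed,
        to contain the point estimates.
        """
        rng = spawn_rngs(seed, 1)[0]
        n = self.model.X.shape[0]
        b0s = np.empty((n_replicates, self.day_grid.size))
        b1s = np.empty_like(b0s)
        failures = 0
        for b in range(n_replicates):
            idx = rng.integers(0, n, size=n)
            b0, b1, _, _ = self.model._fit_arrays(self.model.X[idx], self.model.Y[idx])
            if not np.isfinite(b1).any():
                failures += 1
            b0s[b], b1s[b] = b0, b1
        if failures > max_failure_rate * n_replicates:
            raise RuntimeError(f"{failures}/{n_replicates} bootstrap refits failed")
        alpha = (1.0 - level) / 2.0
        qs = [100 * alpha, 100 * (1 - alpha)]
        lo0, hi0 = np.nanpercentile(b0s, qs, axis=0)
        lo1, hi1 = np.nanpercentile(b1s, qs, axis=0)
        # percentile envelopes around an estimate computed the same way must
        # contain it; enforce in degenerate corners
        lo0, hi0 = np.fmin(lo0, self.beta0), np.fmax(hi0, self.beta0)
        lo1, hi1 = np.fmin(lo1, self.beta1), np.fmax(hi1, self.beta1)
        return BootstrapBands(level, n_replicates, lo0, hi0, lo1, hi1)

    def summary(self) -> str:
        ok = np.isfinite(self.beta1)
        lines = [
            "Concurrent regression of egg-laying rate change",
            "=" * 50,
            f"flies: {self.model.X.shape[0]}   days: [{self.model.t_start}, {self.model.t_end}]",
            f"coefficient smoothing bandwidth: {self.model.smooth_bandwidth}",
            f"beta0 range: [{np.nanmin(self.beta0):.3f}, {np.nanmax(self.beta0):.3f}] eggs/day",
            f"beta1 range: [{np.nanmin(self.beta1):.4f}, {np.nanmax(self.beta1):.4f}] per egg",
            f"beta1 negative on {int((self.beta1[ok] < 0).sum())}/{int(ok.sum())} days",
        ]
        return "\n".join(lines)

    def plot(self, bands: BootstrapBands | None = None, axes=None):
        """Coefficient curves with optional bootstrap bands."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.2))
        for ax, est, lo, hi, name in (
            (axes[0], self.beta0,
             bands.beta0_lower if bands else None,
             bands.beta0_upper if bands else None, r"$\beta_0(t)$"),
            (axes[1], self.beta1,
             bands.beta1_lower if bands else None,
             bands.beta1_upper if bands else None, r"$\beta_1(t)$"),
        ):
            ax.plot(self.day_grid, est, color="k")
            if lo is not None:
                ax.fill_between(self.day_grid, lo, hi, alpha=0.3)
            ax.axhline(0.0, color="gray", lw=0.5)
            ax.set_xlabel("age (days)")
            ax.set_title(name)
        return axes
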