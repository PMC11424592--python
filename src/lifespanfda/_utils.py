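"""Shared numerical helpers: quadrature, smoothing, kernel density, seeding."""

from __future__ import annotations

import numpy as np
from numpy.random import Generator, SeedSequence
from scipy.stats import norm

__all__ = [
    "trapezoid_weights",
    "local_linear_smooth",
    "reflected_kde",
    "silverman_bandwidth",
    "spawn_rngs",
    "as_increasing_grid",
]


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights w such that w @ f == trapezoid integral of f on grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be 1-D with at least two points")
    w = np.empty_like(grid)
    d = np.diff(grid)
    w[0] = d[0] / 2.0
    w[-1] = d[-1] / 2.0
    w[1:-1] = (d[:-1] + d[1:]) / 2.0
    return w


def as_increasing_grid(grid, name: str = "grid") -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError(f"{name} must be 1-D with at least two points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    if not np.all(np.isfinite(grid)):
        raise ValueError(f"{name} must be finite")
    return grid


def local_linear_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_out: np.ndarray,
    bandwidth: float,
    kernel: str = "epanechnikov",
) -> np.ndarray:
    """Local-linear kernel smoother.

    Reproduces polynomials of degree <= 1 exactly and has the usual
    O(h^2) interior bias on curved targets; near the boundary the local
    line still adapts, so no separate boundary correction is needed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_out = np.atleast_1d(np.asarray(x_out, dtype=float))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need at least two finite observations to smooth")

    u = (x_out[:, None] - x[None, :]) / bandwidth
    if kernel == "epanechnikov":
        k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    elif kernel == "gaussian":
        k = np.exp(-0.5 * u**2)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    # weighted least squares moments; fall back to local constant where the
    # design within the window is degenerate
    s0 = k.sum(axis=1)
    s1 = (k * u).sum(axis=1)
    s2 = (k * u**2).sum(axis=1)
    t0 = (k * y).sum(axis=1)
    t1 = (k * u * y).sum(axis=1)
    denom = s0 * s2 - s1**2
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (s2 * t0 - s1 * t1) / denom
        fallback = t0 / s0
    bad = ~np.isfinite(est)
    est[bad] = fallback[bad]
    empty = s0 <= 0
    if np.any(empty):
        # widen: nearest-neighbour value for windows containing no data
        idx = np.abs(x_out[empty, None] - x[None, :]).argmin(axis=1)
        est[empty] = y[idx]
    return est


def silverman_bandwidth(sample: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Silverman rule-of-thumb bandwidth for a Gaussian kernel."""
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    if weights is None:
        sd = float(np.std(sample))
        q75, q25 = np.percentile(sample, [75, 25])
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
        mu = float(weights @ sample)
        sd = float(np.sqrt(weights @ (sample - mu) ** 2))
        order = np.argsort(sample)
        cw = np.cumsum(weights[order])
        q25 = float(np.interp(0.25, cw, sample[order]))
        q75 = float(np.interp(0.75, cw, sample[order]))
    iqr = q75 - q25
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(float(np.mean(sample))), 1.0) * 1e-3
    return 0.9 * scale * n ** (-0.2)


def reflected_kde(
    sample: np.ndarray,
    grid: np.ndarray,
    bandwidth: float | None = None,
    support: tuple[float, float] | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian kernel density with reflection at both support boundaries.

    Reflection removes the O(1) boundary bias of a plain kernel estimate for
    densities that do not vanish at the edge of their support (day 0 for
    egg-laying, age 0 for remaining lifetime). The result is renormalised to
    integrate to one on ``grid`` by the trapezoid rule.
    """
    sample = np.asarray(sample, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    if weights is None:
        weights = np.full(sample.size, 1.0 / sample.size)
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    if support is None:
        support = (float(grid[0]), float(grid[-1]))
    lo, hi = support
    if bandwidth is None:
        bandwidth = silverman_bandwidth(sample, weights)
    if bandwidth <= 0:
        bandwidth = 1e-6 * max(hi - lo, 1.0)

    points = [sample, 2 * lo - sample, 2 * hi - sample]
    dens = np.zeros_like(grid)
    for pts in points:
        z = (grid[:, None] - pts[None, :]) / bandwidth
        dens += (norm.pdf(z) @ weights) / bandwidth
    dens = np.where((grid < lo) | (grid > hi), 0.0, dens)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate density estimate")
    return dens / area


def spawn_rngs(seed: int, n: int) -> list[Generator]:
    """Deterministic stream splitting: one master seed, independent children.

    Children are spawned in a fixed order from ``SeedSequence(seed)``, so any
    stage can be regenerated in isolation from (seed, stage index).
    """
    children = SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]
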