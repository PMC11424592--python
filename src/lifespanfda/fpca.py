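"""Product functional principal component analysis for day x hour surfaces.

Hourly activity over the lifespan is a function-valued stochastic process
X(s, t): at each age t (days) one observes an intra-day activity curve in
hour s. Product FPCA represents the centred process through products of
marginal eigenfunctions,

    X(s, t) - mu(s, t) = sum_j sum_k chi_jk phi_k(t) psi_j(s),

where psi_j are eigenfunctions of the hour-marginal covariance kernel
G_S(s, u) = integral_T G((s,t),(u,t)) dt, phi_k are eigenfunctions of the
day-marginal kernel G_T(t, u) = integral_S G((s,t),(s,u)) ds, and the scores
chi_jk = integral integral (X - mu) psi_j phi_k are zero-mean uncorrelated
random variables. Unlike a full 2-D eigendecomposition this keeps the two
time scales (circadian hour, age in days) separately interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import local_linear_smooth, trapezoid_weights
from .distributions import InsufficientDataError

__all__ = [
    "ActivityPanel",
    "ProductFPCA",
    "ProductFPCAResults",
    "estimate_mean_surface",
    "marginal_kernels",
]


@dataclass(frozen=True)
class ActivityPanel:
    """Complete day x hour count surfaces on shared grids.

    ``surfaces`` has shape (n_flies, n_days, n_hours) with no missing cells:
    the cohort is restricted to flies observed over the full day range.
    """

    fly_ids: np.ndarray
    day_grid: np.ndarray
    hour_grid: np.ndarray
    surfaces: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.surfaces, dtype=float)
        if s.ndim != 3 or s.shape[1:] != (len(self.day_grid), len(self.hour_grid)):
            raise ValueError("surfaces must have shape (n, n_days, n_hours)")
        if not np.all(np.isfinite(s)):
            raise ValueError("surfaces contain missing cells")
        if np.any(s < 0):
            raise ValueError("activity counts must be nonnegative")
        object.__setattr__(self, "surfaces", s)
        object.__setattr__(self, "fly_ids", np.asarray(self.fly_ids))
        object.__setattr__(self, "day_grid", np.asarray(self.day_grid, dtype=float))
        object.__setattr__(self, "hour_grid", np.asarray(self.hour_grid, dtype=float))

    @property
    def n_flies(self) -> int:
        return self.surfaces.shape[0]

    @classmethod
    def from_long(cls, activity: pd.DataFrame, max_day: float = 32.0) -> "ActivityPanel":
        """Build a panel from long-format (fly_id, day, hour, count) records.

        Only flies with complete coverage of days [0, max_day] are retained,
        mirroring the cohort restriction to flies surviving the full window.
        """
        sub = activity[activity["day"] <= max_day]
        day_grid = np.sort(sub["day"].unique())
        hour_grid = np.sort(sub["hour"].unique())
        wide = sub.pivot_table(
            index="fly_id", columns=["day", "hour"], values="count", aggfunc="sum"
        )
        full = wide.dropna(axis=0)
        n_cells = day_grid.size * hour_grid.size
        if full.shape[1] != n_cells:
            raise ValueError("irregular day/hour grid in activity table")
        surfaces = full.to_numpy().reshape(len(full), day_grid.size, hour_grid.size)
        return cls(full.index.to_numpy(), day_grid, hour_grid, surfaces)


def estimate_mean_surface(panel: ActivityPanel, smooth_bandwidths=None) -> np.ndarray:
    """Cross-sectional mean surface, optionally local-linear smoothed.

    ``smooth_bandwidths`` = (day_bw, hour_bw) applies a separable
    local-linear pass along each axis; the default (None) returns the raw
    pointwise mean, which is appropriate for dense count panels.
    """
    if panel.n_flies < 2:
        raise InsufficientDataError("mean surface requires at least 2 flies")
    mu = panel.surfaces.mean(axis=0)
    if smooth_bandwidths is not None:
        day_bw, hour_bw = smooth_bandwidths
        mu = np.stack(
            [local_linear_smooth(panel.day_grid, mu[:, s], panel.day_grid, day_bw)
             for s in range(mu.shape[1])], axis=1
        )
        mu = np.stack(
            [local_linear_smooth(panel.hour_grid, mu[t, :], panel.hour_grid, hour_bw)
             for t in range(mu.shape[0])], axis=0
        )
    return mu


def marginal_kernels(panel: ActivityPanel, mean: np.ndarray):
    """Hour- and day-marginal covariance kernels (G_S, G_T).

    The sample covariance G((s1,t1),(s2,t2)) (divisor n) is contracted by
    trapezoid integration over the shared day index for G_S (shape S x S)
    and over the shared hour index for G_T (shape D x D).
    """
    if panel.n_flies < 2:
        raise InsufficientDataError("covariance requires at least 2 flies")
    mean = np.asarray(mean, dtype=float)
    if mean.shape != panel.surfaces.shape[1:]:
        raise ValueError("mean surface shape does not match panel grids")
    R = panel.surfaces - mean[None]
    w_t = trapezoid_weights(panel.day_grid)
    w_s = trapezoid_weights(panel.hour_grid)
    n = panel.n_flies
    G_S = np.einsum("its,t,itu->su", R, w_t, R) / n
    G_T = np.einsum("its,s,ius->tu", R, w_s, R) / n
    G_S = (G_S + G_S.T) / 2
    G_T = (G_T + G_T.T) / 2
    return G_S, G_T


def _weighted_eigh(kernel: np.ndarray, grid: np.ndarray, n_comp: int):
    """Top eigenpairs of a covariance kernel in the trapezoid inner product.

    Solves the symmetric problem W^(1/2) K W^(1/2) v = lam v and rescales so
    the eigenfunctions are orthonormal under sum(w * f * g). Signs follow a
    deterministic convention: nonnegative trapezoid integral, falling back
    to a nonnegative left endpoint when the integral is (near) zero.
    """
    if not np.all(np.isfinite(kernel)):
        raise ValueError("covariance kernel contains non-finite entries")
    w = trapezoid_weights(grid)
    sw = np.sqrt(w)
    sym = sw[:, None] * kernel * sw[None, :]
    lam, vec = np.linalg.eigh(sym)
    order = np.argsort(lam)[::-1][:n_comp]
    lam = np.clip(lam[order], 0.0, None)
    funcs = (vec[:, order] / sw[:, None]).T
    for i, f in enumerate(funcs):
        integral = float(w @ f)
        if integral < -1e-8 or (abs(integral) <= 1e-8 and f[0] < 0):
            funcs[i] = -f
    return lam, funcs


class ProductFPCA:
    """Product FPCA model for an :class:`ActivityPanel`.

    Parameters
    ----------
    panel : ActivityPanel
    n_hour_components, n_day_components : int
        Numbers J and K of marginal hour and day eigenfunctions to retain.
    smooth_bandwidths : tuple, optional
        Passed through to :func:`estimate_mean_surface`.
    """

    def __init__(
        self,
        panel: ActivityPanel,
        n_hour_components: int = 2,
        n_day_components: int = 2,
        smooth_bandwidths=None,
    ):
        if n_hour_components > panel.hour_grid.size:
            raise ValueError("n_hour_components exceeds hour grid size")
        if n_day_components > panel.day_grid.size:
            raise ValueError("n_day_components exceeds day grid size")
        self.panel = panel
        self.J = n_hour_components
        self.K = n_day_components
        self.smooth_bandwidths = smooth_bandwidths

    def fit(self) -> "ProductFPCAResults":
        panel = self.panel
        mu = estimate_mean_surface(panel, self.smooth_bandwidths)
        G_S, G_T = marginal_kernels(panel, mu)
        hour_vals, psi = _weighted_eigh(G_S, panel.hour_grid, self.J)
        day_vals, phi = _weighted_eigh(G_T, panel.day_grid, self.K)
        w_t = trapezoid_weights(panel.day_grid)
        w_s = trapezoid_weights(panel.hour_grid)
        R = panel.surfaces - mu[None]
        # chi_ijk = double trapezoid integral of R_i against phi_k psi_j
        scores = np.einsum("its,t,s,kt,js->ijk", R, w_t, w_s, phi, psi, optimize=True)
        total_var = float(np.einsum("its,t,s->", R**2, w_t, w_s) / panel.n_flies)
        score_var = scores.var(axis=0)
        fve = score_var / total_var if total_var > 0 else np.zeros_like(score_var)
        return ProductFPCAResults(
            self, mu, G_S, G_T, psi, phi, hour_vals, day_vals, scores, fve, total_var
        )


@dataclass
class ProductFPCAResults:
    model: ProductFPCA
    mean_surface: np.ndarray
    hour_kernel: np.ndarray
    day_kernel: np.ndarray
    hour_eigenfunctions: np.ndarray  # (J, S)
    day_eigenfunctions: np.ndarray  # (K, D)
    hour_eigenvalues: np.ndarray
    day_eigenvalues: np.ndarray
    scores: np.ndarray  # (n, J, K)
    fve: np.ndarray  # (J, K)
    total_variance: float

    def components(self) -> pd.DataFrame:
        """Product components sorted by fraction of variance explained."""
        J, K = self.fve.shape
        rows = [
            {"hour_j": j + 1, "day_k": k + 1,
             "score_variance": float(self.scores[:, j, k].var()),
             "fve": float(self.fve[j, k])}
            for j in range(J) for k in range(K)
        ]
        return (
            pd.DataFrame(rows)
            .sort_values("fve", ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )

    def eigensurface(self, j: int, k: int) -> np.ndarray:
        """Product eigensurface phi_k(t) psi_j(s) (1-based indices)."""
        return np.outer(self.day_eigenfunctions[k - 1], self.hour_eigenfunctions[j - 1])

    def reconstruct(self, n_hour: int | None = None, n_day: int | None = None) -> np.ndarray:
        """Truncated Karhunen-Loeve reconstruction of every fly's surface."""
        J = self.model.J if n_hour is None else n_hour
        K = self.model.K if n_day is None else n_day
        if J > self.model.J or K > self.model.K:
            raise ValueError("cannot reconstruct with more components than fitted")
        out = np.repeat(self.mean_surface[None], self.model.panel.n_flies, axis=0)
        if J > 0 and K > 0:
            out = out + np.einsum(
                "ijk,kt,js->its",
                self.scores[:, :J, :K],
                self.day_eigenfunctions[:K],
                self.hour_eigenfunctions[:J],
            )
        return out

    def summary(self) -> str:
        comp = self.components()
        lines = [
            "Product FPCA of day x hour activity surfaces",
            "=" * 50,
            f"flies: {self.model.panel.n_flies}   "
            f"grid: {self.model.panel.day_grid.size} days x {self.model.panel.hour_grid.size} hours",
            f"components: J={self.model.J} hour x K={self.model.K} day",
            f"total centred variance: {self.total_variance:.4g}",
            "",
            "component  (psi_j x phi_k)   FVE",
        ]
        for _, r in comp.iterrows():
            lines.append(
                f"  psi_{int(r.hour_j)} x phi_{int(r.day_k)}        "
                f"{100 * r.fve:6.2f}%"
            )
        lines.append(f"  cumulative            {100 * comp.fve.sum():6.2f}%")
        return "\n".join(lines)

    def plot_eigensurfaces(self, pairs=None, axes=None):
        """Heatmaps of the leading product eigensurfaces."""
        import matplotlib.pyplot as plt

        comp = self.components()
        if pairs is None:
            pairs = [(int(r.hour_j), int(r.day_k)) for _, r in comp.head(4).iterrows()]
        if axes is None:
            _, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3))
        axes = np.atleast_1d(axes)
        for ax, (j, k) in zip(axes, pairs):
            surf = self.eigensurface(j, k)
            ax.imshow(surf.T, origin="lower", aspect="auto",
                      extent=[self.model.panel.day_grid[0], self.model.panel.day_grid[-1],
                              self.model.panel.hour_grid[0], self.model.panel.hour_grid[-1]])
            ax.set_xlabel("age (days)")
            ax.set_ylabel("hour")
            ax.set_title(f"psi_{j} x phi_{k}")
        return axes
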