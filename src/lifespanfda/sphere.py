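"""Riemannian FPCA for longitudinal compositional behavior data.

Daily proportions of three behaviors (flying, walking, resting) are
compositional: nonnegative and summing to one. The square-root transform
Y_j(t) = sqrt(Z_j(t) / sum_j Z_j(t)) places each day's composition on the
positive orthant of the unit sphere S^2, where the geodesic (great-circle)
metric respects the constraint geometry. Spherical FPCA then proceeds by

1. computing the intrinsic (Fréchet) mean curve mu(t) day by day,
2. mapping every trajectory into the tangent spaces of mu(t) with the
   Riemannian log map (pointwise tangent spaces, no parallel transport),
3. running a multivariate FPCA on the tangent-valued curves under the
   quadrature-weighted inner product, and
4. mapping truncated reconstructions back with the Riemannian exp map, so
   fitted trajectories are again valid unit-norm compositions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_increasing_grid, trapezoid_weights
from .distributions import InsufficientDataError

__all__ = [
    "GeometryError",
    "SphericalTrajectory",
    "BehaviorTrajectories",
    "compositional_sqrt_transform",
    "log_map",
    "exp_map",
    "geodesic_distance",
    "frechet_mean_curve",
    "SphericalFPCA",
    "SphericalFPCAResults",
]

logger = logging.getLogger(__name__)

BEHAVIORS = ("fly", "walk", "rest")


class GeometryError(ValueError):
    """Raised for invalid spherical-geometry inputs (antipodal, non-tangent)."""


@dataclass(frozen=True)
class SphericalTrajectory:
    """Unit-norm square-root composition vectors on a day grid.

    Rows of ``values`` (shape (n_days, 3), order fly/walk/rest) lie on the
    positive orthant of S^2; days masked for lack of observations are NaN.
    """

    fly_id: str
    day_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        dg = as_increasing_grid(self.day_grid, "day_grid")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (dg.size, 3):
            raise ValueError("values must have shape (n_days, 3)")
        ok = np.isfinite(v).all(axis=1)
        if np.any(v[ok] < -1e-8):
            raise ValueError("sqrt proportions must be nonnegative")
        norms = np.linalg.norm(v[ok], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("rows must have unit Euclidean norm (tol 1e-8)")
        object.__setattr__(self, "day_grid", dg)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BehaviorTrajectories:
    """A cohort of spherical trajectories on one shared day grid."""

    fly_ids: np.ndarray
    day_grid: np.ndarray
    values: np.ndarray  # (n, n_days, 3)

    def __post_init__(self):
        object.__setattr__(self, "fly_ids", np.asarray(self.fly_ids))
        object.__setattr__(self, "day_grid", np.asarray(self.day_grid, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> SphericalTrajectory:
        return SphericalTrajectory(str(self.fly_ids[i]), self.day_grid, self.values[i])


def compositional_sqrt_transform(
    behavior: pd.DataFrame, max_day: float | None = 41.0
) -> BehaviorTrajectories:
    """Square-root compositional transform of daily behavior counts.

    Each (fly, day) row (n_fly, n_walk, n_rest) becomes the unit vector of
    square-rooted proportions among the three behaviors. Days with a zero
    total are masked (NaN) and logged. Only flies covering the complete day
    grid up to ``max_day`` are retained (the survivor cohort).
    """
    df = behavior.copy()
    if max_day is not None:
        df = df[df["day"] <= max_day]
    counts = df[["n_fly", "n_walk", "n_rest"]].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        logger.warning("%d fly-days with zero behavior totals masked", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        sqrtp = np.sqrt(counts / totals[:, None])
    sqrtp[zero] = np.nan
    df = df.assign(_y0=sqrtp[:, 0], _y1=sqrtp[:, 1], _y2=sqrtp[:, 2])
    day_grid = np.sort(df["day"].unique())
    wide = df.pivot_table(index="fly_id", columns="day", values=["_y0", "_y1", "_y2"])
    full = wide.loc[wide.notna().all(axis=1)]
    dropped = set(wide.index) - set(full.index)
    if dropped:
        logger.warning("%d flies dropped (incomplete day coverage)", len(dropped))
    n = len(full)
    vals = np.empty((n, day_grid.size, 3))
    for j, comp in enumerate(["_y0", "_y1", "_y2"]):
        vals[:, :, j] = full[comp].reindex(columns=day_grid).to_numpy()
    return BehaviorTrajectories(full.index.to_numpy(), day_grid.astype(float), vals)


def _clamp_dot(p, q):
    return np.clip(np.sum(p * q, axis=-1), -1.0, 1.0)


def log_map(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Riemannian log map on S^2: the tangent vector at p pointing to q.

    Its norm is the geodesic distance arccos<p, q>. Broadcasts over leading
    axes. Antipodal pairs (which cannot occur on the positive orthant) raise
    :class:`GeometryError`.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dot = _clamp_dot(p, q)
    if np.any(dot <= -1.0 + 1e-12):
        raise GeometryError("log map undefined for antipodal points")
    theta = np.arccos(dot)
    residual = q - dot[..., None] * p
    nrm = np.linalg.norm(residual, axis=-1)
    scale = np.where(nrm > 1e-15, theta / np.where(nrm > 1e-15, nrm, 1.0), 0.0)
    return scale[..., None] * residual


def exp_map(p: np.ndarray, v: np.ndarray, tangent_tol: float = 1e-6) -> np.ndarray:
    """Riemannian exp map on S^2: cos(|v|) p + sin(|v|) v/|v|.

    ``v`` must be tangent to ``p`` within ``tangent_tol``; exp_map(p, 0) = p.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    nv = np.linalg.norm(v, axis=-1)
    proj = np.abs(np.sum(p * v, axis=-1))
    if np.any(proj > tangent_tol * np.maximum(1.0, nv)):
        raise GeometryError("v is not tangent to p")
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(nv[..., None] > 0, v / np.where(nv[..., None] > 0, nv[..., None], 1.0), 0.0)
    out = np.cos(nv)[..., None] * p + np.sin(nv)[..., None] * direction
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def geodesic_distance(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Great-circle distance arccos<p, q> (radians)."""
    return np.arccos(_clamp_dot(np.asarray(p, float), np.asarray(q, float)))


def frechet_mean_curve(
    values: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> np.ndarray:
    """Pointwise intrinsic (Fréchet) mean of spherical trajectories.

    At each day the mean is computed by iterated tangent averaging: map the
    available points to the tangent space of the current iterate, average,
    exp back; iterate until the update norm falls below ``tol``. For data
    confined to the positive orthant the iteration contracts. NaN rows
    (masked days) are skipped per day.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[0] < 2:
        raise InsufficientDataError("need at least 2 trajectories")
    n, T, _ = values.shape
    mean = np.empty((T, 3))
    for t in range(T):
        pts = values[:, t, :]
        pts = pts[np.isfinite(pts).all(axis=1)]
        if pts.shape[0] == 0:
            mean[t] = np.nan
            continue
        m = pts.mean(axis=0)
        m = m / np.linalg.norm(m)
        for _ in range(max_iter):
            v = log_map(m[None], pts).mean(axis=0)
            m_new = exp_map(m, v, tangent_tol=1e-6)
            if np.linalg.norm(v) < tol:
                m = m_new
                break
            m = m_new
        else:
            raise RuntimeError(
                f"Fréchet mean did not converge at day index {t}: "
                f"update norm {np.linalg.norm(v):.2e}"
            )
        mean[t] = m
    return mean


class SphericalFPCA:
    """Spherical FPCA model for a cohort of behavior trajectories.

    Parameters
    ----------
    trajectories : BehaviorTrajectories
    n_components : int
        Number K of tangent-space components to retain (K <= 3 * n_days).
    """

    def __init__(self, trajectories: BehaviorTrajectories, n_components: int = 3):
        if len(trajectories) < 2:
            raise InsufficientDataError("spherical FPCA requires at least 2 trajectories")
        if n_components > 3 * trajectories.day_grid.size:
            raise ValueError("n_components exceeds tangent dimension")
        self.trajectories = trajectories
        self.K = n_components

    def fit(self) -> "SphericalFPCAResults":
        traj = self.trajectories
        mu = frechet_mean_curve(traj.values)
        # tangent representation; at the Fréchet mean the log-mapped data
        # average to zero day by day, so no extra centring is applied
        tangent = log_map(mu[None], traj.values)  # (n, T, 3)
        n, T, _ = tangent.shape
        w_t = trapezoid_weights(traj.day_grid)
        w = np.repeat(w_t, 3)
        V = np.nan_to_num(tangent.reshape(n, T * 3))
        finite = np.isfinite(tangent.reshape(n, T * 3))
        counts = finite.T.astype(float) @ finite.astype(float)
        cov = (V.T @ V) / np.maximum(counts, 1.0)
        sw = np.sqrt(w)
        lam, vec = np.linalg.eigh(sw[:, None] * cov * sw[None, :])
        order = np.argsort(lam)[::-1]
        lam_all = np.clip(lam[order], 0.0, None)
        K = self.K
        funcs = (vec[:, order[:K]] / sw[:, None]).T.reshape(K, T, 3)
        # sign convention: first (in behavior order rest, walk, fly) nonzero
        # quadrature integral made nonnegative
        for k in range(K):
            for j in (2, 1, 0):
                integral = float(w_t @ funcs[k, :, j])
                if abs(integral) > 1e-8:
                    if integral < 0:
                        funcs[k] = -funcs[k]
                    break
        scores = np.einsum("itj,t,ktj->ik", np.nan_to_num(tangent), w_t, funcs)
        total = float(lam_all.sum())
        fve = lam_all[:K] / total if total > 0 else np.zeros(K)
        return SphericalFPCAResults(self, mu, funcs, lam_all[:K], scores, fve, total)


@dataclass
class SphericalFPCAResults:
    model: SphericalFPCA
    mean_curve: np.ndarray  # (T, 3) on the sphere
    eigenfunctions: np.ndarray  # (K, T, 3), tangent to mean_curve pointwise
    eigenvalues: np.ndarray
    scores: np.ndarray  # (n, K)
    fve: np.ndarray
    total_variance: float

    @property
    def day_grid(self) -> np.ndarray:
        return self.model.trajectories.day_grid

    def reconstruct(self, i: int, n_components: int | None = None) -> SphericalTrajectory:
        """Truncated tangent expansion of fly i, exp-mapped back to the sphere."""
        K = self.model.K if n_components is None else n_components
        if K > self.model.K:
            raise ValueError("cannot use more components than fitted")
        v = np.einsum("k,ktj->tj", self.scores[i, :K], self.eigenfunctions[:K]) \
            if K > 0 else np.zeros_like(self.mean_curve)
        vals = exp_map(self.mean_curve, v, tangent_tol=1e-6)
        vals = np.abs(vals)
        vals /= np.linalg.norm(vals, axis=-1, keepdims=True)
        return SphericalTrajectory(
            str(self.model.trajectories.fly_ids[i]), self.day_grid, vals
        )

    def reconstruction_error(self, n_components: int | None = None) -> float:
        """Mean geodesic distance between observed and fitted trajectories."""
        errs = []
        for i in range(len(self.model.trajectories)):
            fit = self.reconstruct(i, n_components)
            obs = self.model.trajectories.values[i]
            ok = np.isfinite(obs).all(axis=1)
            errs.append(geodesic_distance(obs[ok], fit.values[ok]).mean())
        return float(np.mean(errs))

    def summary(self) -> str:
        lines = [
            "Spherical FPCA of behavior compositions (fly/walk/rest)",
            "=" * 55,
            f"flies: {len(self.model.trajectories)}   "
            f"days: {self.day_grid[0]:.0f}..{self.day_grid[-1]:.0f}",
            f"total tangent variance: {self.total_variance:.4g} rad^2",
            "",
            "component   eigenvalue    FVE    cumulative",
        ]
        cum = 0.0
        for k in range(self.model.K):
            cum += self.fve[k]
            lines.append(
                f"  phi_{k + 1}     {self.eigenvalues[k]:10.4g}  "
                f"{100 * self.fve[k]:6.2f}%  {100 * cum:6.2f}%"
            )
        return "\n".join(lines)

    def plot_mean_and_eigenfunctions(self, axes=None):
        """Mean curve and eigenfunctions, one panel per component."""
        import matplotlib.pyplot as plt

        K = self.model.K
        if axes is None:
            _, axes = plt.subplots(1, K + 1, figsize=(3.2 * (K + 1), 3))
        for j, b in enumerate(BEHAVIORS):
            axes[0].plot(self.day_grid, self.mean_curve[:, j], label=b)
        axes[0].set_title("mean curve")
        axes[0].legend(fontsize=7)
        for k in range(K):
            for j in range(3):
                axes[k + 1].plot(self.day_grid, self.eigenfunctions[k, :, j])
            axes[k + 1].set_title(f"phi_{k + 1} ({100 * self.fve[k]:.1f}%)")
        for ax in axes:
            ax.set_xlabel("age (days)")
        return axes
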