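"""Seeded synthetic medfly cohorts with known ground truth.

Every generator draws from the statistical model that the matching analysis
stage assumes, so recovery of the generating parameters is a meaningful test
of each estimator:

* lifespans — Gompertz mortality (hazard alpha * exp(beta * t)), diet acting
  on the baseline alpha, truncated to (min_age, max_age];
* hourly activity surfaces — mean surface plus a separable Karhunen-Loeve
  expansion (products of hour and day eigenfunctions) with Gaussian scores,
  observed as Poisson counts through a softplus rate link;
* daily egg counts — a doubly stochastic Poisson (Cox) process whose
  intensity factor tau and event-time density are linked to age-at-death so
  that long-lived flies lay fewer eggs early and relatively more late
  (cost-of-reproduction pattern);
* behavior compositions — a spherical trajectory model: square-root
  compositions perturbed in the tangent space of a mean curve by a small
  number of functional components, observed as daily multinomial counts.

All randomness flows from one integer seed through
:func:`lifespanfda._utils.spawn_rngs` (SeedSequence spawning in a fixed
order), so any stage can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._utils import as_increasing_grid, spawn_rngs, trapezoid_weights

__all__ = [
    "CohortSpec",
    "ActivityGroundTruth",
    "EggGroundTruth",
    "BehaviorGroundTruth",
    "gen_lifespans",
    "gen_activity",
    "gen_activity_surfaces",
    "gen_egg_counts",
    "gen_behavior",
    "gen_behavior_trajectories",
    "orthonormalize",
]

DIET_LABELS = ("C10", "C20", "C50")


def orthonormalize(funcs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Gram-Schmidt under the quadrature inner product <f,g> = sum(w * f * g).

    ``funcs`` has shape (K, ...) with the leading axis indexing functions;
    weights broadcast over the remaining axes.
    """
    funcs = np.array(funcs, dtype=float)
    out = []
    for f in funcs:
        for g in out:
            f = f - np.sum(weights * f * g) * g
        nrm = np.sqrt(np.sum(weights * f * f))
        if nrm < 1e-12:
            raise ValueError("functions are linearly dependent under the quadrature")
        out.append(f / nrm)
    return np.array(out)


# ---------------------------------------------------------------------------
# lifespans


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated cohort with Gompertz mortality.

    ``gompertz_alpha_per_diet`` maps each diet label to the baseline hazard
    (1/day) at age 0; ``gompertz_beta`` is the shared log-slope of the hazard
    (1/day). ``min_age`` > 0 conditions the draw on survival past that age,
    which is how survivor cohorts (e.g. egg-laying flies alive past day 35)
    are generated with an exact target size.
    """

    n_flies: int = 96
    diet_labels: tuple = DIET_LABELS
    gompertz_alpha_per_diet: dict = field(
        default_factory=lambda: {"C10": 0.00040, "C20": 0.00022, "C50": 0.00030}
    )
    gompertz_beta: float = 0.10
    max_age: float = 90.0
    min_age: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.max_age <= 0:
            raise ValueError("max_age must be positive")
        if not (0 <= self.min_age < self.max_age):
            raise ValueError("min_age must lie in [0, max_age)")
        if self.gompertz_beta < 0:
            raise ValueError("gompertz_beta must be nonnegative")
        for lab in self.diet_labels:
            a = self.gompertz_alpha_per_diet.get(lab)
            if a is None or a <= 0:
                raise ValueError(f"missing or non-positive alpha for diet {lab!r}")


def _gompertz_cdf(t, alpha, beta):
    t = np.asarray(t, dtype=float)
    if beta == 0:
        return 1.0 - np.exp(-alpha * t)
    return 1.0 - np.exp(-(alpha / beta) * np.expm1(beta * t))


def _gompertz_ppf(u, alpha, beta):
    u = np.asarray(u, dtype=float)
    if beta == 0:
        return -np.log1p(-u) / alpha
    return np.log1p(-(beta / alpha) * np.log1p(-u)) / beta


def gen_lifespans(spec: CohortSpec) -> pd.DataFrame:
    """Draw a lifespan table: columns (fly_id, diet, age_at_death).

    Flies are assigned to diets in equal blocks (remainder to the first
    diets); ages-at-death are inverse-CDF draws from the Gompertz law
    conditioned on (min_age, max_age].
    """
    rng = spawn_rngs(spec.seed, 1)[0]
    n_d = len(spec.diet_labels)
    base, extra = divmod(spec.n_flies, n_d)
    diets = []
    for i, lab in enumerate(spec.diet_labels):
        diets.extend([lab] * (base + (1 if i < extra else 0)))
    rows = []
    for i, diet in enumerate(diets):
        a = spec.gompertz_alpha_per_diet[diet]
        b = spec.gompertz_beta
        lo = _gompertz_cdf(spec.min_age, a, b)
        hi = _gompertz_cdf(spec.max_age, a, b)
        u = rng.uniform(lo, hi)
        rows.append((f"fly_{i:04d}", diet, float(_gompertz_ppf(u, a, b))))
    return pd.DataFrame(rows, columns=["fly_id", "diet", "age_at_death"])


# ---------------------------------------------------------------------------
# activity surfaces


@dataclass(frozen=True)
class ActivityGroundTruth:
    """Separable Karhunen-Loeve truth for day x hour activity surfaces.

    ``mean_surface`` has shape (n_days, n_hours); ``day_eigenfunctions`` has
    shape (K, n_days) and ``hour_eigenfunctions`` (J, n_hours), each set
    orthonormal under the trapezoid inner product on its grid;
    ``score_variances[j, k]`` is Var(chi_jk) for the product component
    psi_j(s) * phi_k(t).
    """

    hour_grid: np.ndarray
    day_grid: np.ndarray
    mean_surface: np.ndarray
    hour_eigenfunctions: np.ndarray
    day_eigenfunctions: np.ndarray
    score_variances: np.ndarray

    def __post_init__(self):
        hg = as_increasing_grid(self.hour_grid, "hour_grid")
        dg = as_increasing_grid(self.day_grid, "day_grid")
        mu = np.asarray(self.mean_surface, dtype=float)
        psi = np.asarray(self.hour_eigenfunctions, dtype=float)
        phi = np.asarray(self.day_eigenfunctions, dtype=float)
        var = np.asarray(self.score_variances, dtype=float)
        if mu.shape != (dg.size, hg.size):
            raise ValueError("mean_surface must have shape (n_days, n_hours)")
        if psi.shape[1] != hg.size or phi.shape[1] != dg.size:
            raise ValueError("eigenfunction grids do not match the surface grids")
        if var.shape != (psi.shape[0], phi.shape[0]):
            raise ValueError("score_variances must have shape (J, K)")
        if np.any(var < 0):
            raise ValueError("score variances must be nonnegative")
        for funcs, w in ((psi, trapezoid_weights(hg)), (phi, trapezoid_weights(dg))):
            gram = (funcs * w) @ funcs.T
            if not np.allclose(gram, np.eye(funcs.shape[0]), atol=1e-6):
                raise ValueError("eigenfunctions must be orthonormal (tol 1e-6)")
        for name, val in (
            ("hour_grid", hg), ("day_grid", dg), ("mean_surface", mu),
            ("hour_eigenfunctions", psi), ("day_eigenfunctions", phi),
            ("score_variances", var),
        ):
            object.__setattr__(self, name, val)

    @classmethod
    def default(cls, score_variances=None) -> "ActivityGroundTruth":
        """Two hour x two day product components.

        The mean surface carries a circadian cycle (peak in the afternoon)
        damped by an early-life transient; the hour components contrast
        morning with afternoon activity and the day components early with
        late ages. The default score variances are sized so that, on top of
        the Poisson count noise of the observation model, the four product
        eigensurfaces explain roughly 12 / 7 / 3 / 1.5 percent of the total
        count variance — the order of magnitude seen in hourly locomotor
        monitoring, where most cell-level variance is shot noise.
        ``score_variances`` is a (J=2, K=2) matrix with [j, k] the variance
        of the score on psi_j(s) phi_k(t).
        """
        hg = np.linspace(0.0, 24.0, 25)
        dg = np.linspace(0.0, 32.0, 33)
        mu = (
            5.0
            + 2.5 * np.sin(2 * np.pi * (hg[None, :] - 6.0) / 24.0)
            + 1.5 * np.exp(-dg[:, None] / 20.0)
        )
        psi = orthonormalize(
            [np.cos(np.pi * hg / 24.0), np.cos(2 * np.pi * hg / 24.0)],
            trapezoid_weights(hg),
        )
        phi = orthonormalize(
            [np.cos(np.pi * dg / 32.0), np.cos(2 * np.pi * dg / 32.0)],
            trapezoid_weights(dg),
        )
        if score_variances is None:
            score_variances = [[700.0, 450.0], [190.0, 80.0]]
        var = np.asarray(score_variances, dtype=float)
        return cls(hg, dg, mu, psi, phi, var)

    def covariance_surface(self) -> np.ndarray:
        """Model covariance of vec(surface): sum of var_jk (phi_k psi_j)^(x2)."""
        n = self.day_grid.size * self.hour_grid.size
        cov = np.zeros((n, n))
        for j in range(self.hour_eigenfunctions.shape[0]):
            for k in range(self.day_eigenfunctions.shape[0]):
                eig = np.outer(self.day_eigenfunctions[k], self.hour_eigenfunctions[j]).ravel()
                cov += self.score_variances[j, k] * np.outer(eig, eig)
        return cov


def _softplus_rate(latent: np.ndarray, sharpness: float = 2.0) -> np.ndarray:
    return np.logaddexp(0.0, sharpness * latent) / sharpness


def gen_activity_surfaces(
    lifespans: pd.DataFrame,
    truth: ActivityGroundTruth,
    seed: int,
    noise: str = "poisson",
    link: str = "softplus",
):
    """Latent-to-observed activity surfaces for every fly (no death truncation).

    Returns (fly_ids, surfaces, scores) with surfaces of shape
    (n, n_days, n_hours) and scores of shape (n, J, K).
    """
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    if link not in ("softplus", "identity"):
        raise ValueError("link must be 'softplus' or 'identity'")
    rng = spawn_rngs(seed, 1)[0]
    psi, phi = truth.hour_eigenfunctions, truth.day_eigenfunctions
    J, K = psi.shape[0], phi.shape[0]
    n = len(lifespans)
    scores = rng.normal(size=(n, J, K)) * np.sqrt(truth.score_variances)[None]
    # latent_i(t, s) = mu(t, s) + sum_jk chi_ijk phi_k(t) psi_j(s)
    latent = truth.mean_surface[None] + np.einsum("ijk,kt,js->its", scores, phi, psi)
    if link == "softplus":
        rate = _softplus_rate(latent)
    else:
        rate = np.clip(latent, 0.0, None)
    if noise == "poisson":
        surfaces = rng.poisson(rate).astype(float)
    else:
        surfaces = rate
    return lifespans["fly_id"].to_numpy(), surfaces, scores


def gen_activity(
    lifespans: pd.DataFrame,
    truth: ActivityGroundTruth,
    seed: int,
    noise: str = "poisson",
    link: str = "softplus",
) -> pd.DataFrame:
    """Long-format hourly activity counts: columns (fly_id, day, hour, count).

    Only days up to each fly's age-at-death are emitted; the day and hour
    values are the grid points of the ground truth.
    """
    fly_ids, surfaces, _ = gen_activity_surfaces(lifespans, truth, seed, noise, link)
    death = lifespans.set_index("fly_id")["age_at_death"]
    frames = []
    dg, hg = truth.day_grid, truth.hour_grid
    for i, fid in enumerate(fly_ids):
        keep = dg <= death[fid]
        if not keep.any():
            continue
        day_idx = np.where(keep)[0]
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": fid,
                    "day": np.repeat(dg[day_idx], hg.size),
                    "hour": np.tile(hg, day_idx.size),
                    "count": surfaces[i, day_idx, :].ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# egg laying


@dataclass(frozen=True)
class EggGroundTruth:
    """Per-fly Cox-process truth for daily egg counts.

    Each fly i has an intensity factor tau_i (= expected total eggs on
    [0, horizon]) and an event-time density: a normal with mean ``peak_i``
    and sd ``spread_i`` truncated to [0, horizon]. The link to age-at-death
    x_i (centred at 35 days) is

        tau_i   = tau0   + tau_slope   * (x_i - 35) + noise,  floored at tau_min
        peak_i  = peak0  + peak_slope  * (x_i - 35) + noise,  clipped to [4, horizon - 5]
        spread_i = spread0 + spread_slope * (x_i - 35),       floored at 2

    With the default negative tau_slope and positive peak/spread slopes,
    long-lived flies lay fewer eggs early and relatively more late — the
    cost-of-reproduction pattern.
    """

    fly_id: np.ndarray
    age_at_death: np.ndarray
    tau: np.ndarray
    peak: np.ndarray
    spread: np.ndarray
    horizon: float = 40.0
    link: dict = field(default_factory=dict)

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        if np.any(tau < 0):
            raise ValueError("intensity factors must be nonnegative")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        object.__setattr__(self, "fly_id", np.asarray(self.fly_id))
        object.__setattr__(self, "age_at_death", np.asarray(self.age_at_death, dtype=float))
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "peak", np.asarray(self.peak, dtype=float))
        object.__setattr__(self, "spread", np.asarray(self.spread, dtype=float))

    DEFAULT_LINK = {
        "tau0": 120.0,
        "tau_slope": -0.8,
        "tau_sd": 15.0,
        "tau_min": 5.0,
        "peak0": 12.0,
        "peak_slope": 0.08,
        "peak_sd": 1.5,
        "spread0": 6.0,
        "spread_slope": 0.10,
    }

    @classmethod
    def from_lifespans(
        cls,
        lifespans: pd.DataFrame,
        seed: int,
        horizon: float = 40.0,
        link: dict | None = None,
    ) -> "EggGroundTruth":
        link = {**cls.DEFAULT_LINK, **(link or {})}
        rng = spawn_rngs(seed, 1)[0]
        x = lifespans["age_at_death"].to_numpy(dtype=float)
        xc = x - 35.0
        tau = link["tau0"] + link["tau_slope"] * xc + rng.normal(0, link["tau_sd"], x.size)
        tau = np.maximum(tau, link["tau_min"])
        peak = link["peak0"] + link["peak_slope"] * xc + rng.normal(0, link["peak_sd"], x.size)
        peak = np.clip(peak, 4.0, horizon - 5.0)
        spread = np.maximum(link["spread0"] + link["spread_slope"] * xc, 2.0)
        return cls(
            lifespans["fly_id"].to_numpy(), x, tau, peak, spread, horizon, link
        )

    def event_time_cdf(self, t: np.ndarray) -> np.ndarray:
        """CDF matrix (n_flies, len(t)) of the truncated-normal event-time laws."""
        t = np.asarray(t, dtype=float)
        a = (0.0 - self.peak) / self.spread
        b = (self.horizon - self.peak) / self.spread
        out = np.empty((self.tau.size, t.size))
        for i in range(self.tau.size):
            out[i] = truncnorm.cdf(t, a[i], b[i], loc=self.peak[i], scale=self.spread[i])
        return out


def gen_egg_counts(
    lifespans: pd.DataFrame,
    truth: EggGroundTruth,
    seed: int,
    n_days: int | None = None,
) -> pd.DataFrame:
    """Daily egg counts: columns (fly_id, day, eggs); day d covers (d-1, d].

    Counts are Poisson with mean tau_i * (F_i(d) - F_i(d-1)); only days up to
    each fly's age-at-death are emitted.
    """
    if n_days is None:
        n_days = int(np.floor(truth.horizon))
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    rng = spawn_rngs(seed, 1)[0]
    edges = np.arange(0, n_days + 1, dtype=float)
    F = truth.event_time_cdf(edges)
    day_mass = np.diff(F, axis=1)  # (n, n_days)
    means = truth.tau[:, None] * day_mass
    counts = rng.poisson(means)
    death = lifespans.set_index("fly_id")["age_at_death"]
    days = edges[1:]
    frames = []
    for i, fid in enumerate(truth.fly_id):
        keep = days <= death[fid]
        frames.append(
            pd.DataFrame({"fly_id": fid, "day": days[keep].astype(int), "eggs": counts[i, keep]})
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# behaviors


def _sphere_tangent_basis(mu: np.ndarray):
    """Smooth tangent frame along a mean curve on the positive orthant of S^2.

    mu has shape (n_days, 3) in the (fly, walk, rest) coordinate order.
    u1 lies in the walk-rest plane (no flying component), u2 = mu x u1.
    """
    u1 = np.zeros_like(mu)
    u1[:, 1] = mu[:, 2]
    u1[:, 2] = -mu[:, 1]
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    u2 = np.cross(mu, u1)
    u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
    return u1, u2


@dataclass(frozen=True)
class BehaviorGroundTruth:
    """Spherical-trajectory truth for (fly, walk, rest) compositions.

    ``mean_composition`` (n_days, 3) holds proportions summing to one at each
    age; subject deviations are Gaussian scores on ``tangent_eigenfunctions``
    (K, n_days, 3), each tangent to the square-root mean curve pointwise and
    orthonormal under the trapezoid inner product on the day grid.
    """

    day_grid: np.ndarray
    mean_composition: np.ndarray
    tangent_eigenfunctions: np.ndarray
    score_variances: np.ndarray

    def __post_init__(self):
        dg = as_increasing_grid(self.day_grid, "day_grid")
        p = np.asarray(self.mean_composition, dtype=float)
        eig = np.asarray(self.tangent_eigenfunctions, dtype=float)
        var = np.asarray(self.score_variances, dtype=float)
        if p.shape != (dg.size, 3):
            raise ValueError("mean_composition must have shape (n_days, 3)")
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("mean compositions must be nonnegative and sum to 1")
        if eig.shape[1:] != (dg.size, 3) or var.shape != (eig.shape[0],):
            raise ValueError("tangent eigenfunctions/score variances inconsistent")
        if np.any(var < 0):
            raise ValueError("score variances must be nonnegative")
        mu = np.sqrt(p)
        if np.max(np.abs(np.einsum("ktj,tj->kt", eig, mu))) > 1e-6:
            raise ValueError("tangent eigenfunctions must be orthogonal to the mean curve")
        for name, val in (
            ("day_grid", dg), ("mean_composition", p),
            ("tangent_eigenfunctions", eig), ("score_variances", var),
        ):
            object.__setattr__(self, name, val)

    @property
    def mean_sphere_curve(self) -> np.ndarray:
        return np.sqrt(self.mean_composition)

    @classmethod
    def default(
        cls, score_variances=(0.8, 0.12, 0.04), day_grid=None
    ) -> "BehaviorGroundTruth":
        """Three tangent components; resting dominates and rises with age.

        The leading component shifts the walk/rest balance uniformly over
        age, the second contrasts early with late ages on the same axis, and
        the third moves flying against the other behaviors. Default score
        variances give geodesic deviations of roughly 0.1-0.3 rad, keeping
        trajectories well inside the positive orthant.
        """
        if day_grid is None:
            day_grid = np.arange(0.0, 42.0)
        dg = as_increasing_grid(day_grid, "day_grid")
        frac = (dg - dg[0]) / (dg[-1] - dg[0])
        p_fly = 0.10 - 0.04 * frac
        p_rest = 0.50 + 0.08 * frac
        p_walk = 1.0 - p_fly - p_rest
        p = np.stack([p_fly, p_walk, p_rest], axis=1)
        mu = np.sqrt(p)
        u1, u2 = _sphere_tangent_basis(mu)
        shapes = [
            np.ones(dg.size)[:, None] * u1,
            np.cos(np.pi * frac)[:, None] * u1,
            np.ones(dg.size)[:, None] * u2,
        ]
        w = trapezoid_weights(dg)[:, None]
        eig = orthonormalize(np.array(shapes), w)
        return cls(dg, p, eig, np.asarray(score_variances, dtype=float))


def _exp_map_rows(p: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise spherical exponential map (p unit rows, v tangent rows)."""
    nv = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(nv > 0, v / np.where(nv > 0, nv, 1.0), 0.0)
    return np.cos(nv) * p + np.sin(nv) * direction


def gen_behavior_trajectories(
    lifespans: pd.DataFrame, truth: BehaviorGroundTruth, seed: int
):
    """Latent square-root composition curves for every fly.

    Returns (fly_ids, trajectories, scores) with trajectories of shape
    (n, n_days, 3), unit-norm rows. Components that leave the positive
    orthant (rare under the default variances) are folded to their absolute
    value, which is what observing proportions implies.
    """
    rng = spawn_rngs(seed, 1)[0]
    n = len(lifespans)
    K = truth.score_variances.size
    scores = rng.normal(size=(n, K)) * np.sqrt(truth.score_variances)[None]
    mu = truth.mean_sphere_curve
    tangent = np.einsum("ik,ktj->itj", scores, truth.tangent_eigenfunctions)
    traj = _exp_map_rows(mu[None], tangent)
    traj = np.abs(traj)
    traj /= np.linalg.norm(traj, axis=-1, keepdims=True)
    return lifespans["fly_id"].to_numpy(), traj, scores


def gen_behavior(
    lifespans: pd.DataFrame,
    truth: BehaviorGroundTruth,
    seed: int,
    n_daily_obs: int = 12,
) -> pd.DataFrame:
    """Daily behavior observation counts: columns (fly_id, day, n_fly, n_walk, n_rest).

    Each day's counts are one multinomial(n_daily_obs, p(t)) draw with
    p(t) the square of the fly's latent sphere trajectory; only days up to
    min(last grid day, age-at-death) are emitted.
    """
    if n_daily_obs < 1:
        raise ValueError("n_daily_obs must be >= 1")
    _, rng_obs = spawn_rngs(seed, 2)
    fly_ids, traj, _ = gen_behavior_trajectories(lifespans, truth, seed)
    probs = traj**2
    probs /= probs.sum(axis=-1, keepdims=True)
    death = lifespans.set_index("fly_id")["age_at_death"]
    dg = truth.day_grid
    frames = []
    for i, fid in enumerate(fly_ids):
        keep = np.where(dg <= death[fid])[0]
        if keep.size == 0:
            continue
        counts = rng_obs.multinomial(n_daily_obs, probs[i, keep])
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": fid,
                    "day": dg[keep],
                    "n_fly": counts[:, 0],
                    "n_walk": counts[:, 1],
                    "n_rest": counts[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
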