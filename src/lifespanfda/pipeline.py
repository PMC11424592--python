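"""End-to-end orchestration of the five analyses from a single config.

The pipeline simulates (or loads) the three cohorts — activity-monitored
flies, egg-laying flies surviving past the Cox horizon, and behavior-scored
flies surviving past the behavior window — then runs, in order:
remaining-lifetime Fréchet regression, product FPCA of activity surfaces,
Cox point-process regression of egg-laying on longevity, concurrent
regression of reproductive-rate change, and spherical FPCA of behavior
compositions. Every output file is hashed into a JSON manifest, so a run is
reproducible bit for bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.random import SeedSequence

from . import io as lio
from .concurrent import ConcurrentRegression
from .cox import CoxPointProcessRegression
from .fpca import ActivityPanel, ProductFPCA
from .frechet import RemainingLifetimeFrechet, diet_indicators
from .simulate import (
    ActivityGroundTruth,
    BehaviorGroundTruth,
    CohortSpec,
    EggGroundTruth,
    gen_activity,
    gen_behavior,
    gen_egg_counts,
    gen_lifespans,
)
from .sphere import SphericalFPCA, compositional_sqrt_transform

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "remaining_lifetime",
    "product_fpca",
    "cox",
    "concurrent",
    "spherical_fpca",
)


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    The three cohorts carry different survival restrictions (full activity
    window, past the Cox horizon, past the behavior window), which is why
    each stage block names its cohort explicitly.
    """

    seed: int = 0
    output_dir: str = "pipeline_out"
    stages: tuple = ALL_STAGES
    # cohort sizes mirror the monitored medfly experiments: 96 activity
    # flies in three diet groups, 473 egg-laying flies alive past day 35,
    # 51 behavior flies (their survivor subset is taken downstream)
    activity_cohort: dict = field(default_factory=lambda: {"n_flies": 96, "seed": 0})
    egg_cohort: dict = field(
        default_factory=lambda: {"n_flies": 473, "min_age": 36.0, "seed": 0}
    )
    behavior_cohort: dict = field(
        default_factory=lambda: {"n_flies": 51, "min_age": 41.5, "seed": 0}
    )
    remaining_lifetime: dict = field(
        default_factory=lambda: {"ages": list(range(1, 31)), "report_ages": [1, 10, 20, 30]}
    )
    product_fpca: dict = field(
        default_factory=lambda: {"n_hour_components": 2, "n_day_components": 2}
    )
    cox: dict = field(
        default_factory=lambda: {"horizon": 35.0, "m_min": 10,
                                 "predict_ages": [36, 50, 65, 80, 90]}
    )
    concurrent: dict = field(
        default_factory=lambda: {"t_start": 10, "t_end": 35,
                                 "n_bootstrap": 200, "level": 0.95}
    )
    spherical_fpca: dict = field(default_factory=lambda: {"n_components": 3})

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                default = getattr(cls(), f.name)
                if isinstance(default, dict) and isinstance(raw[f.name], dict):
                    merged[f.name] = {**default, **raw[f.name]}
                else:
                    merged[f.name] = raw[f.name]
        cfg = cls(**merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if self.cox["horizon"] <= 0:
            raise ValueError("cox horizon must be positive")
        if not (0 < self.concurrent["level"] < 1):
            raise ValueError("concurrent level must be in (0, 1)")
        if self.concurrent["t_start"] >= self.concurrent["t_end"]:
            raise ValueError("concurrent day range is empty")
        if self.product_fpca["n_hour_components"] < 1 or self.product_fpca["n_day_components"] < 1:
            raise ValueError("product FPCA needs at least one component per axis")
        if self.spherical_fpca["n_components"] < 1:
            raise ValueError("spherical FPCA needs at least one component")

    def stage_seeds(self) -> dict:
        """Integer sub-seeds for every randomised stage, derived from the
        master seed via SeedSequence in a fixed documented order."""
        state = SeedSequence(self.seed).generate_state(8)
        names = [
            "activity_lifespans", "activity", "egg_lifespans", "egg_truth",
            "egg_counts", "behavior_lifespans", "behavior", "cox_jitter",
        ]
        return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def _curve_frame(rows):
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the output manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    files: dict[str, Path] = {}
    stage_info: dict[str, dict] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        files[name] = path

    # ---- simulate the three cohorts ---------------------------------
    act_spec = CohortSpec(**{**config.activity_cohort, "seed": seeds["activity_lifespans"]})
    act_lifespans = gen_lifespans(act_spec)
    act_truth = ActivityGroundTruth.default()
    activity = gen_activity(act_lifespans, act_truth, seeds["activity"])

    egg_spec = CohortSpec(**{**config.egg_cohort, "seed": seeds["egg_lifespans"]})
    egg_lifespans = gen_lifespans(egg_spec)
    egg_truth = EggGroundTruth.from_lifespans(egg_lifespans, seeds["egg_truth"])
    eggs = gen_egg_counts(egg_lifespans, egg_truth, seeds["egg_counts"])

    beh_spec = CohortSpec(**{**config.behavior_cohort, "seed": seeds["behavior_lifespans"]})
    beh_lifespans = gen_lifespans(beh_spec)
    beh_truth = BehaviorGroundTruth.default()
    behavior = gen_behavior(beh_lifespans, beh_truth, seeds["behavior"])

    emit("activity_lifespans.csv", lambda p: lio.write_lifespans(act_lifespans, p))
    emit("activity.csv", lambda p: lio.write_activity(activity, p))
    emit("egg_lifespans.csv", lambda p: lio.write_lifespans(egg_lifespans, p))
    emit("eggs.csv", lambda p: lio.write_eggs(eggs, p))
    emit("behavior_lifespans.csv", lambda p: lio.write_lifespans(beh_lifespans, p))
    emit("behavior.csv", lambda p: lio.write_behavior(behavior, p))
    emit("egg_truth.json", lambda p: lio.truth_to_json(egg_truth, p))
    emit("activity_truth.json", lambda p: lio.truth_to_json(act_truth, p))
    emit("behavior_truth.json", lambda p: lio.truth_to_json(beh_truth, p))

    # ---- stage: remaining-lifetime Fréchet regression ---------------
    if "remaining_lifetime" in config.stages:
        pars = config.remaining_lifetime
        cov = diet_indicators(act_lifespans)
        res = RemainingLifetimeFrechet(
            act_lifespans, ages=pars["ages"], covariates=cov
        ).fit()
        rows_q, rows_d, rows_h = [], [], []
        diets = sorted(act_lifespans["diet"].unique())
        combos = {
            d: tuple(float(d == c) for c in diets if c != diets[0]) for d in diets
        }
        for a in pars["report_ages"]:
            for diet, ind in combos.items():
                q, dens, haz = res.predict_curves(float(a), ind)
                base = {"a": a, "diet": diet}
                rows_q.append(q.to_frame().assign(**base))
                rows_d.append(dens.to_frame().assign(**base))
                rows_h.append(haz.to_frame().assign(**base))
        emit("remaining_quantiles.csv", lambda p: _curve_frame(rows_q).to_csv(p, index=False))
        emit("remaining_densities.csv", lambda p: _curve_frame(rows_d).to_csv(p, index=False))
        emit("remaining_hazards.csv", lambda p: _curve_frame(rows_h).to_csv(p, index=False))
        stage_info["remaining_lifetime"] = {
            "n_cells": len(res.cells), "ages": list(pars["ages"])
        }

    # ---- stage: product FPCA ----------------------------------------
    if "product_fpca" in config.stages:
        pars = config.product_fpca
        panel = ActivityPanel.from_long(activity)
        res = ProductFPCA(
            panel, pars["n_hour_components"], pars["n_day_components"]
        ).fit()
        emit("fpca_mean_surface.csv", lambda p: pd.DataFrame(
            res.mean_surface, index=panel.day_grid, columns=panel.hour_grid
        ).to_csv(p))
        emit("fpca_hour_eigenfunctions.csv", lambda p: pd.DataFrame(
            res.hour_eigenfunctions.T, index=panel.hour_grid
        ).to_csv(p))
        emit("fpca_day_eigenfunctions.csv", lambda p: pd.DataFrame(
            res.day_eigenfunctions.T, index=panel.day_grid
        ).to_csv(p))
        emit("fpca_components.csv", lambda p: res.components().to_csv(p, index=False))
        stage_info["product_fpca"] = {
            "n_flies": panel.n_flies,
            "fve": res.components()["fve"].tolist(),
        }

    # ---- stage: Cox point-process regression ------------------------
    if "cox" in config.stages:
        pars = config.cox
        model = CoxPointProcessRegression.from_tables(
            eggs, egg_lifespans, horizon=pars["horizon"],
            jitter_seed=seeds["cox_jitter"], m_min=pars["m_min"],
        )
        res = model.fit()
        rows = []
        for x in pars["predict_ages"]:
            grid, lam = res.predict_intensity(float(x))
            rows.append(pd.DataFrame({"age_at_death": x, "day": grid, "intensity": lam}))
        emit("cox_intensities.csv", lambda p: _curve_frame(rows).to_csv(p, index=False))
        emit("cox_tau_fit.json", lambda p: _write_json(p, {
            "intercept": res.tau_intercept, "slope": res.tau_slope,
            "n_flies": int(model.x.size),
        }))
        stage_info["cox"] = {"n_flies": int(model.x.size), "tau_slope": res.tau_slope}

    # ---- stage: concurrent regression -------------------------------
    if "concurrent" in config.stages:
        pars = config.concurrent
        res = ConcurrentRegression(eggs, pars["t_start"], pars["t_end"]).fit()
        bands = res.bootstrap_bands(
            n_replicates=pars["n_bootstrap"], level=pars["level"],
            seed=seeds["cox_jitter"] + 1,
        )
        frame = pd.DataFrame({
            "day": res.day_grid,
            "beta0": res.beta0, "beta1": res.beta1,
            "beta0_lower": bands.beta0_lower, "beta0_upper": bands.beta0_upper,
            "beta1_lower": bands.beta1_lower, "beta1_upper": bands.beta1_upper,
            "beta1_significant": bands.beta1_significant(),
        })
        emit("concurrent_coefficients.csv", lambda p: frame.to_csv(p, index=False))
        stage_info["concurrent"] = {
            "n_flies": int(res.model.X.shape[0]),
            "days_beta1_negative": int(np.nansum(res.beta1 < 0)),
        }

    # ---- stage: spherical FPCA --------------------------------------
    if "spherical_fpca" in config.stages:
        pars = config.spherical_fpca
        traj = compositional_sqrt_transform(behavior)
        res = SphericalFPCA(traj, pars["n_components"]).fit()
        emit("sphere_mean_curve.csv", lambda p: pd.DataFrame(
            res.mean_curve, index=traj.day_grid, columns=["fly", "walk", "rest"]
        ).to_csv(p))
        eig_frames = []
        for k in range(pars["n_components"]):
            eig_frames.append(pd.DataFrame(
                res.eigenfunctions[k], index=traj.day_grid,
                columns=["fly", "walk", "rest"],
            ).assign(component=k + 1))
        emit("sphere_eigenfunctions.csv", lambda p: _curve_frame(eig_frames).to_csv(p))
        emit("sphere_fve.json", lambda p: _write_json(p, {
            "fve": res.fve.tolist(), "eigenvalues": res.eigenvalues.tolist(),
        }))
        stage_info["spherical_fpca"] = {
            "n_flies": len(traj), "fve": res.fve.tolist()
        }

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": stage_info,
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
        "config": dataclasses.asdict(config),
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
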