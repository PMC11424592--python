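"""Readers and writers for the four cohort CSV schemas and ground-truth JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ActivityGroundTruth, BehaviorGroundTruth, EggGroundTruth

__all__ = [
    "read_lifespans",
    "write_lifespans",
    "read_activity",
    "write_activity",
    "read_eggs",
    "write_eggs",
    "read_behavior",
    "write_behavior",
    "truth_to_json",
    "truth_from_json",
]

_SCHEMAS = {
    "lifespans": ["fly_id", "diet", "age_at_death"],
    "activity": ["fly_id", "day", "hour", "count"],
    "eggs": ["fly_id", "day", "eggs"],
    "behavior": ["fly_id", "day", "n_fly", "n_walk", "n_rest"],
}


def _check(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    cols = _SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{schema} table missing columns {missing}")
    df = df[cols].copy()
    numeric = [c for c in cols if c != "fly_id" and c != "diet"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c])
        if df[c].isna().any():
            raise ValueError(f"{schema} table has missing values in column {c!r}")
    if schema == "lifespans":
        if df["fly_id"].duplicated().any():
            raise ValueError("fly_id must be unique in a lifespan table")
        if (df["age_at_death"] <= 0).any():
            raise ValueError("age_at_death must be positive")
    if schema in ("activity", "eggs"):
        value = "count" if schema == "activity" else "eggs"
        if (df[value] < 0).any():
            raise ValueError(f"{value} must be nonnegative")
    if schema == "behavior":
        if (df[["n_fly", "n_walk", "n_rest"]] < 0).to_numpy().any():
            raise ValueError("behavior counts must be nonnegative")
    return df


def _make_rw(schema):
    def read(path: str | Path) -> pd.DataFrame:
        return _check(pd.read_csv(path), schema)

    def write(df: pd.DataFrame, path: str | Path) -> None:
        _check(df, schema).to_csv(path, index=False)

    read.__name__ = f"read_{schema}"
    write.__name__ = f"write_{schema}"
    read.__doc__ = f"Read and validate a {schema} CSV ({', '.join(_SCHEMAS[schema])})."
    write.__doc__ = f"Validate and write a {schema} CSV ({', '.join(_SCHEMAS[schema])})."
    return read, write


read_lifespans, write_lifespans = _make_rw("lifespans")
read_activity, write_activity = _make_rw("activity")
read_eggs, write_eggs = _make_rw("eggs")
read_behavior, write_behavior = _make_rw("behavior")

_TRUTH_CLASSES = {
    "ActivityGroundTruth": ActivityGroundTruth,
    "EggGroundTruth": EggGroundTruth,
    "BehaviorGroundTruth": BehaviorGroundTruth,
}


def truth_to_json(truth, path: str | Path) -> None:
    """Serialize a ground-truth object to JSON (lossless: floats round-trip)."""
    payload = {"__class__": type(truth).__name__}
    for f in dataclasses.fields(truth):
        val = getattr(truth, f.name)
        if isinstance(val, np.ndarray):
            val = {"__array__": val.tolist(), "dtype": str(val.dtype)}
        payload[f.name] = val
    Path(path).write_text(json.dumps(payload, indent=2))


def truth_from_json(path: str | Path):
    """Inverse of :func:`truth_to_json`."""
    payload = json.loads(Path(path).read_text())
    cls = _TRUTH_CLASSES[payload.pop("__class__")]
    kwargs = {}
    for key, val in payload.items():
        if isinstance(val, dict) and "__array__" in val:
            val = np.asarray(val["__array__"], dtype=val["dtype"])
        kwargs[key] = val
    return cls(**kwargs)
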