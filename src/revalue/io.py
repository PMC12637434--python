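"""File I/O: trial tables and value tables as CSV, spike containers as
HDF5, configuration as YAML, plus fail-fast schema validation and run
manifests.

CSV dialect: UTF-8, comma separated, header required, '.' decimal; times in
seconds as floats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .task import SessionData, TaskConfig

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "write_values_csv",
    "read_values_csv",
    "write_spikes_h5",
    "read_spikes_h5",
    "write_config_yaml",
    "read_config_yaml",
    "validate_trial_counts",
    "write_manifest",
]

TRIALS_COLUMNS = [
    "session_id",
    "trial",
    "block_side",
    "choice",
    "outcome",
    "stim_collected",
    "R",
    "t_go",
    "t_move",
    "t_outcome",
    "t_stim",
]

VALUES_REQUIRED = ["trial", "q_L", "q_R", "q_contra", "q_ipsi", "delta_q", "v", "p_right"]


class SchemaError(ValueError):
    """A named, fail-fast validation error; no partial outputs follow it."""


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def write_trials_csv(session: SessionData, path: str | Path) -> None:
    session.to_dataframe().to_csv(path, index=False)


def read_trials_csv(
    path: str | Path, hemisphere: str = "left", config: TaskConfig | None = None
) -> SessionData:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRIALS_COLUMNS, "trial table")
    for col in ("trial", "block_side", "choice", "outcome", "R", "t_go"):
        if df[col].isna().any():
            raise SchemaError(f"trial table has NaN in required column {col!r}")
    return SessionData.from_dataframe(df, hemisphere=hemisphere, config=config)


def write_values_csv(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, index=False)


def read_values_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, VALUES_REQUIRED, "value table")
    return df


def write_spikes_h5(
    path: str | Path,
    counts: np.ndarray,
    bin_edges: np.ndarray,
    metadata: pd.DataFrame | None = None,
) -> None:
    """Spike container: counts[neuron, trial, bin] + bin edges + metadata."""
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise SchemaError("counts must be (n_neurons, n_trials, n_bins)")
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=counts)
        f.create_dataset("bin_edges", data=np.asarray(bin_edges, dtype=float))
        if metadata is not None:
            grp = f.create_group("neurons")
            for col in metadata.columns:
                vals = metadata[col].to_numpy()
                if vals.dtype.kind in ("U", "O"):
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)


def read_spikes_h5(path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame | None]:
    with h5py.File(path, "r") as f:
        counts = f["counts"][...]
        edges = f["bin_edges"][...]
        meta = None
        if "neurons" in f:
            cols = {}
            for col in f["neurons"]:
                v = f["neurons"][col][...]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[col] = v
            meta = pd.DataFrame(cols)
    return counts, edges, meta


def write_config_yaml(config, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f, sort_keys=True)


def read_config_yaml(path: str | Path, cls=TaskConfig):
    with open(path) as f:
        data = yaml.safe_load(f)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    for key, val in data.items():
        if isinstance(val, list):
            data[key] = tuple(val)
    return cls(**data)


def validate_trial_counts(**named_counts: int) -> None:
    """Raise a SchemaError naming every source if trial counts disagree."""
    values = set(named_counts.values())
    if len(values) > 1:
        detail = ", ".join(f"{k}={v}" for k, v in named_counts.items())
        raise SchemaError(f"inconsistent trial counts across inputs: {detail}")


def write_manifest(path: str | Path, seed: int, config=None, extra: dict | None = None) -> None:
    """Reproducibility manifest: seed, config hash, package version."""
    from . import __version__

    payload = {"seed": int(seed), "version": __version__}
    if config is not None:
        blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
        payload["config"] = dataclasses.asdict(config)
        payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    if extra:
        payload.update(extra)
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, default=str)
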