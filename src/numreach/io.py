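"""Trajectory file I/O and run configuration.

The on-disk dialect is a long CSV with header ``trial_id,t_ms,x_cm,depth_cm``
(one row per motion sample) plus a JSON sidecar keyed by trial id holding
per-trial metadata (ratio, counts, movement time, choice, RT, ...).
Positions round-trip at full float precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trials import SimTrial, TrialDataset

__all__ = [
    "ParseError",
    "RunConfig",
    "write_trajectories",
    "read_trajectories",
    "sidecar_path_for",
]

REQUIRED_COLUMNS = ["trial_id", "t_ms", "x_cm", "depth_cm"]


class ParseError(ValueError):
    """Malformed trajectory file; the message carries the offending line."""


def sidecar_path_for(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_trajectories(dataset: TrialDataset, csv_path, sidecar_path=None) -> None:
    """Write a dataset as trajectory CSV + JSON metadata sidecar."""
    csv_path = Path(csv_path)
    frame = dataset.to_frame()
    # %.17g guarantees bit-exact float round-trips through the text format
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = Path(sidecar_path) if sidecar_path else sidecar_path_for(csv_path)
    with open(sidecar, "w") as fh:
        json.dump(dataset.sidecar(), fh, indent=1)


def read_trajectories(csv_path, sidecar_path=None) -> TrialDataset:
    """Read a trajectory CSV (and its sidecar, when present) back into a dataset.

    Rows must be grouped by trial with strictly increasing ``t_ms`` within
    each trial; violations raise :class:`ParseError` with the file line
    number.  A missing sidecar loads the trajectories with metadata marked
    absent.
    """
    csv_path = Path(csv_path)
    try:
        frame = pd.read_csv(csv_path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{csv_path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{csv_path}: line 1: missing columns {missing}")
    sidecar = Path(sidecar_path) if sidecar_path else sidecar_path_for(csv_path)
    meta_by_trial: dict = {}
    metadata_absent = not sidecar.exists()
    if not metadata_absent:
        with open(sidecar) as fh:
            meta_by_trial = json.load(fh)

    trials = []
    for trial_id, group in frame.groupby("trial_id", sort=False):
        t = group["t_ms"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            line = int(group.index[bad[0] + 1]) + 2  # header + 0-based index
            raise ParseError(
                f"{csv_path}: line {line}: non-monotone t_ms within trial {trial_id}"
            )
        x = group["x_cm"].to_numpy(dtype=float)
        depth_raw = group["depth_cm"].to_numpy(dtype=float)
        depth = None if np.isnan(depth_raw).all() else depth_raw
        dt = float(np.median(np.diff(t))) / 1000.0 if len(t) > 1 else 0.001
        info = meta_by_trial.get(str(trial_id), {})
        meta = {k: v for k, v in info.items()
                if k not in ("ratio", "n_left", "n_right", "tf_s", "correct_side",
                             "choice", "correct", "rt_ms", "responded", "com_count")}
        if metadata_absent:
            meta["metadata_absent"] = True
        endpoint_side = "left" if x[-1] < 0 else "right"
        trials.append(
            SimTrial(
                trial_id=int(trial_id),
                n_left=int(info.get("n_left", 0)),
                n_right=int(info.get("n_right", 0)),
                ratio=float(info.get("ratio", np.nan)),
                correct_side=info.get("correct_side"),
                tf_s=float(info.get("tf_s", t[-1] / 1000.0)),
                dt=dt,
                x_cm=x,
                depth_cm=depth,
                choice=info.get("choice", endpoint_side),
                correct=info.get("correct"),
                rt_ms=info.get("rt_ms"),
                responded=bool(info.get("responded", True)),
                com_count=int(info.get("com_count", 0)),
                meta=meta,
            )
        )
    return TrialDataset(trials, {"source": str(csv_path),
                                 "metadata_absent": metadata_absent})


@dataclass
class RunConfig:
    """Serializable configuration for a CLI run.

    Round-trips losslessly through YAML; unknown keys are rejected so a
    typo in a config file fails loudly instead of silently using defaults.
    """

    command: str = ""
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    model: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
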