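"""Trial records and dataset container shared by the simulator, the
synthetic-data generator and file I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["SimTrial", "TrialDataset"]


@dataclass
class SimTrial:
    """One reach trial: stimulus, trajectory, and behavioural annotations.

    Trajectories are in screen coordinates (horizontal x, right-positive,
    cm) sampled every ``dt`` seconds from movement-clock zero; ``depth_cm``
    runs from 0 at the start button to ~29 cm at the screen.  Model trials
    additionally carry the evidence stream and the belief time series (one
    entry per evidence sample).
    """

    trial_id: int
    n_left: int
    n_right: int
    ratio: float
    correct_side: str | None
    tf_s: float
    dt: float
    x_cm: np.ndarray
    depth_cm: np.ndarray | None
    choice: str
    correct: bool | None
    rt_ms: float | None
    responded: bool = True
    com_count: int = 0
    com_directions: list = field(default_factory=list)
    sample_times_ms: np.ndarray | None = None
    raw: np.ndarray | None = None
    ema: np.ndarray | None = None
    p_correct: np.ndarray | None = None
    certainty: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(len(self.x_cm)) * self.dt * 1000.0

    @property
    def endpoint_side(self) -> str:
        """Side of the final horizontal position; midline endpoints count right."""
        return "left" if self.x_cm[-1] < 0 else "right"

    @property
    def n_steps(self) -> int:
        return len(self.x_cm) - 1


@dataclass
class TrialDataset:
    """An ordered collection of trials plus block-level metadata."""

    trials: list[SimTrial]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[SimTrial]:
        return iter(self.trials)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return TrialDataset(self.trials[idx], dict(self.meta))
        return self.trials[idx]

    def by_ratio(self) -> dict[float, list[SimTrial]]:
        groups: dict[float, list[SimTrial]] = {}
        for trial in self.trials:
            groups.setdefault(round(trial.ratio, 6), []).append(trial)
        return dict(sorted(groups.items()))

    def to_frame(self) -> pd.DataFrame:
        """Long table of samples: trial_id, t_ms, x_cm, depth_cm."""
        parts = []
        for trial in self.trials:
            n = len(trial.x_cm)
            depth = trial.depth_cm if trial.depth_cm is not None else np.full(n, np.nan)
            parts.append(
                pd.DataFrame(
                    {
                        "trial_id": np.full(n, trial.trial_id, dtype=int),
                        "t_ms": trial.t_ms,
                        "x_cm": trial.x_cm,
                        "depth_cm": depth,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["trial_id", "t_ms", "x_cm", "depth_cm"])
        return pd.concat(parts, ignore_index=True)

    def sidecar(self) -> dict:
        """Per-trial metadata keyed by trial id (JSON-serializable)."""
        out = {}
        for trial in self.trials:
            out[str(trial.trial_id)] = {
                "ratio": trial.ratio,
                "n_left": trial.n_left,
                "n_right": trial.n_right,
                "tf_s": trial.tf_s,
                "correct_side": trial.correct_side,
                "choice": trial.choice,
                "correct": trial.correct,
                "rt_ms": trial.rt_ms,
                "responded": trial.responded,
                "com_count": trial.com_count,
                **{k: v for k, v in trial.meta.items() if _jsonable(v)},
            }
        return out


def _jsonable(value) -> bool:
    return isinstance(value, (bool, int, float, str, type(None)))
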