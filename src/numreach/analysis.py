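"""Reach-trajectory preprocessing and behavioural measures.

Mirrors the preprocessing applied to the motion-capture data of the
comparison task: trajectories are time-normalized to 101 points, a trial
counts as correct when at least 50% of points *and* the endpoint lie on
the appropriate side of the screen midline, left and right reaches are
averaged after sign-flipping the left ones, positions are evaluated up to
99% of the depth travel (the recording stopped short of the screen), and
pull-back trials are excluded.  Changes of mind are excursions of at
least 1 cm into the half-plane opposite the endpoint side; RT is the time
to accumulate 0.28 mm of path length plus a non-decision time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trials import SimTrial, TrialDataset

__all__ = [
    "NormalizedTrajectory",
    "RatioSummary",
    "normalize_time",
    "normalize_trial",
    "classify_correct",
    "flip_and_average",
    "summary_table",
    "compute_rt",
    "detect_changes_of_mind",
    "heading_angle",
    "exclude_pullbacks",
]

#: Points in a time-normalized trajectory (both endpoints included).
N_POINTS = 101


@dataclass
class NormalizedTrajectory:
    """A 101-point time-normalized horizontal trajectory with annotations."""

    horizontal: np.ndarray
    side: str
    correct: bool | None
    rt_ms: float | None
    com_count: int
    com_directions: list

    def __post_init__(self) -> None:
        if len(self.horizontal) != N_POINTS:
            raise ValueError(f"normalized trajectories have {N_POINTS} points")


@dataclass
class RatioSummary:
    """Per-ratio behavioural summary.

    ``hp`` is the mean horizontal position: the average of the 101 points
    of the mean (flipped) trajectory — a scalar reach-curvature index.
    """

    ratio: float
    mean_trajectory: np.ndarray
    hp: float
    accuracy: float
    mean_rt_ms: float
    com_rate: float
    n_trials: int


def normalize_time(t, x, n_points: int = N_POINTS) -> np.ndarray:
    """Linearly interpolate a (t, x) series onto equally spaced times.

    The grid spans [t_first, t_last]; at least two strictly increasing
    samples are required.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    grid = np.linspace(t[0], t[-1], n_points)
    return np.interp(grid, t, x)


def _truncate_by_depth(t, x, depth, frac: float):
    """Drop samples after the depth travel reaches ``frac`` of its final value.

    Emulates the recording gap near the screen; applied before time
    normalization.  No-op when depth is absent or never reaches the cut.
    """
    if depth is None or frac is None:
        return t, x
    total = depth[-1]
    if total <= 0:
        return t, x
    past = np.flatnonzero(depth >= frac * total)
    if past.size == 0 or past[0] < 2:
        return t, x
    stop = past[0] + 1
    return t[:stop], x[:stop]


def normalize_trial(
    trial: SimTrial,
    n_points: int = N_POINTS,
    truncate_frac: float | None = 0.99,
) -> NormalizedTrajectory:
    """Time-normalize one trial's horizontal trajectory."""
    t = trial.t_ms
    x = trial.x_cm
    t, x = _truncate_by_depth(t, x, trial.depth_cm, truncate_frac)
    horiz = normalize_time(t, x, n_points)
    correct = (
        None
        if trial.correct_side is None
        else classify_correct(horiz, trial.correct_side)
    )
    return NormalizedTrajectory(
        horizontal=horiz,
        side=trial.endpoint_side,
        correct=correct,
        rt_ms=trial.rt_ms,
        com_count=trial.com_count,
        com_directions=list(trial.com_directions),
    )


def classify_correct(horizontal, correct_side: str) -> bool:
    """Correct-trial rule: >= 50% of points AND the endpoint on the correct side.

    The midline is x = 0 (screen-centred coordinates); points exactly on
    the midline do not count toward the correct side.
    """
    if correct_side not in ("left", "right"):
        raise ValueError(f"correct_side must be 'left' or 'right', got {correct_side!r}")
    x = np.asarray(horizontal, dtype=float)
    sign = 1.0 if correct_side == "right" else -1.0
    on_side = sign * x > 0
    return bool(on_side[-1] and on_side.mean() >= 0.5)


def flip_and_average(
    dataset,
    n_points: int = N_POINTS,
    include_incorrect: bool = False,
    truncate_frac: float | None = 0.99,
    drop_nonresponsive: bool = True,
) -> dict[float, RatioSummary]:
    """Per-ratio mean trajectories and behavioural summaries.

    Left-target trials are sign-flipped so the correct target is positive,
    then averaged pointwise over the (by default correct-only) trials.
    Accuracy and the change-of-mind rate are computed over all responsive
    trials of the ratio; an empty group yields a summary with ``n_trials =
    0`` and NaN measures, with a warning.
    """
    groups = (
        dataset.by_ratio() if isinstance(dataset, TrialDataset) else _group_trials(dataset)
    )
    out: dict[float, RatioSummary] = {}
    for ratio, trials in groups.items():
        if drop_nonresponsive:
            trials = [t for t in trials if t.responded]
        normed = [normalize_trial(t, n_points, truncate_frac) for t in trials]
        graded = [nt for nt in normed if nt.correct is not None]
        accuracy = float(np.mean([nt.correct for nt in graded])) if graded else np.nan
        kept = [
            (t, nt)
            for t, nt in zip(trials, normed)
            if include_incorrect or nt.correct is None or nt.correct
        ]
        if not kept:
            warnings.warn(f"no analyzable trials at ratio {ratio}", RuntimeWarning,
                          stacklevel=2)
            out[ratio] = RatioSummary(ratio, np.full(n_points, np.nan), np.nan,
                                      accuracy, np.nan, np.nan, 0)
            continue
        flipped = []
        for t, nt in kept:
            side = t.correct_side if t.correct_side is not None else t.endpoint_side
            flip = -1.0 if side == "left" else 1.0
            flipped.append(flip * nt.horizontal)
        mean_traj = np.mean(flipped, axis=0)
        rts = [t.rt_ms for t in trials if t.rt_ms is not None]
        out[ratio] = RatioSummary(
            ratio=ratio,
            mean_trajectory=mean_traj,
            hp=float(mean_traj.mean()),
            accuracy=accuracy,
            mean_rt_ms=float(np.mean(rts)) if rts else np.nan,
            com_rate=float(np.mean([t.com_count > 0 for t in trials])),
            n_trials=len(kept),
        )
    return out


def _group_trials(trials) -> dict[float, list[SimTrial]]:
    groups: dict[float, list[SimTrial]] = {}
    for t in trials:
        groups.setdefault(round(t.ratio, 6), []).append(t)
    return dict(sorted(groups.items()))


def summary_table(summaries: dict[float, RatioSummary]) -> pd.DataFrame:
    """Flat per-ratio summary table (ratio, hp_cm, accuracy, mean_rt_ms, com_rate)."""
    return pd.DataFrame.from_records(
        [
            {
                "ratio": s.ratio,
                "hp_cm": s.hp,
                "accuracy": s.accuracy,
                "mean_rt_ms": s.mean_rt_ms,
                "com_rate": s.com_rate,
                "n_trials": s.n_trials,
            }
            for s in summaries.values()
        ]
    )


def compute_rt(
    x,
    depth,
    dt: float,
    displacement_threshold_mm: float = 0.28,
    ndt_ms: float = 300.0,
) -> float | None:
    """RT = time for 0.28 mm of cumulative path length, plus non-decision time.

    Returns ``None`` (undefined RT) for an effector that never travels that
    far — such trials are flagged rather than given an RT.
    """
    x = np.asarray(x, dtype=float)
    if depth is None:
        depth = np.zeros_like(x)
    seg = np.hypot(np.diff(x), np.diff(np.asarray(depth, dtype=float)))
    dist = np.cumsum(seg)
    thr_cm = displacement_threshold_mm / 10.0
    hits = np.flatnonzero(dist >= thr_cm)
    if hits.size == 0:
        return None
    return float((hits[0] + 1) * dt * 1000.0 + ndt_ms)


def detect_changes_of_mind(
    x,
    penetration_cm: float = 1.0,
    endpoint_is_correct: bool | None = None,
) -> tuple[int, list]:
    """Count change-of-mind excursions in a horizontal trajectory.

    An event is a maximal excursion into the half-plane opposite the
    endpoint side that penetrates at least ``penetration_cm`` beyond the
    midline before returning.  Each event is labelled from the endpoint's
    correctness: returning to a correct endpoint is an incorrect->correct
    change (the majority case), to an incorrect endpoint correct->incorrect.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0, []
    end_sign = np.sign(x[-1])
    if end_sign == 0:
        return 0, []
    opp = end_sign * x < 0
    if not opp.any():
        return 0, []
    # maximal runs of samples on the opposite side
    edges = np.diff(opp.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if opp[0]:
        starts = np.concatenate([[0], starts])
    if opp[-1]:  # cannot happen (endpoint is on the endpoint side) but be safe
        ends = np.concatenate([ends, [x.size]])
    count = 0
    for a, b in zip(starts, ends):
        if np.max(np.abs(x[a:b])) >= penetration_cm:
            count += 1
    if endpoint_is_correct is None:
        label = "toward_endpoint"
    elif endpoint_is_correct:
        label = "incorrect_to_correct"
    else:
        label = "correct_to_incorrect"
    return count, [label] * count


def heading_angle(x, depth, dt: float, toward_side: str | None = None) -> float:
    """Heading angle (degrees) at the time of peak speed.

    The angle between the displacement vector from the start position and
    the depth axis, signed positive toward the chosen (endpoint) side:
    straight-ahead motion is 0 deg, purely lateral motion toward the chosen
    side +90 deg.  Undefined (NaN) if the effector has not moved at peak
    speed.
    """
    x = np.asarray(x, dtype=float)
    depth = (
        np.zeros_like(x) if depth is None else np.asarray(depth, dtype=float)
    )
    vx = np.diff(x) / dt
    vd = np.diff(depth) / dt
    speed = np.hypot(vx, vd)
    if speed.size == 0 or np.all(speed == 0):
        return float("nan")
    i = int(np.argmax(speed)) + 1
    if toward_side is None:
        end = x[-1]
        side_sign = -1.0 if end < 0 else 1.0
    else:
        side_sign = -1.0 if toward_side == "left" else 1.0
    disp_h = (x[i] - x[0]) * side_sign
    disp_d = depth[i] - depth[0]
    if disp_h == 0 and disp_d == 0:
        return float("nan")
    return float(np.degrees(np.arctan2(disp_h, disp_d)))


def exclude_pullbacks(
    dataset: TrialDataset,
    vel_threshold_cm_s: float = 0.5,
    sustain_ms: float = 10.0,
) -> tuple[TrialDataset, float]:
    """Remove trials whose depth velocity reverses mid-flight.

    A pull-back is a sustained (>= ``sustain_ms``) stretch of depth
    velocity below ``-vel_threshold_cm_s``, i.e. the finger retreating from
    the screen.  Returns the filtered dataset and the dropout fraction.
    """
    kept = []
    dropped = 0
    for trial in dataset:
        if trial.depth_cm is None:
            kept.append(trial)
            continue
        v = np.diff(trial.depth_cm) / trial.dt
        pull = v < -vel_threshold_cm_s
        need = max(int(round(sustain_ms / 1000.0 / trial.dt)), 1)
        if _longest_run(pull) >= need:
            dropped += 1
        else:
            kept.append(trial)
    total = len(dataset)
    rate = dropped / total if total else 0.0
    meta = dict(dataset.meta)
    meta["pullback_dropout"] = rate
    return TrialDataset(kept, meta), rate


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(np.int8), [0]])
    edges = np.diff(padded)
    return int(np.max(np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)))
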