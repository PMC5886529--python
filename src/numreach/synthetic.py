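"""Human-like synthetic trajectory datasets with known ground truth.

The generator emulates the structure of the comparison-task data — 5
ratios {0.1, 0.25, 0.5, 0.75, 0.9} (optionally plus equal-count trials),
420 trials per subject, 22 subjects, counterbalanced sides, per-ratio
movement-time distributions, error rates following the erfc psychometric
function at a known Weber fraction, occasional change-of-mind excursions
and pull-back dropouts — so every analysis and fitting stage can be tested
without any recorded data.

Paths are deliberately generator-side constructs (piecewise minimum-jerk
segments plus small smooth positional noise), *not* runs of the model:
analysis tests against this module are therefore independent of simulator
correctness.  Every injected latent (true side, correctness, injected
events) is recorded in the trial metadata sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import analysis
from .controller import minjerk_closed_form
from .evidence import predicted_error_rate, sample_pair
from .trials import SimTrial, TrialDataset

__all__ = ["SyntheticDesign", "tf_sampler", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of a synthetic dataset.

    Rates are per-trial probabilities; ``pullback_rate`` defaults to the
    7.66% dropout observed in the recorded sample and ``com_rate`` to the
    ~3% change-of-mind incidence.  ``dt`` defaults to 5 ms (a 200 Hz
    motion-capture grid).
    """

    ratios: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
    trials_per_subject: int = 420
    n_subjects: int = 22
    omega_true: float = 0.17
    com_rate: float = 0.03
    pullback_rate: float = 0.0766
    noise_sd_cm: float = 0.05
    dt: float = 0.005
    target_cm: float = 10.0
    start_depth_cm: float = 29.0
    ndt_ms: float = 300.0
    tf_mean_base_s: float = 0.55
    tf_mean_slope_s: float = 0.10
    tf_cv: float = 0.10
    pair_mode: str = "sampled"
    max_count: int = 25

    def __post_init__(self) -> None:
        if self.trials_per_subject % len(self.ratios) != 0:
            raise ValueError("trials_per_subject must be divisible by the number of ratios")
        for name in ("com_rate", "pullback_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.omega_true > 0:
            raise ValueError("omega_true must be > 0")


def tf_sampler(ratio: float, design: SyntheticDesign, rng: np.random.Generator) -> float:
    """Movement time for one trial: lognormal, slower for harder ratios.

    The per-ratio mean rises linearly with ratio from ~0.56 s to ~0.65 s
    (reaches of roughly 600 ms on average); coefficient of variation
    ``tf_cv``.  A zero CV gives a constant movement time.
    """
    mean = design.tf_mean_base_s + design.tf_mean_slope_s * ratio
    sd = design.tf_cv * mean
    if sd == 0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return max(float(rng.lognormal(mu, math.sqrt(sigma2))), 0.15)


def _segment_path(t: np.ndarray, segments: list[tuple[float, float, float, float]]):
    """Piecewise minimum-jerk path through (t0, t1, x0, x1) rest-to-rest segments."""
    x = np.empty_like(t)
    for t0, t1, x0, x1 in segments:
        sel = (t >= t0) & (t <= t1)
        x[sel] = x0 + minjerk_closed_form(x1 - x0, t1 - t0, t[sel] - t0)
    return x


def _smooth_noise(n: int, sd: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    window = max(int(round(0.05 / dt)), 1)
    raw = rng.normal(0.0, sd, n + window - 1)
    kernel = np.ones(window) / window
    return np.convolve(raw, kernel, mode="valid")


def _one_trial(
    trial_id: int,
    subject: int,
    ratio: float,
    larger_side: str,
    design: SyntheticDesign,
    rng: np.random.Generator,
) -> SimTrial:
    pair = sample_pair(ratio, rng, larger_side=larger_side,
                       max_count=design.max_count, mode=design.pair_mode)
    tf = tf_sampler(ratio, design, rng)
    steps = max(int(round(tf / design.dt)), 2)
    t = np.arange(steps + 1) * design.dt
    tf_eff = t[-1]

    correct_side = pair.correct_side
    if correct_side is None:
        chosen = "left" if rng.random() < 0.5 else "right"
        is_correct = None
    else:
        err = predicted_error_rate(pair, design.omega_true)
        is_correct = bool(rng.random() >= err)
        chosen = correct_side if is_correct else ("left" if correct_side == "right" else "right")
    target = design.target_cm if chosen == "right" else -design.target_cm

    inject_com = rng.random() < design.com_rate
    if inject_com:
        # a brief early excursion: deep enough to count (>= 1 cm past the
        # midline) but quick enough that the trial still satisfies the
        # 50%-of-points correctness rule
        exc = rng.uniform(1.2, 2.0) * (-np.sign(target))
        t_turn = rng.uniform(0.15, 0.25) * tf_eff
        segments = [(0.0, t_turn, 0.0, exc), (t_turn, tf_eff, exc, target)]
    else:
        segments = [(0.0, tf_eff, 0.0, target)]
    x = _segment_path(t, segments)

    inject_pull = rng.random() < design.pullback_rate
    d_goal = design.start_depth_cm
    if inject_pull:
        back = rng.uniform(2.0, 3.0)
        d1, t1 = 0.60 * d_goal, 0.55 * tf_eff
        t2 = 0.70 * tf_eff
        depth = _segment_path(
            t, [(0.0, t1, 0.0, d1), (t1, t2, d1, d1 - back), (t2, tf_eff, d1 - back, d_goal)]
        )
    else:
        depth = _segment_path(t, [(0.0, tf_eff, 0.0, d_goal)])

    # small smooth positional noise, enveloped by depth progress so the
    # start of the path stays pinned at the midline
    x = x + _smooth_noise(len(x), design.noise_sd_cm, design.dt, rng) * (depth / d_goal)

    rt = analysis.compute_rt(x, depth, design.dt, ndt_ms=design.ndt_ms)
    endpoint_correct = None if is_correct is None else (chosen == correct_side)
    com_count, com_dirs = analysis.detect_changes_of_mind(
        x, endpoint_is_correct=endpoint_correct
    )
    return SimTrial(
        trial_id=trial_id,
        n_left=pair.n_left,
        n_right=pair.n_right,
        ratio=pair.ratio,
        correct_side=correct_side,
        tf_s=tf_eff,
        dt=design.dt,
        x_cm=x,
        depth_cm=depth,
        choice=chosen,
        correct=is_correct,
        rt_ms=rt,
        responded=rt is not None,
        com_count=com_count,
        com_directions=com_dirs,
        meta={
            "synthetic": True,
            "subject": subject,
            "injected_correct": is_correct,
            "injected_com": inject_com,
            "injected_pullback": inject_pull,
        },
    )


def generate_dataset(design: SyntheticDesign | None = None, seed: int = 0) -> TrialDataset:
    """Generate a full synthetic dataset with a ground-truth sidecar.

    Trials are balanced over ratios within subject with counterbalanced
    correct side; each trial draws from its own child stream of ``seed``.
    The latent truths (injected correctness, change-of-mind and pull-back
    events) live in each trial's ``meta``.
    """
    design = design or SyntheticDesign()
    per_ratio = design.trials_per_subject // len(design.ratios)
    n_trials = design.n_subjects * design.trials_per_subject
    children = np.random.SeedSequence(seed).spawn(n_trials)
    trials = []
    i = 0
    for subject in range(design.n_subjects):
        for ratio in design.ratios:
            for j in range(per_ratio):
                rng = np.random.default_rng(children[i])
                side = "left" if j % 2 == 0 else "right"
                trials.append(_one_trial(i, subject, ratio, side, design, rng))
                i += 1
    meta = {"synthetic": True, "seed": seed, "design": design}
    return TrialDataset(trials, meta)
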