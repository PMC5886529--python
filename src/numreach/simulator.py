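"""Full-trial simulation: threshold-free model, its accumulation-gated
extension, and the traditional collapsing-bound accumulator.

A threshold-free trial proceeds on a 1 ms movement clock.  Every ``R`` ms a
Weber-noised evidence sample arrives, is EMA-filtered with decay ``D``, and
updates the flat-prior posterior over the numerical difference (acuity
``W``).  Heading goes to the side with the larger posterior probability,
and the minimum-jerk feedback update toward that side's target is scaled
by the entropy-based certainty (or certainty ** depth-distance in the
satisficing variant).  Before the first sample arrives certainty is zero
and the effector holds still while the movement clock runs.  The stimulus
is only visible briefly (200 ms), but sampling continues from the internal
(memory) representation for the whole flight.

The gated extension sums EMA samples and withholds motor updates until the
running sum clears a +-threshold; inference then uses pre- and
post-threshold samples alike.  A zero threshold reduces exactly to the
threshold-free model.

The traditional model accumulates per-tick Gaussian samples (drift set by
the numerical ratio, variance ``sig2``) to a collapsing bound
``thr / (1 + t)^k``; only after the crossing does the effector move, with
certainty read off the two-hypothesis correct/incorrect posterior.

Internally, whole blocks of trials are integrated simultaneously with
NumPy; per-trial randomness comes from independent child streams of one
seed sequence so each trial is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal, special

from . import analysis
from .controller import ControllerConfig, min_jerk_jerk
from .evidence import StimulusPair, sample_evidence, sample_pair
from .inference import certainty_of
from .trials import SimTrial, TrialDataset

__all__ = [
    "ModelParams",
    "DDMParams",
    "BlockDesign",
    "simulate_trial",
    "simulate_trial_thresholded",
    "simulate_block",
    "drift_for_ratio",
    "collapsing_threshold",
    "simulate_ddm_trial",
    "simulate_ddm_block",
    "threshold_sweep",
]


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the threshold-free model.

    r_ms:
        Evidence sampling interval, ms, in [1, 100].
    d:
        EMA memory decay in [0, 1]; 1 = memory-free, ~0 = primacy.
    w:
        Likelihood noise (acuity) of the Bayesian estimate, variance units.
    omega:
        Weber fraction of the numerosity representation.
    ndt_ms:
        Non-decision time added to RTs, ms, in [200, 500].
    threshold:
        Optional accumulation gate on the summed EMA stream, numerical-
        difference units; 0 (default) is the threshold-free model.
    satisficing:
        If set, the motor weight is certainty ** distance-to-screen, which
        releases the certainty brake as the reach nears the screen.
    satisficing_distance:
        How the normalized distance (1 at the start button, 0 at screen
        arrival) is tracked: 'time' (default) uses the remaining fraction
        of the movement, i.e. the depth schedule of an unimpeded reach,
        which guarantees the brake is fully released by arrival; 'depth'
        reads the simulated (certainty-gated) depth coordinate itself,
        under which a maximally uncertain reach can stall short of the
        screen.
    """

    r_ms: float = 30.0
    d: float = 1.0
    w: float = 16.0
    omega: float = 0.17
    ndt_ms: float = 300.0
    threshold: float = 0.0
    satisficing: bool = False
    satisficing_distance: str = "time"

    def __post_init__(self) -> None:
        if not 1.0 <= self.r_ms <= 100.0:
            raise ValueError(f"R must be in [1, 100] ms, got {self.r_ms}")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"D must be in [0, 1], got {self.d}")
        if not self.w > 0:
            raise ValueError(f"W must be > 0, got {self.w}")
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if not 200.0 <= self.ndt_ms <= 500.0:
            raise ValueError(f"ndt must be in [200, 500] ms, got {self.ndt_ms}")
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")
        if self.satisficing_distance not in ("time", "depth"):
            raise ValueError(
                f"satisficing_distance must be 'time' or 'depth', "
                f"got {self.satisficing_distance!r}"
            )


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the traditional collapsing-bound accumulator.

    ``thr`` (bound), ``dft`` (drift scale entering the ratio-to-drift map),
    ``sig2`` (per-sample variance), ``ndt_s`` (non-decision time, s) and
    ``k`` (bound collapse rate) follow the usual five-parameter scheme.
    ``second_thr`` and ``deadline_ms`` switch on the post-lift-off
    change-of-mind mechanism: an opposing crossing of the second bound
    flips the target, and at the deadline accumulation stops with the
    target locked to the side of the larger posterior.  ``time_unit``
    selects the units of t in the collapse law (seconds by default; with
    the published collapse rates a per-ms unit flattens the bound within a
    few ticks).
    """

    thr: float = 0.62
    dft: float = 0.28
    sig2: float = 0.14
    ndt_s: float = 0.19
    k: float = 3.56
    second_thr: float | None = None
    deadline_ms: float | None = None
    time_unit: str = "s"
    max_decision_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.thr > 0:
            raise ValueError(f"thr must be > 0, got {self.thr}")
        if not self.sig2 > 0:
            raise ValueError(f"sig2 must be > 0, got {self.sig2}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.time_unit not in ("s", "ms"):
            raise ValueError(f"time_unit must be 's' or 'ms', got {self.time_unit!r}")


@dataclass(frozen=True)
class BlockDesign:
    """Experiment design for a simulated block.

    Defaults emulate the comparison task: ratios {0.1, 0.25, 0.5, 0.75,
    0.9}, counterbalanced correct side, dot counts capped at 25, and
    per-ratio lognormal movement-time distributions with means rising from
    ~0.56 s (easy) to ~0.64 s (hard) — reaches of roughly 600 ms on
    average, slower for harder comparisons.
    """

    ratios: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
    trials_per_ratio: int = 480
    pair_mode: str = "sampled"
    max_count: int = 25
    dt: float = 0.001
    tf_mean_base_s: float = 0.55
    tf_mean_slope_s: float = 0.10
    tf_cv: float = 0.10
    tf_min_s: float = 0.15
    tf_sampler: Callable[[float, np.random.Generator], float] | None = None
    controller: ControllerConfig = field(default_factory=ControllerConfig)

    def tf_mean(self, ratio: float) -> float:
        return self.tf_mean_base_s + self.tf_mean_slope_s * ratio

    def sample_tf(self, ratio: float, rng: np.random.Generator) -> float:
        """Movement time for one trial, drawn fresh at trial start."""
        if self.tf_sampler is not None:
            tf = float(self.tf_sampler(ratio, rng))
        else:
            mean = self.tf_mean(ratio)
            sd = self.tf_cv * mean
            if sd == 0:
                tf = mean
            else:
                sigma2 = math.log(1.0 + (sd / mean) ** 2)
                mu = math.log(mean) - sigma2 / 2.0
                tf = float(rng.lognormal(mu, math.sqrt(sigma2)))
        return max(tf, self.tf_min_s)


# ---------------------------------------------------------------------------
# threshold-free model
# ---------------------------------------------------------------------------


def _batch_beliefs(E: np.ndarray, n_samp: np.ndarray, params: ModelParams):
    """EMA, running posterior and certainty for a padded evidence matrix."""
    n, S = E.shape
    if S == 0:
        z = np.zeros((n, 0))
        return z, z, z, z, np.zeros(n, dtype=int)
    mask = np.arange(S)[None, :] < n_samp[:, None]
    d = params.d
    zi = (1.0 - d) * E[:, :1]
    ema, _ = signal.lfilter([d], [1.0, -(1.0 - d)], E, axis=1, zi=zi)
    ema = np.where(mask, ema, 0.0)
    counts = np.arange(1, S + 1, dtype=float)
    means = np.cumsum(ema, axis=1) / counts[None, :]
    p = special.ndtr(means * np.sqrt(counts[None, :] / params.w))
    cert = certainty_of(p)
    # accumulation gate: number of samples needed for |sum of EMA| >= threshold
    if params.threshold > 0:
        csum = np.abs(np.cumsum(ema, axis=1))
        ok = csum >= params.threshold - 1e-12
        reached = ok.any(axis=1)
        first = np.argmax(ok, axis=1)
        gate_need = np.where(reached, first + 1, S + 1)
    else:
        gate_need = np.ones(n, dtype=int)
    return ema, means, p, cert, gate_need


def _simulate_batch(
    params: ModelParams,
    E: np.ndarray,
    n_samp: np.ndarray,
    tf_s: np.ndarray,
    cfg: ControllerConfig,
):
    """Integrate a batch of trials simultaneously (positive = correct frame).

    Returns per-trial frame trajectories, depth, belief series, gate info,
    and the per-trial step counts.
    """
    n = len(tf_s)
    dt = cfg.dt
    dt_ms = dt * 1000.0
    steps = np.rint(tf_s / dt).astype(int)
    steps = np.maximum(steps, 1)
    K = int(steps.max())
    ema, means, p, cert, gate_need = _batch_beliefs(E, n_samp, params)
    head = np.where(p >= 0.5, 1.0, -1.0)

    satisficing = params.satisficing or cfg.weight_mode == "satisficing"
    unweighted = cfg.weight_mode == "unweighted"
    x_f = abs(cfg.target_horizontal)
    depth_goal = cfg.start_depth
    rows = np.arange(n)

    ph = np.zeros(n); vh = np.zeros(n); ah = np.zeros(n)
    pd_ = np.zeros(n); vd = np.zeros(n); ad = np.zeros(n)
    X = np.zeros((n, K + 1))
    DEP = np.zeros((n, K + 1))
    S = E.shape[1]
    for k in range(K):
        t_ms = k * dt_ms
        m = int((t_ms + 1e-9) // params.r_ms)
        if m == 0:
            # no evidence yet anywhere: effector holds still, clock runs
            continue
        idx = min(m, S) - 1
        active = (k < steps).astype(float)
        cert_k = cert[:, idx]
        opened = (gate_need <= m).astype(float)
        if unweighted:
            w_base = opened
        else:
            w_base = cert_k * opened
        if satisficing:
            if params.satisficing_distance == "time":
                dist = np.clip(1.0 - (k * dt) / tf_s, 0.0, 1.0)
            else:
                dist = np.clip(1.0 - pd_ / depth_goal, 0.0, 1.0)
            w_base = np.power(w_base, dist)
        wdt = w_base * active * dt
        tgt = head[:, idx] * x_f
        delta = np.maximum(tf_s - k * dt, cfg.delta_min)
        jh = min_jerk_jerk(ph, vh, ah, tgt, delta)
        jd = min_jerk_jerk(pd_, vd, ad, depth_goal, delta)
        ph = ph + wdt * vh
        vh = vh + wdt * ah
        ah = ah + wdt * jh
        pd_ = pd_ + wdt * vd
        vd = vd + wdt * ad
        ad = ad + wdt * jd
        X[:, k + 1] = ph
        DEP[:, k + 1] = pd_
    # columns past a trial's own end were written with its frozen state, so
    # forward-fill them to hold the endpoint
    if np.any(steps < K):
        col = np.minimum(np.arange(K + 1)[None, :], steps[:, None])
        X = X[rows[:, None], col]
        DEP = DEP[rows[:, None], col]
    return {
        "X": X,
        "DEP": DEP,
        "steps": steps,
        "ema": ema,
        "means": means,
        "p": p,
        "cert": cert,
        "gate_need": gate_need,
    }


def _rt_from_paths(X, DEP, steps, dt_ms, ndt_ms, threshold_mm=0.28):
    """Vectorized RT: first tick the cumulative path length reaches 0.28 mm."""
    seg = np.hypot(np.diff(X, axis=1), np.diff(DEP, axis=1))
    dist = np.cumsum(seg, axis=1)
    thr_cm = threshold_mm / 10.0
    hit = dist >= thr_cm
    any_hit = hit.any(axis=1)
    first = np.argmax(hit, axis=1)
    rt = np.where(any_hit, (first + 1) * dt_ms + ndt_ms, np.nan)
    return rt, any_hit


def _assemble_trials(
    params: ModelParams,
    pairs: Sequence[StimulusPair],
    tf_s: np.ndarray,
    E: np.ndarray,
    n_samp: np.ndarray,
    out: dict,
    cfg: ControllerConfig,
    trial_ids: Sequence[int],
    detect_com: bool = True,
) -> list[SimTrial]:
    dt = cfg.dt
    dt_ms = dt * 1000.0
    rt, responded_rt = _rt_from_paths(out["X"], out["DEP"], out["steps"], dt_ms, params.ndt_ms)
    trials = []
    for i, pair in enumerate(pairs):
        steps_i = int(out["steps"][i])
        sign = pair.frame_sign
        x = sign * out["X"][i, : steps_i + 1]
        depth = out["DEP"][i, : steps_i + 1].copy()
        ns = int(n_samp[i])
        endpoint = out["X"][i, steps_i]
        gate_open = bool(out["gate_need"][i] <= ns)
        responded = bool(responded_rt[i]) and gate_open
        choice = "right" if sign * (endpoint if endpoint != 0 else 1.0) > 0 else "left"
        correct = None if pair.correct_side is None else bool(endpoint > 0)
        com_count, com_dirs = 0, []
        if detect_com:
            com_count, com_dirs = analysis.detect_changes_of_mind(
                x, endpoint_is_correct=correct
            )
        meta = {}
        if ns == 0:
            meta["no_evidence"] = True
        if not gate_open and params.threshold > 0:
            meta["gate_never_opened"] = True
        trial = SimTrial(
            trial_id=int(trial_ids[i]),
            n_left=pair.n_left,
            n_right=pair.n_right,
            ratio=pair.ratio,
            correct_side=pair.correct_side,
            tf_s=float(tf_s[i]),
            dt=dt,
            x_cm=x,
            depth_cm=depth,
            choice=choice,
            correct=correct,
            rt_ms=float(rt[i]) if responded else None,
            responded=responded,
            com_count=com_count,
            com_directions=com_dirs,
            sample_times_ms=params.r_ms * np.arange(1, ns + 1),
            raw=E[i, :ns].copy(),
            ema=out["ema"][i, :ns].copy(),
            p_correct=out["p"][i, :ns].copy(),
            certainty=out["cert"][i, :ns].copy(),
            meta=meta,
        )
        trials.append(trial)
    return trials


def simulate_trial(
    params: ModelParams,
    pair: StimulusPair,
    tf_s: float,
    dt: float = 0.001,
    rng: np.random.Generator | None = None,
    config: ControllerConfig | None = None,
) -> SimTrial:
    """Simulate a single threshold-free (or gated) trial.

    Evidence is drawn from ``rng``; the trajectory is returned in screen
    coordinates together with the evidence stream and belief series.  A
    movement shorter than one sampling interval yields a drift-less trial
    flagged ``no_evidence``.
    """
    if not tf_s > 0:
        raise ValueError(f"tf_s must be > 0, got {tf_s}")
    rng = np.random.default_rng() if rng is None else rng
    cfg = config or ControllerConfig()
    if dt != cfg.dt:
        cfg = replace(cfg, dt=dt, delta_min=max(dt, cfg.delta_min if cfg.delta_min >= dt else dt))
    ns = int(tf_s * 1000.0 // params.r_ms)
    raw = np.asarray(sample_evidence(pair, params.omega, rng, size=ns), dtype=float)
    E = raw[None, :] if ns else np.zeros((1, 0))
    n_samp = np.array([ns])
    tf = np.array([float(tf_s)])
    out = _simulate_batch(params, E, n_samp, tf, cfg)
    return _assemble_trials(params, [pair], tf, E, n_samp, out, cfg, [0])[0]


def simulate_trial_thresholded(
    params: ModelParams,
    pair: StimulusPair,
    tf_s: float,
    dt: float = 0.001,
    rng: np.random.Generator | None = None,
    config: ControllerConfig | None = None,
) -> SimTrial:
    """Gated variant: motor updates wait for the accumulation threshold.

    Requires ``params.threshold > 0``; with the gate at 0 the trajectory is
    identical to :func:`simulate_trial` under the same rng state.
    """
    if not params.threshold > 0:
        raise ValueError("simulate_trial_thresholded requires params.threshold > 0")
    return simulate_trial(params, pair, tf_s, dt=dt, rng=rng, config=config)


def simulate_block(
    params: ModelParams,
    design: BlockDesign | None = None,
    seed: int = 0,
    detect_com: bool = True,
) -> TrialDataset:
    """Simulate a full block: ratios x trials-per-ratio, counterbalanced sides.

    Each trial owns an independent child stream of ``seed`` (drawn in the
    order pair, movement time, evidence), so the block is bit-reproducible
    and individual trials can be regenerated in isolation.
    """
    design = design or BlockDesign()
    cfg = design.controller
    if cfg.dt != design.dt:
        cfg = replace(cfg, dt=design.dt, delta_min=max(design.dt, cfg.delta_min))
    n_trials = len(design.ratios) * design.trials_per_ratio
    children = np.random.SeedSequence(seed).spawn(n_trials)
    pairs: list[StimulusPair] = []
    tf_s = np.empty(n_trials)
    ev: list[np.ndarray] = []
    n_samp = np.empty(n_trials, dtype=int)
    i = 0
    for ratio in design.ratios:
        for j in range(design.trials_per_ratio):
            rng = np.random.default_rng(children[i])
            side = "left" if j % 2 == 0 else "right"
            pair = sample_pair(ratio, rng, larger_side=side,
                               max_count=design.max_count, mode=design.pair_mode)
            tf = design.sample_tf(ratio, rng)
            ns = int(tf * 1000.0 // params.r_ms)
            raw = np.asarray(sample_evidence(pair, params.omega, rng, size=ns), dtype=float)
            pairs.append(pair)
            tf_s[i] = tf
            ev.append(raw)
            n_samp[i] = ns
            i += 1
    S = int(n_samp.max()) if n_trials else 0
    E = np.zeros((n_trials, S))
    for i, raw in enumerate(ev):
        E[i, : len(raw)] = raw
    out = _simulate_batch(params, E, n_samp, tf_s, cfg)
    trials = _assemble_trials(
        params, pairs, tf_s, E, n_samp, out, cfg, range(n_trials), detect_com=detect_com
    )
    meta = {"model": "threshold-free" if params.threshold == 0 else "thresholded",
            "seed": seed, "params": params, "design": design}
    return TrialDataset(trials, meta)


# ---------------------------------------------------------------------------
# traditional collapsing-bound model
# ---------------------------------------------------------------------------


def drift_for_ratio(ratio: float, dft: float):
    """Map a numerical ratio to an accumulation drift.

    ``1 - erfc(|ratio - 1| / (sqrt(2) * dft * sqrt(ratio**2 + 1)))``: zero
    at ratio 1 (no signal) and approaching 1 for easy ratios / small drift
    scale.  Vectorized over ``ratio``.
    """
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0) or np.any(ratio > 1):
        raise ValueError("ratio must be in (0, 1]")
    if not dft > 0:
        raise ValueError(f"dft must be > 0, got {dft}")
    arg = np.abs(ratio - 1.0) / (math.sqrt(2.0) * dft * np.sqrt(ratio**2 + 1.0))
    out = 1.0 - special.erfc(arg)
    return float(out) if out.ndim == 0 else out


def collapsing_threshold(thr: float, k: float, t):
    """Collapsing decision bound ``thr / (1 + t)**k`` (t in the model's unit)."""
    if not thr > 0:
        raise ValueError(f"thr must be > 0, got {thr}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    t = np.asarray(t, dtype=float)
    out = thr / (1.0 + t) ** k
    return float(out) if out.ndim == 0 else out


def _simulate_ddm_batch(
    ddm: DDMParams,
    ratios: np.ndarray,
    tf_s: np.ndarray,
    rngs: Sequence[np.random.Generator],
    cfg: ControllerConfig,
    dt: float = 0.001,
):
    """Vectorized decision + movement phases of the traditional model."""
    n = len(ratios)
    drift = np.asarray(drift_for_ratio(ratios, ddm.dft), dtype=float)
    sd = math.sqrt(ddm.sig2)
    dt_ms = dt * 1000.0
    n_dec = int(round(ddm.max_decision_s / dt))
    steps = np.maximum(np.rint(tf_s / dt).astype(int), 1)
    K = int(steps.max())

    dec = np.empty((n, n_dec))
    mov = np.empty((n, K))
    for i, rng in enumerate(rngs):
        dec[i] = rng.normal(drift[i], sd, n_dec)
        mov[i] = rng.normal(drift[i], sd, K)

    csum = np.cumsum(dec, axis=1)
    t_axis = np.arange(1, n_dec + 1) * (dt if ddm.time_unit == "s" else dt_ms)
    bound = collapsing_threshold(ddm.thr, ddm.k, t_axis)
    hit = np.abs(csum) >= bound[None, :]
    responded = hit.any(axis=1)
    first = np.argmax(hit, axis=1)
    rows = np.arange(n)
    s_at_cross = csum[rows, first]
    choice0 = np.where(s_at_cross >= 0, 1.0, -1.0)
    decision_ms = np.where(responded, (first + 1) * dt_ms, np.nan)
    rt_ms = decision_ms + ddm.ndt_s * 1000.0

    # movement phase: sampling continues, certainty from the two-hypothesis
    # posterior, controller runs toward the currently chosen target
    tot = s_at_cross[:, None] + np.cumsum(mov, axis=1)
    deadline_steps = (
        int(round(ddm.deadline_ms / dt_ms)) if ddm.deadline_ms is not None else None
    )
    x_f = abs(cfg.target_horizontal)
    depth_goal = cfg.start_depth
    choice = choice0.copy()
    locked = np.zeros(n, dtype=bool)
    ph = np.zeros(n); vh = np.zeros(n); ah = np.zeros(n)
    pd_ = np.zeros(n); vd = np.zeros(n); ad = np.zeros(n)
    X = np.zeros((n, K + 1))
    DEP = np.zeros((n, K + 1))
    frozen_tot = tot[:, 0].copy()
    for k in range(K):
        if deadline_steps is not None and k >= deadline_steps:
            tot_k = frozen_tot
            if not locked.all():
                # lock the target to the higher-posterior side at the deadline
                choice = np.where(frozen_tot != 0, np.sign(frozen_tot), choice)
                locked[:] = True
        else:
            tot_k = tot[:, k]
            frozen_tot = tot_k
            if ddm.second_thr is not None:
                flip = (tot_k * choice < 0) & (np.abs(tot_k) >= ddm.second_thr)
                choice = np.where(flip, -choice, choice)
        p_corr = special.expit(2.0 * drift * tot_k / ddm.sig2)
        p_chosen = np.where(choice > 0, p_corr, 1.0 - p_corr)
        w = certainty_of(p_chosen)
        active = (k < steps) & responded
        wdt = w * active * dt
        tgt = choice * x_f
        delta = np.maximum(tf_s - k * dt, cfg.delta_min)
        jh = min_jerk_jerk(ph, vh, ah, tgt, delta)
        jd = min_jerk_jerk(pd_, vd, ad, depth_goal, delta)
        ph = ph + wdt * vh
        vh = vh + wdt * ah
        ah = ah + wdt * jh
        pd_ = pd_ + wdt * vd
        vd = vd + wdt * ad
        ad = ad + wdt * jd
        X[:, k + 1] = ph
        DEP[:, k + 1] = pd_
    if np.any(steps < K):
        col = np.minimum(np.arange(K + 1)[None, :], steps[:, None])
        X = X[rows[:, None], col]
        DEP = DEP[rows[:, None], col]
    return {
        "X": X,
        "DEP": DEP,
        "steps": steps,
        "responded": responded,
        "rt_ms": rt_ms,
        "decision_ms": decision_ms,
        "choice_sign": choice,
        "choice0_sign": choice0,
    }


def _assemble_ddm_trials(ddm, pairs, tf_s, out, cfg, trial_ids, detect_com=True):
    trials = []
    for i, pair in enumerate(pairs):
        steps_i = int(out["steps"][i])
        sign = pair.frame_sign
        x = sign * out["X"][i, : steps_i + 1]
        depth = out["DEP"][i, : steps_i + 1].copy()
        responded = bool(out["responded"][i])
        endpoint = out["X"][i, steps_i]
        choice = "right" if sign * (endpoint if endpoint != 0 else 1.0) > 0 else "left"
        correct = None if pair.correct_side is None else (bool(endpoint > 0) if responded else None)
        com_count, com_dirs = (0, [])
        if detect_com and responded:
            com_count, com_dirs = analysis.detect_changes_of_mind(
                x, endpoint_is_correct=correct
            )
        crossing = None
        if responded:
            c0 = out["choice0_sign"][i]
            crossing = "right" if sign * c0 > 0 else "left"
        meta = {"model": "ddm", "decision_ms": float(out["decision_ms"][i])
                if responded else None, "crossing_side": crossing}
        if not responded:
            meta["non_responsive"] = True
        trials.append(
            SimTrial(
                trial_id=int(trial_ids[i]),
                n_left=pair.n_left,
                n_right=pair.n_right,
                ratio=pair.ratio,
                correct_side=pair.correct_side,
                tf_s=float(tf_s[i]),
                dt=cfg.dt,
                x_cm=x,
                depth_cm=depth,
                choice=choice,
                correct=correct,
                rt_ms=float(out["rt_ms"][i]) if responded else None,
                responded=responded,
                com_count=com_count,
                com_directions=com_dirs,
                meta=meta,
            )
        )
    return trials


def simulate_ddm_trial(
    ddm: DDMParams,
    ratio: float,
    tf_s: float,
    dt: float = 0.001,
    rng: np.random.Generator | None = None,
    config: ControllerConfig | None = None,
    larger_side: str = "right",
) -> SimTrial:
    """One trial of the traditional collapsing-bound model.

    Accumulates per-tick samples to the collapsing bound, then moves for
    ``tf_s`` with certainty-weighted minimum-jerk updates toward the chosen
    target.  RT is the bound-crossing time plus non-decision time.  A trial
    that never crosses within the decision window is flagged non-responsive.
    """
    rng = np.random.default_rng() if rng is None else rng
    cfg = config or ControllerConfig()
    if dt != cfg.dt:
        cfg = replace(cfg, dt=dt, delta_min=max(dt, cfg.delta_min))
    pair = _pair_for_ddm(ratio, larger_side)
    out = _simulate_ddm_batch(
        ddm, np.array([ratio]), np.array([float(tf_s)]), [rng], cfg, dt=dt
    )
    return _assemble_ddm_trials(ddm, [pair], np.array([tf_s]), out, cfg, [0])[0]


def _pair_for_ddm(ratio: float, larger_side: str) -> StimulusPair:
    """Representative dot pair for bookkeeping (the DDM consumes only the ratio)."""
    from .evidence import pairs_for_ratio

    small, large = pairs_for_ratio(ratio)[-1]
    return (
        StimulusPair(large, small) if larger_side == "left" else StimulusPair(small, large)
    )


def simulate_ddm_block(
    ddm: DDMParams,
    design: BlockDesign | None = None,
    seed: int = 0,
    detect_com: bool = True,
) -> TrialDataset:
    """A full block of the traditional model (counterbalanced sides)."""
    design = design or BlockDesign()
    cfg = design.controller
    if cfg.dt != design.dt:
        cfg = replace(cfg, dt=design.dt, delta_min=max(design.dt, cfg.delta_min))
    n_trials = len(design.ratios) * design.trials_per_ratio
    children = np.random.SeedSequence(seed).spawn(n_trials)
    rngs = []
    pairs = []
    ratios = np.empty(n_trials)
    tf_s = np.empty(n_trials)
    i = 0
    for ratio in design.ratios:
        for j in range(design.trials_per_ratio):
            rng = np.random.default_rng(children[i])
            side = "left" if j % 2 == 0 else "right"
            pairs.append(_pair_for_ddm(ratio, side))
            ratios[i] = ratio
            tf_s[i] = design.sample_tf(ratio, rng)
            rngs.append(rng)
            i += 1
    out = _simulate_ddm_batch(ddm, ratios, tf_s, rngs, cfg, dt=design.dt)
    trials = _assemble_ddm_trials(ddm, pairs, tf_s, out, cfg, range(n_trials),
                                  detect_com=detect_com)
    return TrialDataset(trials, {"model": "ddm", "seed": seed, "params": ddm,
                                 "design": design})


# ---------------------------------------------------------------------------
# threshold sensitivity sweep
# ---------------------------------------------------------------------------


def threshold_sweep(
    params: ModelParams,
    design: BlockDesign | None = None,
    thresholds: Sequence[float] = (0.0, 0.27, 1.0, 3.0, 9.0, 27.0),
    seed: int = 0,
    mid_index: int = 50,
) -> pd.DataFrame:
    """Sweep the accumulation gate and measure the mid-flight ratio gradient.

    For each gate level the block is re-simulated with common random
    numbers and the across-ratio range of mean (flipped) horizontal
    positions at the mid-flight normalized time point is recorded.  Large
    gates withhold movement until certainty is high, so reaches become
    direct and the gradient flattens.
    """
    design = design or BlockDesign()
    records = []
    for thr in thresholds:
        p = replace(params, threshold=float(thr))
        data = simulate_block(p, design, seed=seed, detect_com=False)
        summaries = analysis.flip_and_average(data)
        mids = {r: s.mean_trajectory[mid_index] for r, s in summaries.items()
                if s.n_trials > 0}
        rng_mid = (max(mids.values()) - min(mids.values())) if len(mids) >= 2 else np.nan
        nonresp = np.mean([not t.responded for t in data])
        rec = {"threshold": float(thr), "range_mid_cm": rng_mid,
               "nonresponsive_rate": float(nonresp)}
        for r, v in mids.items():
            rec[f"mid_cm_ratio_{r:g}"] = v
        records.append(rec)
    return pd.DataFrame.from_records(records)
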