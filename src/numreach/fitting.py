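"""Global parameter search for both model families.

The objective is the one used to fit the reaching data: simulate a block
(480 trajectories per ratio by default), summarize it exactly as the data
are summarized, and score the sum of two mean squared errors — MSE of the
per-ratio mean horizontal positions (HP) and MSE of the per-ratio
accuracies.  The traditional accumulator is instead scored on accuracy
plus RT quantiles {0.1, 0.25, 0.5, 0.75, 0.9}.

Optimization uses scipy's DIRECT space-partitioning search (derivative-
free, deterministic, bounded); the objective's Monte Carlo noise is tamed
with common random numbers — every evaluation re-simulates with the same
seed — and the best point is re-scored on fresh seeds afterwards to report
an honest mean +/- SD loss.  The acuity ``W`` is searched in log space.
Non-decision time is not a search dimension for the threshold-free model;
it is set manually in the 200-500 ms range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from . import analysis
from .simulator import BlockDesign, DDMParams, ModelParams, simulate_block, simulate_ddm_block

__all__ = [
    "FitResult",
    "block_targets",
    "ddm_targets",
    "objective",
    "ddm_objective",
    "fit_threshold_free",
    "fit_ddm",
    "RT_QUANTILES",
]

RT_QUANTILES = (0.1, 0.25, 0.5, 0.75, 0.9)

#: Search boxes per free parameter.  W and D act multiplicatively on the
#: belief (W scales the posterior width, D the per-sample memory weight),
#: so both are searched in log10 space; R, omega and the gate are linear.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r_ms": (1.0, 100.0),
    "log10_d": (-2.5, 0.0),
    "log10_w": (-0.5, 2.0),
    "omega": (0.05, 1.0),
    "threshold": (0.0, 5.0),
}

#: Parameters searched on a log10 scale (mapped back before simulation).
_LOG_PARAMS = {"w": "log10_w", "d": "log10_d"}

DEFAULT_DDM_BOUNDS: dict[str, tuple[float, float]] = {
    "thr": (0.05, 3.0),
    "dft": (0.05, 1.5),
    "sig2": (0.01, 1.0),
    "k": (0.0, 8.0),
    "ndt_s": (0.1, 0.5),
}


@dataclass
class FitResult:
    """Outcome of a global search."""

    params: object
    loss: float
    n_evaluations: int
    seed: int
    converged: bool
    trace: list = field(default_factory=list)
    loss_mean: float | None = None
    loss_sd: float | None = None
    message: str = ""


def block_targets(dataset) -> dict[float, tuple[float, float]]:
    """Per-ratio (hp, accuracy) targets from a dataset's summaries."""
    summaries = analysis.flip_and_average(dataset)
    return {r: (s.hp, s.accuracy) for r, s in summaries.items()}


def ddm_targets(dataset, quantiles: Sequence[float] = RT_QUANTILES):
    """Per-ratio (accuracy, RT quantiles in s) targets for the accumulator fit."""
    out = {}
    for ratio, trials in dataset.by_ratio().items():
        graded = [t.correct for t in trials if t.correct is not None and t.responded]
        rts = np.array([t.rt_ms for t in trials if t.rt_ms is not None]) / 1000.0
        acc = float(np.mean(graded)) if graded else np.nan
        qs = np.quantile(rts, quantiles) if rts.size else np.full(len(quantiles), np.nan)
        out[ratio] = (acc, qs)
    return out


def _is_degenerate(targets: Mapping[float, tuple[float, float]]) -> bool:
    hps = np.array([v[0] for v in targets.values()])
    accs = np.array([v[1] for v in targets.values()])
    return bool(np.all(np.abs(accs - 0.5) < 1e-3) and np.all(np.abs(hps) < 1e-3))


def objective(
    params: ModelParams,
    targets: Mapping[float, tuple[float, float]],
    design: BlockDesign,
    seed: int = 0,
) -> float:
    """Composite loss MSE(hp) + MSE(accuracy) for one parameter point.

    Simulated with common random numbers (the given seed) so the loss is a
    deterministic function of (params, seed); any non-finite simulation
    summary yields an infinite, optimizer-safe loss.
    """
    data = simulate_block(params, design, seed=seed, detect_com=False)
    summaries = analysis.flip_and_average(data)
    errs_hp, errs_acc = [], []
    for ratio, (hp_t, acc_t) in targets.items():
        s = summaries.get(round(ratio, 6))
        if s is None or not np.isfinite(s.hp) or not np.isfinite(s.accuracy):
            return float("inf")
        errs_hp.append(s.hp - hp_t)
        errs_acc.append(s.accuracy - acc_t)
    return float(np.mean(np.square(errs_hp)) + np.mean(np.square(errs_acc)))


def ddm_objective(
    ddm: DDMParams,
    targets,
    design: BlockDesign,
    seed: int = 0,
    quantiles: Sequence[float] = RT_QUANTILES,
) -> float:
    """MSE over accuracies and RT quantiles for the traditional model."""
    data = simulate_ddm_block(ddm, design, seed=seed, detect_com=False)
    sim = ddm_targets(data, quantiles)
    errs = []
    for ratio, (acc_t, q_t) in targets.items():
        got = sim.get(round(ratio, 6))
        if got is None or not np.isfinite(got[0]) or not np.all(np.isfinite(got[1])):
            return float("inf")
        errs.append(got[0] - acc_t)
        errs.extend(np.asarray(got[1]) - np.asarray(q_t))
    return float(np.mean(np.square(errs)))


def _direct_search(func, bounds, budget, trace, polish_frac: float = 0.35):
    """DIRECT global stage plus a bounded Powell polish of the best point.

    The objective is deterministic under common random numbers, so the
    polish descends the same surface the partitioning explored; roughly
    ``polish_frac`` of the budget is reserved for it.
    """
    n_polish = max(int(budget * polish_frac), 30)
    res = optimize.direct(
        func,
        bounds=bounds,
        maxfun=budget,
        maxiter=max(budget, 1000),
        locally_biased=True,
    )
    polished = optimize.minimize(
        func,
        res.x,
        method="Powell",
        bounds=bounds,
        options={"maxfev": n_polish, "xtol": 1e-3, "ftol": 1e-4},
    )
    best = polished if polished.fun <= res.fun else res
    converged = res.status in (1, 2) or len(trace) <= budget + n_polish
    return best, converged


def fit_threshold_free(
    targets: Mapping[float, tuple[float, float]],
    design: BlockDesign | None = None,
    free: Sequence[str] = ("r_ms", "w", "d"),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    budget: int = 200,
    seed: int = 0,
    base_params: ModelParams | None = None,
    n_reval_seeds: int = 10,
) -> FitResult:
    """Global search over the threshold-free model's box.

    ``free`` selects the searched parameters among {r_ms, w, d, omega,
    threshold}; everything else stays at ``base_params``.  The search is
    deterministic given ``seed`` (common random numbers inside the
    objective, DIRECT partitioning outside).  Degenerate targets — chance
    accuracy and flat positions everywhere — are unidentifiable and are
    flagged rather than fitted silently.
    """
    if budget < 50:
        raise ValueError("budget must be >= 50 evaluations")
    design = design or BlockDesign()
    base = base_params or ModelParams()
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    degenerate = _is_degenerate(targets)
    if degenerate:
        warnings.warn("targets are degenerate (chance accuracy, flat positions); "
                      "the fit is unidentifiable", RuntimeWarning, stacklevel=2)

    names = list(free)
    lo_hi = []
    for name in names:
        key = _LOG_PARAMS.get(name, name)
        if name in _LOG_PARAMS and name in (bounds or {}):
            lo, hi = (bounds or {})[name]
            lo_hi.append((np.log10(max(lo, 1e-3)), np.log10(hi)))
        else:
            lo_hi.append(box[key])

    def to_params(x) -> ModelParams:
        updates = {}
        for name, val in zip(names, x):
            if name in _LOG_PARAMS:
                updates[name] = 10.0 ** float(val)
            else:
                updates[name] = float(val)
        return replace(base, **updates)

    trace: list[tuple[dict, float]] = []

    def func(x):
        params = to_params(x)
        loss = objective(params, targets, design, seed=seed)
        trace.append(({n: getattr(params, n) for n in
                       ("r_ms", "w", "d", "omega", "threshold")}, loss))
        return loss

    res, converged = _direct_search(func, lo_hi, budget, trace)
    best = to_params(res.x)
    reval = [objective(best, targets, design, seed=seed + 1000 + i)
             for i in range(n_reval_seeds)]
    return FitResult(
        params=best,
        loss=float(res.fun),
        n_evaluations=len(trace),
        seed=seed,
        converged=bool(converged and not degenerate),
        trace=trace,
        loss_mean=float(np.mean(reval)) if reval else None,
        loss_sd=float(np.std(reval)) if reval else None,
        message="unidentifiable targets" if degenerate else res.message,
    )


def fit_ddm(
    targets,
    design: BlockDesign | None = None,
    free: Sequence[str] = ("thr", "dft", "sig2", "k"),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    budget: int = 200,
    seed: int = 0,
    base_params: DDMParams | None = None,
    n_reval_seeds: int = 10,
    quantiles: Sequence[float] = RT_QUANTILES,
) -> FitResult:
    """Global search for the traditional accumulator on accuracy + RT quantiles.

    Any robust derivative-free method would do; the same DIRECT search is
    used for reproducibility.  Pinning ``k`` at 0 recovers the
    fixed-threshold special case.
    """
    if budget < 50:
        raise ValueError("budget must be >= 50 evaluations")
    design = design or BlockDesign()
    base = base_params or DDMParams()
    box = dict(DEFAULT_DDM_BOUNDS)
    if bounds:
        box.update(bounds)
    names = list(free)
    lo_hi = [box[name] for name in names]

    def to_params(x) -> DDMParams:
        return replace(base, **{n: float(v) for n, v in zip(names, x)})

    trace: list[tuple[dict, float]] = []

    def func(x):
        ddm = to_params(x)
        loss = ddm_objective(ddm, targets, design, seed=seed, quantiles=quantiles)
        trace.append(({n: getattr(ddm, n) for n in
                       ("thr", "dft", "sig2", "ndt_s", "k")}, loss))
        return loss

    res, converged = _direct_search(func, lo_hi, budget, trace)
    best = to_params(res.x)
    reval = [ddm_objective(best, targets, design, seed=seed + 1000 + i,
                           quantiles=quantiles) for i in range(n_reval_seeds)]
    return FitResult(
        params=best,
        loss=float(res.fun),
        n_evaluations=len(trace),
        seed=seed,
        converged=bool(converged),
        trace=trace,
        loss_mean=float(np.mean(reval)) if reval else None,
        loss_sd=float(np.std(reval)) if reval else None,
        message=res.message,
    )
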