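"""Weber-scaled evidence sampling, memory decay, and the psychometric function.

The internal representation of the numerical difference between two dot
arrays is modelled as Gaussian with a spread that grows with the overall
magnitude of the numerosities (Weber scaling)::

    s(i) ~ Normal(|n_L - n_R|,  (omega * sqrt(n_L**2 + n_R**2))**2)

Samples are expressed in units of numerical difference, in a
*larger-side-positive* frame: positive samples favour the side that truly
has more dots; negative samples are evidence for the wrong side.  The
per-sample probability of a misleading (negative) sample is exactly the
psychometric error rate

    err = 0.5 * erfc(|n_L - n_R| / (omega * sqrt(2) * sqrt(n_L**2 + n_R**2)))

which is the standard erfc psychometric function of numerosity comparison
and the function used here to estimate Weber fractions from accuracy.

Memory effects are modelled by filtering the evidence stream with an
exponential moving average, ``EMA(i) = D*s(i) + (1-D)*EMA(i-1)`` with
``EMA(0) = s(1)``: ``D = 1`` leaves the stream untouched (memory-free
sampling), ``D -> 0`` locks the stream onto the first sample (primacy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, signal, special, stats

__all__ = [
    "MAX_DOTS_DEFAULT",
    "StimulusPair",
    "EvidenceStream",
    "WeberModel",
    "WeberFit",
    "sample_evidence",
    "generate_stream",
    "apply_ema",
    "predicted_error_rate",
    "prob_evidence_below",
    "fit_weber",
    "pairs_for_ratio",
    "sample_pair",
]

#: Largest dot count used in the comparison task.
MAX_DOTS_DEFAULT = 25


@dataclass(frozen=True)
class StimulusPair:
    """The two dot counts shown on a trial.

    Attributes
    ----------
    n_left, n_right:
        Integer dot counts, each at least 1 and at most ``max_count``.
    max_count:
        Upper bound on either count (default 25).
    """

    n_left: int
    n_right: int
    max_count: int = MAX_DOTS_DEFAULT

    def __post_init__(self) -> None:
        for name in ("n_left", "n_right"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"invalid stimulus: {name}={value!r} is not finite")
            if int(value) != value:
                raise ValueError(f"invalid stimulus: {name}={value!r} is not an integer")
            if not 1 <= value <= self.max_count:
                raise ValueError(
                    f"invalid stimulus: {name}={value!r} outside [1, {self.max_count}]"
                )

    @property
    def ratio(self) -> float:
        """Numerical ratio min/max, in (0, 1]; closer to 1 is harder."""
        return min(self.n_left, self.n_right) / max(self.n_left, self.n_right)

    @property
    def correct_side(self) -> str | None:
        """'left' or 'right' for the more numerous side, ``None`` for ties."""
        if self.n_left > self.n_right:
            return "left"
        if self.n_right > self.n_left:
            return "right"
        return None

    @property
    def mean_difference(self) -> float:
        """|n_L - n_R|, the mean of the evidence distribution."""
        return float(abs(self.n_left - self.n_right))

    @property
    def spread(self) -> float:
        """sqrt(n_L**2 + n_R**2), the Weber magnitude term."""
        return float(math.hypot(self.n_left, self.n_right))

    @property
    def frame_sign(self) -> int:
        """Map from the larger-side-positive frame to screen coordinates.

        Screen coordinates are right-positive, so ``screen_x = frame_sign *
        frame_x``.  Equal-count pairs default to a left-positive frame; all
        downstream statistics are invariant to that choice.
        """
        return 1 if self.correct_side == "right" else -1


@dataclass(frozen=True)
class EvidenceStream:
    """Timestamped evidence samples, raw and (optionally) EMA-filtered."""

    sample_times_ms: np.ndarray
    raw: np.ndarray
    ema: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sample_times_ms) != len(self.raw):
            raise ValueError("sample_times_ms and raw must have equal length")
        if self.ema is not None and len(self.ema) != len(self.raw):
            raise ValueError("raw and ema must have equal length")

    def __len__(self) -> int:
        return len(self.raw)

    def with_ema(self, d: float) -> "EvidenceStream":
        """Return a copy with the EMA series computed at memory decay ``d``."""
        return EvidenceStream(self.sample_times_ms, self.raw, apply_ema(self.raw, d))


@dataclass(frozen=True)
class WeberModel:
    """Weber fraction of the numerosity representation."""

    omega: float

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")


@dataclass(frozen=True)
class WeberFit(WeberModel):
    """A fitted Weber fraction together with its goodness of fit."""

    r_squared: float = float("nan")
    n_points: int = 0


def _as_counts(pair) -> tuple[float, float]:
    if isinstance(pair, StimulusPair):
        return float(pair.n_left), float(pair.n_right)
    n_left, n_right = pair
    return float(n_left), float(n_right)


def sample_evidence(pair, omega: float, rng: np.random.Generator, size=None):
    """Draw evidence samples for a stimulus pair.

    Samples are normal with mean ``|n_L - n_R|`` and standard deviation
    ``omega * sqrt(n_L**2 + n_R**2)``, in the larger-side-positive frame.
    ``omega = 0`` is the degenerate noise-free representation.
    """
    n_left, n_right = _as_counts(pair)
    if not (np.isfinite(n_left) and np.isfinite(n_right)):
        raise ValueError("invalid stimulus: non-finite counts")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    mean = abs(n_left - n_right)
    sd = omega * math.hypot(n_left, n_right)
    if sd == 0.0:
        return np.full(size, mean) if size is not None else mean
    return rng.normal(mean, sd, size=size)


def generate_stream(
    pair,
    omega: float,
    r_ms: float,
    duration_ms: float,
    rng: np.random.Generator,
) -> EvidenceStream:
    """Sample an evidence stream at one sample every ``r_ms`` milliseconds.

    Samples arrive at times R, 2R, ...; a duration shorter than R yields a
    legal empty stream (no evidence has arrived yet).
    """
    if not 1.0 <= r_ms <= 100.0:
        raise ValueError(f"sampling interval R must be in [1, 100] ms, got {r_ms}")
    if not duration_ms > 0:
        raise ValueError(f"duration_ms must be > 0, got {duration_ms}")
    n = int(duration_ms // r_ms)
    times = r_ms * np.arange(1, n + 1)
    raw = np.asarray(sample_evidence(pair, omega, rng, size=n), dtype=float)
    return EvidenceStream(times, raw)


def apply_ema(raw: Sequence[float], d: float) -> np.ndarray:
    """Exponential moving average with decay ``d`` and ``EMA(0) = s(1)``.

    ``d = 1`` returns the input unchanged; ``d = 0`` returns a constant
    series pinned at the first sample.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"memory decay D must be in [0, 1], got {d}")
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw.copy()
    # EMA(i) = d*s(i) + (1-d)*EMA(i-1) is an IIR filter with state seeded so
    # that the virtual EMA(0) equals s(1).
    zi = np.array([(1.0 - d) * raw[0]])
    out, _ = signal.lfilter([d], [1.0, -(1.0 - d)], raw, zi=zi)
    return out


def predicted_error_rate(pair, omega: float):
    """Psychometric error rate for a comparison, in [0, 0.5].

    Exactly the probability that a single evidence sample is negative
    (favours the wrong side).
    """
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    n_left, n_right = _as_counts(pair)
    diff = abs(n_left - n_right)
    mag = math.hypot(n_left, n_right)
    return 0.5 * special.erfc(diff / (omega * math.sqrt(2.0) * mag))


def prob_evidence_below(pair, omega: float, x: float) -> float:
    """P(sample <= x) under the evidence distribution of ``pair``.

    Used to reason about accumulation gates: for a 5-vs-10 comparison at
    omega = 0.17 the probability of a sample at or below 0.27 is ~0.006,
    i.e. essentially every first sample clears such a gate.
    """
    n_left, n_right = _as_counts(pair)
    mean = abs(n_left - n_right)
    sd = omega * math.hypot(n_left, n_right)
    if sd == 0.0:
        return float(x >= mean)
    return float(stats.norm.cdf(x, loc=mean, scale=sd))


def fit_weber(
    accuracy_table: Iterable[tuple[object, float]],
    bounds: tuple[float, float] = (1e-4, 10.0),
) -> WeberFit:
    """Estimate the Weber fraction from per-condition accuracies.

    ``accuracy_table`` holds ``(pair, accuracy)`` rows, one per condition
    (pairs may be :class:`StimulusPair` or raw count tuples).  The estimate
    minimises the mean squared deviation between observed error rates
    (1 - accuracy) and the erfc psychometric function; the R^2 of that fit
    is reported alongside.
    """
    rows = [( _as_counts(pair), float(acc)) for pair, acc in accuracy_table]
    if any(not 0.0 <= acc <= 1.0 for _, acc in rows):
        raise ValueError("accuracies must lie in [0, 1]")
    ratios = {round(min(c) / max(c), 12) for c, _ in rows}
    if len(ratios) < 2:
        raise ValueError("need accuracies at >= 2 distinct ratios to identify omega")
    observed = np.array([1.0 - acc for _, acc in rows])
    if np.allclose(observed, 0.5):
        warnings.warn(
            "all accuracies are at chance: omega is unbounded above (degenerate fit)",
            RuntimeWarning,
            stacklevel=2,
        )
    pairs = [c for c, _ in rows]

    def loss(log_omega: float) -> float:
        omega = math.exp(log_omega)
        pred = np.array([predicted_error_rate(c, omega) for c in pairs])
        return float(np.mean((pred - observed) ** 2))

    res = optimize.minimize_scalar(
        loss,
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    omega = math.exp(res.x)
    pred = np.array([predicted_error_rate(c, omega) for c in pairs])
    ss_res = float(np.sum((observed - pred) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return WeberFit(omega=omega, r_squared=r2, n_points=len(rows))


def pairs_for_ratio(ratio: float, max_count: int = MAX_DOTS_DEFAULT) -> list[tuple[int, int]]:
    """All integer (smaller, larger) pairs with the given ratio, counts <= max_count.

    For example ratio 0.1 with max 25 dots admits (1, 10) and (2, 20).
    Equal-count conditions (ratio 1) admit (k, k) for every k.
    """
    from fractions import Fraction

    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    frac = Fraction(ratio).limit_denominator(max_count)
    p, q = frac.numerator, frac.denominator
    pairs = [(k * p, k * q) for k in range(1, max_count // q + 1)]
    if not pairs:
        raise ValueError(f"no integer pair with ratio {ratio} and counts <= {max_count}")
    return pairs


def sample_pair(
    ratio: float,
    rng: np.random.Generator,
    larger_side: str = "right",
    max_count: int = MAX_DOTS_DEFAULT,
    mode: str = "sampled",
) -> StimulusPair:
    """Draw a stimulus pair at a ratio, placing the larger count on a side.

    ``mode='sampled'`` picks uniformly among the admissible integer pairs
    (the task fixed only the ratio and the 25-dot cap); ``'largest'`` and
    ``'smallest'`` pick the extreme pair deterministically.
    """
    pairs = pairs_for_ratio(ratio, max_count)
    if mode == "sampled":
        small, large = pairs[rng.integers(len(pairs))]
    elif mode == "largest":
        small, large = pairs[-1]
    elif mode == "smallest":
        small, large = pairs[0]
    else:
        raise ValueError(f"unknown pair mode {mode!r}")
    if larger_side == "right":
        return StimulusPair(small, large, max_count=max_count)
    if larger_side == "left":
        return StimulusPair(large, small, max_count=max_count)
    raise ValueError(f"larger_side must be 'left' or 'right', got {larger_side!r}")
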