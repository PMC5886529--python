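"""Sequential Bayesian inference over the numerical difference.

With a flat prior over the numerical difference mu and a normal likelihood
with variance ``W`` (the acuity / likelihood-noise parameter, in variance
units), the posterior after ``n`` EMA samples with mean ``e_bar`` is the
textbook conjugate result

    p(mu | e) = Normal(e_bar, W / n)

so the probability that the positive-frame side is the larger one is
``Phi(e_bar * sqrt(n / W))``.  Certainty is a rescaling of the binary
entropy of the two side probabilities into [0, 1]; it is what slows the
motor controller down under uncertainty.

The module also provides the two-hypothesis posterior of the traditional
threshold (drift-diffusion) model: correct-vs-incorrect likelihoods
``Normal(+dft, sig2)`` and ``Normal(-dft, sig2)`` with equal priors, which
reduces algebraically to a logistic in the sample sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "Belief",
    "update_belief",
    "posterior_correct",
    "certainty_of",
    "heading_side",
    "ddm_posterior_correct",
]

#: Probabilities are clipped to [EPS, 1-EPS] before entropy evaluation.
#: Numerics only: certainty saturates at 1 well before the clip matters.
EPS = 1e-12

_H_HALF = np.log(2.0)  # binary entropy at p = 0.5, in nats


@dataclass(frozen=True)
class Belief:
    """Posterior state after ``n_samples`` EMA samples.

    ``p_correct`` is the probability that the positive-frame side is the
    larger one; ``posterior_var = W / n_samples`` shrinks as evidence
    arrives at fixed acuity ``W``.
    """

    e_bar: float
    n_samples: int
    w: float
    posterior_var: float
    p_correct: float
    certainty: float


def certainty_of(p):
    """Entropy-based certainty in [0, 1]: ``(H(0.5) - H(p)) / H(0.5)``.

    Symmetric in ``p <-> 1-p``, zero at ``p = 0.5``, and saturating at 1 as
    ``p`` approaches 0 or 1.  Accepts scalars or arrays.
    """
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    h = -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))
    out = np.clip(1.0 - h / _H_HALF, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def posterior_correct(e_bar, n_samples, w):
    """P(mu > 0) under the Normal(e_bar, W/n) posterior. Vectorized."""
    e_bar = np.asarray(e_bar, dtype=float)
    n_samples = np.asarray(n_samples, dtype=float)
    out = special.ndtr(e_bar * np.sqrt(n_samples / w))
    return float(out) if out.ndim == 0 else out


def update_belief(ema, w: float) -> Belief:
    """Compute the posterior belief from the EMA samples seen so far."""
    if not w > 0:
        raise ValueError(f"likelihood noise W must be > 0, got {w}")
    ema = np.asarray(ema, dtype=float)
    if ema.size == 0:
        raise ValueError("cannot form a belief from an empty sample series")
    n = int(ema.size)
    e_bar = float(ema.mean())
    p = float(posterior_correct(e_bar, n, w))
    return Belief(
        e_bar=e_bar,
        n_samples=n,
        w=float(w),
        posterior_var=float(w) / n,
        p_correct=p,
        certainty=certainty_of(p),
    )


def heading_side(belief: Belief) -> int:
    """Heading of the effector: +1 (positive-frame side) iff p_correct >= 0.5.

    The tie at exactly 0.5 heads to the positive-frame side; certainty is 0
    there, so the motor update is zero and downstream results are
    insensitive to the tie rule.
    """
    return 1 if belief.p_correct >= 0.5 else -1


def ddm_posterior_correct(samples, dft: float, sig2: float):
    """Two-hypothesis posterior of being correct given accumulated samples.

    Equal priors and Gaussian likelihoods Normal(+dft, sig2) vs
    Normal(-dft, sig2) give ``p = logistic(2 * dft * sum(samples) / sig2)``
    (``sig2`` in variance units).  ``samples`` is the series accumulated so
    far; a scalar is treated as a single sample.
    """
    if not sig2 > 0:
        raise ValueError(f"sig2 must be > 0, got {sig2}")
    total = float(np.asarray(samples, dtype=float).sum())
    return float(special.expit(2.0 * dft * total / sig2))
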