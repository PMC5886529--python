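"""Minimum-jerk optimal feedback controller with certainty weighting.

The effector follows the finite-horizon jerk-minimizing feedback law: with
remaining time ``delta = tf - t``, position ``x``, velocity ``v`` and
acceleration ``a``, the commanded jerk toward target ``x_f`` is

    jerk = 60*(x_f - x)/delta**3 - 36*v/delta**2 - 9*a/delta

Integrated open-loop from rest with a fixed target this reproduces the
classical minimum-jerk polynomial ``x_f * (10 tau^3 - 15 tau^4 + 6 tau^5)``.
Certainty enters as a scalar in [0, 1] multiplying the whole state
derivative (all axes, all orders): updates are *delayed*, never redirected,
so the motion stays jerk-optimal in character while uncertainty slows it.

The satisficing variant raises certainty to the normalized remaining depth
distance (1 at the start button, 0 at screen arrival), releasing the
certainty brake as the finger nears the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ControllerConfig",
    "KinematicState",
    "min_jerk_jerk",
    "kinematic_derivative",
    "step",
    "satisficing_weight",
    "minjerk_closed_form",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Integration and geometry settings for the reach controller.

    dt:
        Euler step, seconds (default 1 ms).
    delta_min:
        Floor on the remaining time, seconds; the finite-horizon law is
        singular at delta -> 0, so delta is clamped here (default = dt).
    target_horizontal:
        Lateral target |x_f| in cm (targets sit at +-x_f).
    start_depth:
        Depth travel from start button to screen, cm (the start button sat
        roughly 29 cm from the screen).
    weight_mode:
        'certainty' (weight = certainty), 'satisficing'
        (weight = certainty ** depth_distance) or 'unweighted' (weight = 1).
    """

    dt: float = 0.001
    delta_min: float = 0.001
    target_horizontal: float = 10.0
    start_depth: float = 29.0
    screen_depth: float = 0.0
    weight_mode: str = "certainty"

    def __post_init__(self) -> None:
        if not 0.0 < self.dt <= self.delta_min:
            raise ValueError(
                f"need 0 < dt <= delta_min, got dt={self.dt}, delta_min={self.delta_min}"
            )
        if self.target_horizontal == 0:
            raise ValueError("target_horizontal must be nonzero")
        if self.weight_mode not in ("certainty", "satisficing", "unweighted"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class KinematicState:
    """Effector state: per-axis (position, velocity, acceleration), cm units.

    ``q`` has shape (n_axes, 3); axis 0 is horizontal, axis 1 (if present)
    depth.  The state starts at zeros and ``t`` advances by dt every step
    whether or not the kinematics move.
    """

    q: np.ndarray
    t: float
    tf: float

    @classmethod
    def zeros(cls, tf: float, n_axes: int = 2) -> "KinematicState":
        if not tf > 0:
            raise ValueError(f"movement time tf must be > 0, got {tf}")
        return cls(q=np.zeros((n_axes, 3)), t=0.0, tf=float(tf))

    @property
    def position(self) -> np.ndarray:
        return self.q[:, 0]

    @property
    def velocity(self) -> np.ndarray:
        return self.q[:, 1]

    @property
    def acceleration(self) -> np.ndarray:
        return self.q[:, 2]


def min_jerk_jerk(pos, vel, acc, target, delta):
    """Commanded jerk of the finite-horizon minimum-jerk feedback law.

    Broadcasts over arrays; ``delta`` must already be clamped away from 0.
    """
    d2 = delta * delta
    return (60.0 * (target - pos) / delta - 36.0 * vel) / d2 - 9.0 * acc / delta


def kinematic_derivative(state: KinematicState, targets, delta_min: float = 0.001):
    """State derivative (velocity, acceleration, jerk) per axis.

    ``targets`` holds one x_f per axis.  The remaining time delta = tf - t
    is clamped at ``delta_min`` so the law never divides by zero.
    A state resting exactly on target has derivative zero (fixed point).
    """
    delta = max(state.tf - state.t, delta_min)
    targets = np.asarray(targets, dtype=float)
    jerk = min_jerk_jerk(state.q[:, 0], state.q[:, 1], state.q[:, 2], targets, delta)
    return np.column_stack([state.q[:, 1], state.q[:, 2], jerk])


def step(
    state: KinematicState,
    targets,
    weight: float,
    config: ControllerConfig,
) -> KinematicState:
    """One Euler step with certainty weighting.

    All kinematic components advance by ``weight * qdot * dt``; time
    advances by dt unconditionally, so weight = 0 freezes the effector
    while the movement clock runs.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight must be in [0, 1], got {weight}")
    qdot = kinematic_derivative(state, targets, config.delta_min)
    return replace(state, q=state.q + weight * qdot * config.dt, t=state.t + config.dt)


def satisficing_weight(certainty, depth_distance):
    """Satisficing motor weight: certainty ** depth_distance.

    ``depth_distance`` is the normalized remaining depth (1 at the start
    button, 0 at screen arrival); 0**0 is defined as 1, so an uncertain
    effector is still released onto the nearest target at the screen.
    Accepts scalars or arrays.
    """
    c = np.clip(np.asarray(certainty, dtype=float), 0.0, 1.0)
    d = np.clip(np.asarray(depth_distance, dtype=float), 0.0, 1.0)
    out = np.power(c, d)  # numpy defines 0.0 ** 0.0 == 1.0
    return float(out) if out.ndim == 0 else out


def minjerk_closed_form(x_f: float, tf: float, t):
    """Closed-form minimum-jerk position profile from rest to rest.

    ``x_f * (10 tau^3 - 15 tau^4 + 6 tau^5)`` with tau = t/tf; serves as the
    analytic oracle for the Euler-integrated feedback law.
    """
    tau = np.asarray(t, dtype=float) / tf
    out = x_f * (10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5)
    return float(out) if out.ndim == 0 else out
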