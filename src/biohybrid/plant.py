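"""Surrogate robotic finger and fingertip tactile sensor.

The tendon-driven finger with its PID joint controller is reduced to
critically damped first-order tracking of the commanded joint angle, and
the fingertip sensor to a linear elastic contact: everything downstream
consumes only the shapes of the steady force ``F_DC`` and its rate
``F_AC``, which this surrogate preserves.  Forces are normalized "contact
units": full flexion against the surface gives ``F_DC = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlantConfig", "ForceSignal", "JointState", "step_plant",
           "simulate_joint", "sense_forces", "es_waveform"]


@dataclass(frozen=True)
class PlantConfig:
    servo_tau_ms: float = 25.0       # first-order servo time constant (flexion)
    release_tau_ms: float = 200.0    # extension time constant (tendon return is slower)
    theta1: float = 0.0              # open-hand angle (deg)
    theta2: float = 45.0             # commanded contact angle (deg)
    theta_contact: float = 25.0      # fingertip touches the surface here (deg)
    contact_stiffness: float = 0.05  # contact units per deg of indentation
    sensor_noise_sd: float = 0.0     # contact units, additive on F_DC
    control_rate: float = 1000.0     # Hz

    def __post_init__(self):
        if not (self.theta1 < self.theta_contact < self.theta2):
            raise ValueError("require theta1 < theta_contact < theta2")
        if self.servo_tau_ms <= 0:
            raise ValueError("servo time constant must be positive")


@dataclass
class JointState:
    theta: float          # deg
    theta_dot: float = 0.0


@dataclass(frozen=True)
class ForceSignal:
    """Paired steady-force / force-rate streams from the fingertip."""

    f_dc: np.ndarray      # contact units, >= 0
    f_ac: np.ndarray      # contact units / s (discrete derivative of f_dc)
    rate: float           # Hz

    def __post_init__(self):
        object.__setattr__(self, "f_dc", np.asarray(self.f_dc, dtype=np.float64))
        object.__setattr__(self, "f_ac", np.asarray(self.f_ac, dtype=np.float64))
        if self.f_dc.shape != self.f_ac.shape:
            raise ValueError("f_dc and f_ac must be the same length")

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.f_dc.size) / self.rate

    def __len__(self):
        return self.f_dc.size


def step_plant(theta_d: float, state: JointState, config: PlantConfig, dt: float | None = None):
    """One control tick of the servo; returns ``(new_state, in_contact)``.

    The joint relaxes exponentially toward the command (exact discretization
    of first-order tracking, unconditionally stable).
    """
    if dt is None:
        dt = 1.0 / config.control_rate
    tau = config.servo_tau_ms if theta_d >= state.theta else config.release_tau_ms
    alpha = 1.0 - np.exp(-dt * 1000.0 / tau)
    theta = state.theta + alpha * (theta_d - state.theta)
    new = JointState(theta=theta, theta_dot=(theta - state.theta) / dt)
    return new, theta >= config.theta_contact


def simulate_joint(theta_d: np.ndarray, config: PlantConfig, theta0: float | None = None) -> np.ndarray:
    """Joint-angle trajectory tracking a commanded series at the control rate."""
    theta_d = np.asarray(theta_d, dtype=np.float64)
    a_up = 1.0 - np.exp(-1000.0 / (config.control_rate * config.servo_tau_ms))
    a_dn = 1.0 - np.exp(-1000.0 / (config.control_rate * config.release_tau_ms))
    theta = np.empty_like(theta_d)
    cur = config.theta1 if theta0 is None else theta0
    for i, td in enumerate(theta_d):
        cur += (a_up if td >= cur else a_dn) * (td - cur)
        theta[i] = cur
    return theta


def sense_forces(theta: np.ndarray, config: PlantConfig, rng: np.random.Generator | None = None) -> ForceSignal:
    """Fingertip forces along a joint trajectory.

    ``F_DC = stiffness * max(0, theta - theta_contact)`` (plus optional
    sensor noise, clipped at zero); ``F_AC`` is the centered 3-sample
    discrete derivative of ``F_DC`` in contact units per second.
    """
    theta = np.asarray(theta, dtype=np.float64)
    f_dc = config.contact_stiffness * np.maximum(0.0, theta - config.theta_contact)
    if config.sensor_noise_sd > 0:
        if rng is None:
            raise ValueError("sensor noise requested but no rng supplied")
        f_dc = np.maximum(0.0, f_dc + config.sensor_noise_sd * rng.standard_normal(f_dc.size))
    f_ac = np.gradient(f_dc) * config.control_rate  # centered differencing
    return ForceSignal(f_dc=f_dc, f_ac=f_ac, rate=config.control_rate)


def es_waveform(t, config: PlantConfig, frequency: float = 0.25):
    """Efferent-substitution joint command: square wave decoupled from the BNN.

    Period 4 s at the default 0.25 Hz; starts in the no-contact state
    (``theta1`` for the first half-period), then ``theta2`` for 2 s of
    tactile contact, repeating.
    """
    t = np.asarray(t, dtype=np.float64)
    phase = (t * frequency) % 1.0
    return np.where(phase < 0.5, config.theta1, config.theta2)
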