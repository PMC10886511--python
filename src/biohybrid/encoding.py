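"""Tactile afferent encoding: fingertip forces -> mechanoreceptor spike trains.

Fingertip contact is decomposed into a steady force ``F_DC`` and its rate of
change ``F_AC``.  A single Izhikevich neuron converts these into spike
trains mimicking slowly adapting (SA) or rapidly adapting (RA)
mechanoreceptor afferents:

    SA:  I = beta  + k_SA * F_DC + k_RA * F_AC      (tonic during hold)
    RA:  I = alpha + k_RA * F_AC                    (transients only)

Each encoder spike raises a 4.5 V stimulation trigger; triggers are rendered
as charge-balanced, positive-first biphasic pulses for delivery at the MEA's
afferent electrode.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TRIGGER_LEVEL_V",
    "IzhikevichParams",
    "EncoderGains",
    "NeuronState",
    "StimTriggerTrain",
    "InstabilityError",
    "compute_input_current",
    "step_neuron",
    "encode_force_stream",
    "biphasic_pulse",
    "render_stim_waveform",
]

#: stimulation trigger level raised at each encoder spike (volts)
TRIGGER_LEVEL_V = 4.5

#: membrane potential spike cutoff (mV)
SPIKE_CUTOFF_MV = 30.0


class InstabilityError(ArithmeticError):
    """Euler integration diverged; typically the step ``dt`` is too large."""


@dataclass(frozen=True)
class IzhikevichParams:
    """Izhikevich neuron parameters.

    ``v' = X v^2 + Y v + Z + I - u``, ``u' = a (b v - u)``; when ``v`` reaches
    30 mV the neuron spikes and resets ``v <- c``, ``u <- u + d``.  Defaults
    are the encoder's published parameter set.
    """

    a: float = 0.1
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    X: float = 0.04
    Y: float = 5.0
    Z: float = 140.0
    dt: float = 0.5  # ms

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.c < SPIKE_CUTOFF_MV:
            raise ValueError("reset potential c must lie below the 30 mV cutoff")

    def resting_state(self) -> "NeuronState":
        """Stable zero-input equilibrium (root of X v^2 + (Y - b) v + Z)."""
        roots = np.roots([self.X, self.Y - self.b, self.Z])
        roots = np.sort(roots[np.isreal(roots)].real)
        if roots.size == 0:
            raise ValueError("no real resting potential for these parameters")
        v = roots[0]  # lower root is the stable node for these dynamics
        return NeuronState(v=float(v), u=float(self.b * v))


@dataclass(frozen=True)
class EncoderGains:
    """Baseline currents and force gains of the SA/RA encoders.

    Units are normalized: forces live in [0, 1] "contact units" and the
    gains absorb all scaling into Izhikevich current units.
    """

    alpha: float = 2.0   # RA baseline current (subthreshold: silent off contact)
    beta: float = 3.0    # SA baseline current (subthreshold)
    k_sa: float = 6.0    # current per contact unit of F_DC (~20-60 Hz tonic)
    k_ra: float = 0.5    # current per contact-unit/s of F_AC (~3-10 spikes/edge)
    #: drive the encoders with |F_AC| so that RA afferents respond to both
    #: contact onset and release, as fingertip vibration sensors do.  Set
    #: False for the signed force-rate variant.
    rectify_f_ac: bool = True

    def __post_init__(self):
        if self.k_sa < 0 or self.k_ra < 0:
            raise ValueError("force gains must be nonnegative")


@dataclass
class NeuronState:
    v: float
    u: float


@dataclass(frozen=True)
class StimTriggerTrain:
    """Stimulation trigger events emitted by the afferent encoder."""

    spike_times: np.ndarray          # seconds, strictly increasing
    encoding: str                    # 'SA' or 'RA'
    trigger_level: float = TRIGGER_LEVEL_V

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        object.__setattr__(self, "spike_times", t)

    def __len__(self):
        return self.spike_times.size

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "level_V", "encoding"])
            for t in self.spike_times:
                w.writerow([f"{t:.6f}", self.trigger_level, self.encoding])

    @classmethod
    def from_csv(cls, path) -> "StimTriggerTrain":
        times, enc, lvl = [], "SA", TRIGGER_LEVEL_V
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                times.append(float(row["time_s"]))
                enc = row["encoding"]
                lvl = float(row["level_V"])
        return cls(np.asarray(times), enc, lvl)


def compute_input_current(f_dc: float, f_ac: float, gains: EncoderGains, mode: str) -> float:
    """Encoder input current for one force sample.

    SA responds to both the steady force and its rate; RA depends solely on
    the force rate.
    """
    if not (np.isfinite(f_dc) and np.isfinite(f_ac)):
        raise ValueError("rejected input signal: non-finite force sample")
    if f_dc < 0:
        raise ValueError("rejected input signal: negative steady force")
    if gains.rectify_f_ac:
        f_ac = abs(f_ac)
    if mode == "SA":
        return gains.beta + gains.k_sa * f_dc + gains.k_ra * f_ac
    if mode == "RA":
        return gains.alpha + gains.k_ra * f_ac
    raise ValueError(f"unknown encoding mode {mode!r}")


def step_neuron(state: NeuronState, I: float, params: IzhikevichParams):
    """One forward-Euler step of the encoder neuron.

    Returns ``(new_state, spiked, trigger_level)`` where ``trigger_level`` is
    4.5 V on a spike and 0 V otherwise.  The conventional split update is
    used: ``v`` then ``u``, then the spike/reset test.
    """
    p = params
    v, u = state.v, state.u
    v = v + p.dt * (p.X * v * v + p.Y * v + p.Z + I - u)
    u = u + p.dt * p.a * (p.b * v - u)
    if not (np.isfinite(v) and np.isfinite(u)) or abs(v) > 1e6:
        raise InstabilityError(
            f"Izhikevich integration diverged (|v| > 1e6 mV); reduce dt={p.dt} ms"
        )
    if v >= SPIKE_CUTOFF_MV:
        return NeuronState(v=p.c, u=u + p.d), True, TRIGGER_LEVEL_V
    return NeuronState(v=v, u=u), False, 0.0


def encode_force_stream(
    force,
    mode: str,
    gains: EncoderGains = EncoderGains(),
    params: IzhikevichParams = IzhikevichParams(),
    initial_state: NeuronState | None = None,
) -> StimTriggerTrain:
    """Run the encoder neuron over a sampled force stream.

    ``force`` is a :class:`biohybrid.plant.ForceSignal` (or any object with
    ``f_dc``, ``f_ac`` and ``rate`` attributes) sampled at a fixed control
    rate.  The neuron is integrated with ``ceil`` substeps of ``params.dt``
    per force sample; spike times are reported at substep resolution.
    """
    f_dc = np.asarray(force.f_dc, dtype=float)
    f_ac = np.asarray(force.f_ac, dtype=float)
    if f_dc.size == 0:
        return StimTriggerTrain(np.empty(0), mode)
    tick_ms = 1000.0 / force.rate
    nsub = max(1, int(round(tick_ms / params.dt)))
    p = replace(params, dt=tick_ms / nsub)
    state = initial_state if initial_state is not None else params.resting_state()
    times = []
    for k in range(f_dc.size):
        I = compute_input_current(f_dc[k], f_ac[k], gains, mode)
        for j in range(nsub):
            state, spiked, _ = step_neuron(state, I, p)
            if spiked:
                times.append((k * nsub + j + 1) * p.dt / 1000.0)
    return StimTriggerTrain(np.asarray(times), mode)


def biphasic_pulse(fs: float, amplitude: float = 1.0, phase_width_ms: float = 0.2) -> np.ndarray:
    """Charge-balanced, positive-first biphasic pulse sampled at ``fs``.

    Two rectangular phases of equal width and opposite sign; the sampled
    integral is exactly zero.
    """
    w = max(1, int(round(phase_width_ms * 1e-3 * fs)))
    return np.concatenate([np.full(w, amplitude), np.full(w, -amplitude)])


def render_stim_waveform(
    train: StimTriggerTrain,
    fs: float,
    duration: float,
    amplitude: float = 1.0,
    phase_width_ms: float = 0.2,
) -> np.ndarray:
    """Render trigger events as a stimulation waveform.

    Overlap rule: a minimum inter-pulse separation equal to the full pulse
    width is enforced; a trigger arriving while the previous pulse is still
    active is rejected.
    """
    n = int(round(duration * fs))
    out = np.zeros(n, dtype=np.float32)
    pulse = biphasic_pulse(fs, amplitude, phase_width_ms)
    min_sep = len(pulse) / fs
    last = -np.inf
    for t in train.spike_times:
        if t - last < min_sep:
            continue
        i = int(round(t * fs))
        if i >= n:
            break
        seg = pulse[: n - i]
        out[i : i + seg.size] += seg
        last = t
    return out
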