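"""Embodiment sessions: wire encoder, decoder, plant and culture together.

Three embodiment configurations, distinguished by two switches:

* **CL** (closed loop): efferent spikes drive finger taps; tap forces are
  encoded and stimulated back at the afferent electrode (BNN-driven,
  stimulate).
* **AD** (afferent deprived): taps are driven by efferent spikes, the
  encoder runs, but no stimulation is delivered (BNN-driven, deprive).
* **ES** (efferent substitution): taps follow a fixed 0.25 Hz square wave
  (2 s contact / 2 s open), stimulation is delivered, efferent activity is
  recorded but unused (fixed-waveform, stimulate).

The loop runs at a 1 kHz control tick; extracellular synthesis at 20 kHz is
batched per tick.  The platform's hardware latency (~1 ms) is modeled as a
one-tick delay on both the motor and stimulation pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .culture import CultureConfig, CultureNetwork, TraceAccumulator, ElectrodeTrace
from .decoding import DecoderConfig
from .encoding import EncoderGains, IzhikevichParams, StimTriggerTrain, step_neuron, compute_input_current
from .plant import PlantConfig, ForceSignal, es_waveform

__all__ = ["EmbodimentConfig", "SessionRecord", "run_session", "run_protocol",
           "record_baseline", "MODES", "ENCODINGS"]

MODES = ("CL", "AD", "ES")
ENCODINGS = ("SA", "RA")

#: switch semantics per embodiment mode: (efferent_switch, afferent_switch)
SWITCHES = {
    "CL": ("BNN-driven", "stimulate"),
    "AD": ("BNN-driven", "deprive"),
    "ES": ("fixed-waveform", "stimulate"),
}


@dataclass(frozen=True)
class EmbodimentConfig:
    mode: str                    # CL | AD | ES
    encoding: str                # SA | RA
    seed: int
    duration: float = 300.0      # seconds
    div_label: str = "DIV21"
    #: seed of the culture (network build); sessions recorded on the same
    #: day share one culture but differ in their noise/drive realization.
    #: Defaults to ``seed`` when not given.
    culture_seed: int | None = None
    efferent_switch: str | None = None   # derived from mode unless given
    afferent_switch: str | None = None
    culture: CultureConfig = field(default_factory=CultureConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    plant: PlantConfig = field(default_factory=PlantConfig)
    gains: EncoderGains = field(default_factory=EncoderGains)
    neuron: IzhikevichParams = field(default_factory=IzhikevichParams)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"encoding must be one of {ENCODINGS}")
        eff, aff = SWITCHES[self.mode]
        if self.efferent_switch is None:
            object.__setattr__(self, "efferent_switch", eff)
        if self.afferent_switch is None:
            object.__setattr__(self, "afferent_switch", aff)
        if (self.efferent_switch, self.afferent_switch) != SWITCHES[self.mode]:
            raise ValueError(
                f"switch combination ({self.efferent_switch}, {self.afferent_switch}) "
                f"is inconsistent with mode {self.mode}"
            )


@dataclass
class SessionRecord:
    """Synchronized efferent/afferent/robot streams for one session."""

    mode: str
    encoding: str
    div_label: str
    seed: int
    duration: float
    control_rate: float
    efferent: ElectrodeTrace
    afferent: ElectrodeTrace
    stim_times: np.ndarray        # delivered stimulation pulses (s)
    encoder_triggers: np.ndarray  # encoder spikes regardless of the afferent switch
    ttl: np.ndarray               # MEA_out level at the control rate
    theta_d: np.ndarray           # commanded joint angle (deg)
    theta: np.ndarray             # measured joint angle (deg)
    force: ForceSignal
    tap_times: np.ndarray         # commanded contact onsets (s)
    v_thresh: float

    @property
    def fs(self) -> float:
        return self.efferent.fs

    @property
    def stim_train(self) -> StimTriggerTrain:
        return StimTriggerTrain(self.stim_times, self.encoding)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            meta = f.create_group("meta")
            for k in ("mode", "encoding", "div_label"):
                meta.attrs[k] = getattr(self, k)
            meta.attrs["seed"] = self.seed
            meta.attrs["duration"] = self.duration
            meta.attrs["control_rate"] = self.control_rate
            meta.attrs["v_thresh"] = self.v_thresh
            for name in ("efferent", "afferent"):
                tr = getattr(self, name)
                g = f.create_group(name)
                d = g.create_dataset("voltage", data=tr.data, compression="gzip")
                d.attrs["fs"] = tr.fs
                d.attrs["units"] = "uV"
                d.attrs["band"] = tr.band
                d.attrs["electrode"] = tr.electrode
            robot = f.create_group("robot")
            robot.create_dataset("theta_d", data=self.theta_d)
            robot.create_dataset("theta", data=self.theta)
            robot.create_dataset("f_dc", data=self.force.f_dc)
            robot.create_dataset("f_ac", data=self.force.f_ac)
            robot.create_dataset("ttl", data=self.ttl)
            ev = f.create_group("events")
            ev.create_dataset("stim_times", data=self.stim_times)
            ev.create_dataset("encoder_triggers", data=self.encoder_triggers)
            ev.create_dataset("tap_times", data=self.tap_times)

    @classmethod
    def load(cls, path) -> "SessionRecord":
        with h5py.File(path, "r") as f:
            meta = f["meta"].attrs
            traces = {}
            for name in ("efferent", "afferent"):
                d = f[name]["voltage"]
                traces[name] = ElectrodeTrace(
                    data=d[...], fs=float(d.attrs["fs"]),
                    electrode=int(d.attrs["electrode"]), band=str(d.attrs["band"]),
                )
            cr = float(meta["control_rate"])
            force = ForceSignal(f["robot/f_dc"][...], f["robot/f_ac"][...], cr)
            return cls(
                mode=str(meta["mode"]), encoding=str(meta["encoding"]),
                div_label=str(meta["div_label"]), seed=int(meta["seed"]),
                duration=float(meta["duration"]), control_rate=cr,
                efferent=traces["efferent"], afferent=traces["afferent"],
                stim_times=f["events/stim_times"][...],
                encoder_triggers=f["events/encoder_triggers"][...],
                ttl=f["robot/ttl"][...], theta_d=f["robot/theta_d"][...],
                theta=f["robot/theta"][...], force=force,
                tap_times=f["events/tap_times"][...],
                v_thresh=float(meta["v_thresh"]),
            )


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def run_session(cfg: EmbodimentConfig) -> SessionRecord:
    """Execute one embodiment session and return its synchronized record."""
    net_seed, noise_seed, sensor_seed, drive_seed = _child_seeds(cfg.seed, 4)
    if cfg.culture_seed is not None:
        net_seed = _child_seeds(cfg.culture_seed, 1)[0]
    cc = cfg.culture
    net = CultureNetwork(cc, net_seed)
    if cfg.culture_seed is not None:
        # same culture, fresh session: re-seed the drive realization
        net.rng = np.random.default_rng(drive_seed)
    if cc.warmup_s > 0:  # let the network settle off-record
        net.advance(cc.warmup_s * 1000.0)
        net.t = 0.0
    fs = cc.fs
    rate = cfg.plant.control_rate
    n_ticks = int(round(cfg.duration * rate))
    spt = int(round(fs / rate))  # samples per tick
    acc = TraceAccumulator(
        [cc.efferent_electrode, cc.afferent_electrode], cfg.duration, cc, net,
        np.random.default_rng(noise_seed),
    )
    eff_trace = acc.traces[cc.efferent_electrode]
    v_thresh = (cfg.decoder.v_thresh if cfg.decoder.v_thresh is not None
                else 5.0 * cc.noise_rms)

    dec = cfg.decoder
    bin_ticks = max(1, int(round(dec.bin_size_ms * 1e-3 * rate)))
    ttl_ticks = max(1, int(round(dec.ttl_width_ms * 1e-3 * rate)))
    refractory = max(1, int(round(dec.refractory_ms * 1e-3 * fs)))

    plant_cfg = cfg.plant
    a_up = 1.0 - np.exp(-1000.0 / (rate * plant_cfg.servo_tau_ms))
    a_dn = 1.0 - np.exp(-1000.0 / (rate * plant_cfg.release_tau_ms))
    theta = plant_cfg.theta1
    enc_state = cfg.neuron.resting_state()
    enc_params = cfg.neuron
    enc_sub = max(1, int(round((1000.0 / rate) / enc_params.dt)))
    sensor_rng = np.random.default_rng(sensor_seed)

    stimulate = cfg.afferent_switch == "stimulate"
    bnn_driven = cfg.efferent_switch == "BNN-driven"

    ttl = np.zeros(n_ticks, dtype=np.uint8)
    theta_d_arr = np.empty(n_ticks)
    theta_arr = np.empty(n_ticks)
    f_dc_arr = np.empty(n_ticks)
    stim_times: list[float] = []
    enc_triggers: list[float] = []

    bin_count = 0
    pulse_end = -1           # tick index where the active TTL pulse ends
    last_det = -refractory   # sample index of the last detected spike
    stim_pending = False     # stimulation scheduled for the next tick (1-tick latency)
    ttl_state = 0            # TTL level applied to the plant (1-tick delayed)
    prev_f_dc = 0.0

    if not bnn_driven:
        tgrid = np.arange(n_ticks) / rate
        es_theta_d = es_waveform(tgrid, plant_cfg)

    for k in range(n_ticks):
        t = k / rate
        # 1) culture advances one tick; stimulation scheduled last tick lands now
        deliver = stimulate and stim_pending
        spikes = net.advance(1000.0 / rate, stim=deliver)
        stim_pending = False
        acc.add_spikes(spikes)
        if deliver:
            stim_times.append(t)
            acc.add_artifact(t)

        # 2) plant follows the (1-tick delayed) command
        theta_d = (dec.theta2 if ttl_state else dec.theta1) if bnn_driven else es_theta_d[k]
        theta += (a_up if theta_d >= theta else a_dn) * (theta_d - theta)
        theta_d_arr[k] = theta_d
        theta_arr[k] = theta
        f_dc = plant_cfg.contact_stiffness * max(0.0, theta - plant_cfg.theta_contact)
        if plant_cfg.sensor_noise_sd > 0:
            f_dc = max(0.0, f_dc + plant_cfg.sensor_noise_sd * sensor_rng.standard_normal())
        f_dc_arr[k] = f_dc
        f_ac = (f_dc - prev_f_dc) * rate
        prev_f_dc = f_dc

        # 3) decode this tick's efferent samples (threshold + refractory)
        if bnn_driven:
            seg = eff_trace[k * spt : (k + 1) * spt]
            above = np.flatnonzero(seg >= v_thresh)
            for i in above:
                s = k * spt + i
                if s - last_det >= refractory:
                    bin_count += 1
                    last_det = s
            if (k + 1) % bin_ticks == 0:
                # bins evaluated while a pulse is active cannot emit
                if (k + 1) >= pulse_end and bin_count >= dec.s_thres:
                    pulse_end = k + 1 + ttl_ticks
                bin_count = 0
            ttl_state = 1 if k + 1 < pulse_end else 0
            ttl[k] = 1 if k < pulse_end and pulse_end - k <= ttl_ticks else 0

        # 4) encoder converts this tick's forces into stimulation triggers
        I = compute_input_current(f_dc, f_ac, cfg.gains, cfg.encoding)
        for j in range(enc_sub):
            enc_state, spiked, _ = step_neuron(enc_state, I, enc_params)
            if spiked:
                enc_triggers.append(t + (j + 1) * enc_params.dt / 1000.0)
                stim_pending = True

    if not bnn_driven:
        ttl[:] = 0

    f_dc_arr = np.asarray(f_dc_arr)
    f_ac_centered = np.gradient(f_dc_arr) * rate
    force = ForceSignal(f_dc=f_dc_arr, f_ac=f_ac_centered, rate=rate)
    contact_cmd = (theta_d_arr > (plant_cfg.theta1 + plant_cfg.theta2) / 2).astype(np.int8)
    onsets = np.flatnonzero(np.diff(np.concatenate([[0], contact_cmd])) == 1)
    traces = acc.as_traces()
    return SessionRecord(
        mode=cfg.mode, encoding=cfg.encoding, div_label=cfg.div_label,
        seed=cfg.seed, duration=cfg.duration, control_rate=rate,
        efferent=traces[cc.efferent_electrode], afferent=traces[cc.afferent_electrode],
        stim_times=np.asarray(stim_times), encoder_triggers=np.asarray(enc_triggers),
        ttl=ttl, theta_d=theta_d_arr, theta=theta_arr, force=force,
        tap_times=onsets / rate, v_thresh=float(v_thresh),
    )


def record_baseline(duration: float = 300.0, seed: int = 0,
                    culture: CultureConfig = CultureConfig()) -> SessionRecord:
    """Spontaneous-activity baseline: no stimulation, no robot coupling."""
    from .culture import simulate_culture

    raster, traces = simulate_culture(culture, duration, seed)
    rate = 1000.0
    n = int(round(duration * rate))
    zeros = np.zeros(n)
    return SessionRecord(
        mode="baseline", encoding="none", div_label="baseline", seed=seed,
        duration=duration, control_rate=rate,
        efferent=traces[culture.efferent_electrode],
        afferent=traces[culture.afferent_electrode],
        stim_times=np.empty(0), encoder_triggers=np.empty(0),
        ttl=np.zeros(n, dtype=np.uint8), theta_d=zeros, theta=zeros,
        force=ForceSignal(zeros, zeros, rate), tap_times=np.empty(0),
        v_thresh=5.0 * culture.noise_rms,
    )


def run_protocol(
    n_div: int = 3,
    modes=MODES,
    encodings=ENCODINGS,
    base_seed: int = 0,
    duration: float = 300.0,
    dry_run: bool = False,
    culture: CultureConfig = CultureConfig(),
    **kwargs,
):
    """The full recording protocol: ``n_div x |modes| x |encodings|`` sessions.

    With the defaults (3 DIV, three embodiment modes, two encodings) this
    yields 18 session datasets.  Each session receives a distinct seed
    derived from ``base_seed``.  ``dry_run=True`` returns the planned
    :class:`EmbodimentConfig` list without simulating.
    """
    if n_div < 1:
        raise ValueError("n_div must be at least 1")
    plan = [(div, m, e) for div in range(n_div) for m in modes for e in encodings]
    seeds = _child_seeds(base_seed, len(plan) + n_div)
    div_cultures = seeds[len(plan):]  # one culture per recording day
    configs = [
        EmbodimentConfig(
            mode=m, encoding=e, seed=s, duration=duration,
            div_label=f"DIV{21 + div}", culture=culture,
            culture_seed=div_cultures[div], **kwargs,
        )
        for (div, m, e), s in zip(plan, seeds)
    ]
    if dry_run:
        return configs
    return [run_session(c) for c in configs]
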