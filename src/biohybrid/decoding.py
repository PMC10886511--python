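"""Efferent decoding: extracellular MEA activity -> finger-tap motor commands.

Three stages, mirroring the online controller:

1. amplitude thresholding of the recording-electrode trace separates spikes
   from background noise (``S = 1`` where ``V_MEA >= V_thresh``);
2. spike counts are aggregated over consecutive ``bin_size`` windows
   (50 ms); a bin reaching ``S_thres`` (3 spikes) emits one 100 ms TTL
   pulse, ``MEA_out``;
3. the TTL level selects the desired joint angle: ``theta2`` (fingertip
   contact) while a pulse is active, ``theta1`` (open hand) otherwise.

No multi-unit sorting is attempted: one efferent electrode, amplitude
thresholding only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["DecoderConfig", "TapCommandTimeline", "detect_spikes", "bin_and_trigger",
           "command_joint_angle", "decode_trace", "estimate_noise_rms"]


@dataclass(frozen=True)
class DecoderConfig:
    """Spike-detection and binning parameters of the efferent decoder.

    ``v_thresh=None`` selects the default of 5x the estimated noise RMS of
    the trace (the threshold must at minimum exceed stimulation crosstalk).
    """

    v_thresh: float | None = None   # uV
    bin_size_ms: float = 50.0
    s_thres: int = 3
    ttl_width_ms: float = 100.0
    theta1: float = 0.0             # open-hand angle, deg
    theta2: float = 45.0            # contact angle, deg
    refractory_ms: float = 1.0      # collapses one spike's samples into one event
    sliding: bool = False           # sliding-window binning variant

    def __post_init__(self):
        if self.bin_size_ms <= 0:
            raise ValueError("bin_size_ms must be positive")
        if self.s_thres < 1:
            raise ValueError("s_thres must be at least 1")
        if not self.theta2 > self.theta1:
            raise ValueError("theta2 must exceed theta1")


@dataclass(frozen=True)
class TapCommandTimeline:
    """Decoded motor command streams on the trace's sampling grid."""

    ttl: np.ndarray            # uint8 MEA_out level per sample
    theta_d: np.ndarray        # desired joint angle per sample (deg)
    pulse_onsets: np.ndarray   # seconds
    fs: float

    @property
    def tap_count(self) -> int:
        return self.pulse_onsets.size


def estimate_noise_rms(trace: np.ndarray) -> float:
    """Robust noise RMS via the median absolute deviation (spike-immune)."""
    trace = np.asarray(trace)
    return float(np.median(np.abs(trace - np.median(trace))) / 0.6745)


def detect_spikes(
    trace: np.ndarray,
    v_thresh: float,
    fs: float,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Binary spike series: 1 where ``V_MEA >= v_thresh`` (else 0).

    Consecutive suprathreshold samples within one refractory window are
    collapsed into a single event so a single action potential is not
    counted once per sample.
    """
    trace = np.asarray(trace, dtype=np.float32)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    noise = estimate_noise_rms(trace)
    if v_thresh <= noise:
        warnings.warn(
            f"v_thresh={v_thresh:.1f} uV is at or below the noise RMS "
            f"({noise:.1f} uV); crosstalk/noise may register as spikes",
            stacklevel=2,
        )
    above = np.flatnonzero(trace >= v_thresh)
    S = np.zeros(trace.size, dtype=np.uint8)
    if above.size == 0:
        return S
    dead = max(1, int(round(refractory_ms * 1e-3 * fs)))
    last = -dead
    for i in above:
        if i - last >= dead:
            S[i] = 1
            last = i
    return S


def bin_and_trigger(S: np.ndarray, config: DecoderConfig, fs: float) -> np.ndarray:
    """Aggregate the spike series into TTL pulse onsets (sample indices).

    Binning is tumbling by default (consecutive non-overlapping windows).
    A bin whose count reaches ``s_thres`` emits one pulse of
    ``ttl_width_ms``; bins evaluated while a pulse is still active cannot
    emit a new one.
    """
    S = np.asarray(S)
    n = S.size
    bin_n = max(1, int(round(config.bin_size_ms * 1e-3 * fs)))
    ttl_n = max(1, int(round(config.ttl_width_ms * 1e-3 * fs)))
    onsets = []
    pulse_end = -1
    if config.sliding:
        if n:
            csum = np.concatenate([[0], np.cumsum(S)])
            k = bin_n
            for i in range(n):
                if i < pulse_end:
                    continue
                lo = max(0, i - k + 1)
                if csum[i + 1] - csum[lo] >= config.s_thres:
                    onsets.append(i)
                    pulse_end = i + ttl_n
    else:
        for b in range(0, n, bin_n):
            end = min(b + bin_n, n)
            if end <= pulse_end:
                continue
            if int(S[b:end].sum()) >= config.s_thres:
                onsets.append(end - 1)
                pulse_end = end - 1 + ttl_n
    return np.asarray(onsets, dtype=np.int64)


def command_joint_angle(
    pulse_onsets: np.ndarray, n: int, config: DecoderConfig, fs: float
):
    """Expand pulse onsets into TTL and desired-joint-angle series.

    ``theta_d`` equals ``theta2`` while ``MEA_out = 1`` and ``theta1``
    otherwise.
    """
    ttl = np.zeros(n, dtype=np.uint8)
    ttl_n = max(1, int(round(config.ttl_width_ms * 1e-3 * fs)))
    for i in np.asarray(pulse_onsets, dtype=np.int64):
        ttl[i : i + ttl_n] = 1
    theta_d = np.where(ttl == 1, config.theta2, config.theta1)
    return ttl, theta_d


def decode_trace(trace: np.ndarray, fs: float, config: DecoderConfig = DecoderConfig()) -> TapCommandTimeline:
    """Full decode of one efferent trace into a tap-command timeline."""
    v_thresh = config.v_thresh
    if v_thresh is None:
        v_thresh = 5.0 * estimate_noise_rms(trace)
    S = detect_spikes(trace, v_thresh, fs, config.refractory_ms)
    onsets = bin_and_trigger(S, config, fs)
    ttl, theta_d = command_joint_angle(onsets, len(S), config, fs)
    return TapCommandTimeline(ttl=ttl, theta_d=theta_d, pulse_onsets=onsets / fs, fs=fs)
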