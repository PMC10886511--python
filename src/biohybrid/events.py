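"""Neurotactile event detection via CWT power envelopes.

The detector turns one extracellular trace into a normalized power envelope
and picks finger-tap events off it:

1. **ASP** — the complex-Morlet CWT is evaluated at log-spaced center
   frequencies spanning 100-4000 Hz and its magnitude squared;
2. **SASP** — ASP is divided by its global maximum (range 0-1) and the
   range clipped to [0.05, 0.4] to suppress artifacts (saturating by
   default: values below the floor are raised to it, above the ceiling
   lowered to it);
3. **MASP** — SASP is averaged across the frequency axis per time point,
   smoothed with a 50 ms moving mean, and renormalized to a maximum of 1;
4. events are local maxima of MASP exceeding 0.5 with a minimum peak
   distance of 0.5 s; successive event gaps are the inter-tap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from . import wavelets

__all__ = ["CWTConfig", "MASPSeries", "compute_asp", "scale_clip_masp",
           "compute_masp", "detect_events", "compute_iti", "events_from_session",
           "event_table"]


@dataclass(frozen=True)
class CWTConfig:
    wavelet_bandwidth: float = 1.5     # complex Morlet B
    wavelet_center: float = 1.0        # complex Morlet C
    f_lo: float = 100.0                # Hz
    f_hi: float = 4000.0               # Hz
    n_freqs: int = 64                  # log-spaced voices
    clip_lo: float = 0.05
    clip_hi: float = 0.4
    clip_mode: str = "saturate"        # or 'zero' (discard outside the range)
    smooth_ms: float = 50.0
    peak_threshold: float = 0.5        # on the normalized MASP
    min_peak_distance_s: float = 0.5
    chunk: int = 1 << 20               # CWT block size for long traces

    def __post_init__(self):
        if not (0 < self.clip_lo < self.clip_hi <= 1):
            raise ValueError("require 0 < clip_lo < clip_hi <= 1")
        if self.clip_mode not in ("saturate", "zero"):
            raise ValueError("clip_mode must be 'saturate' or 'zero'")

    def freqs(self) -> np.ndarray:
        return np.geomspace(self.f_lo, self.f_hi, self.n_freqs)

    def validate_band(self, fs: float) -> None:
        if self.f_hi > fs / 2:
            raise ValueError(
                f"wavelet band upper edge {self.f_hi} Hz exceeds Nyquist ({fs / 2} Hz)"
            )


@dataclass(frozen=True)
class MASPSeries:
    """Normalized mean amplitude-squared power envelope of one electrode."""

    values: np.ndarray
    fs: float
    electrode: int = -1

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float32))

    def __len__(self):
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


def _trace_array(trace):
    data = getattr(trace, "data", trace)
    fs = getattr(trace, "fs", None)
    return np.asarray(data), fs


def compute_asp(trace, fs: float | None = None, config: CWTConfig = CWTConfig()):
    """Amplitude-squared CWT power matrix ``(n_freqs, n_samples)``.

    ``trace`` may be an :class:`~biohybrid.culture.ElectrodeTrace` (its own
    sampling rate is used) or a plain array with ``fs`` given.
    """
    data, trace_fs = _trace_array(trace)
    fs = fs or trace_fs
    if fs is None:
        raise ValueError("sampling rate required")
    config.validate_band(fs)
    w = wavelets.cwt(data, fs, config.freqs(),
                     B=config.wavelet_bandwidth, C=config.wavelet_center)
    return (np.abs(w) ** 2).astype(np.float32)


def scale_clip_masp(asp: np.ndarray, fs: float, config: CWTConfig = CWTConfig()) -> MASPSeries:
    """SASP scaling, range clipping, frequency-mean, smoothing, renormalizing.

    An all-zero power matrix maps to an all-zero MASP (divide-by-zero
    guard).  "Mean across time and frequency" is taken as the frequency-axis
    mean per time point: averaging over both axes would collapse the series
    to a scalar and leave nothing to run peak detection on.
    """
    asp = np.asarray(asp)
    if asp.ndim != 2:
        raise ValueError("ASP must be 2-D (freqs x time)")
    if np.any(asp < 0):
        raise ValueError("ASP must be nonnegative")
    m = float(asp.max())
    if m == 0.0:
        return MASPSeries(np.zeros(asp.shape[1], dtype=np.float32), fs)
    sasp = asp / m
    if config.clip_mode == "saturate":
        sasp = np.clip(sasp, config.clip_lo, config.clip_hi)
    else:
        sasp = np.where((sasp < config.clip_lo) | (sasp > config.clip_hi), 0.0, sasp)
    masp = sasp.mean(axis=0)
    win = max(1, int(round(config.smooth_ms * 1e-3 * fs)))
    masp = uniform_filter1d(masp, size=win, mode="nearest")
    peak = masp.max()
    if peak > 0:
        masp = masp / peak
    return MASPSeries(masp.astype(np.float32), fs)


def compute_masp(trace, fs: float | None = None, config: CWTConfig = CWTConfig(),
                 electrode: int = -1) -> MASPSeries:
    """Memory-bounded MASP of a (possibly long) trace.

    Two passes over chunked CWT blocks: the first finds the global ASP
    maximum (the SASP normalizer), the second applies clipping and the
    frequency mean.  Results are identical to the in-memory path.
    """
    data, trace_fs = _trace_array(trace)
    fs = fs or trace_fs
    if fs is None:
        raise ValueError("sampling rate required")
    config.validate_band(fs)
    freqs = config.freqs()
    kw = dict(chunk=config.chunk, B=config.wavelet_bandwidth, C=config.wavelet_center)
    if data.size <= config.chunk:
        return scale_clip_masp(compute_asp(data, fs, config), fs, config)

    gmax = 0.0
    for _, p in wavelets.cwt_power_chunked(data, fs, freqs, reduce=np.max, **kw):
        gmax = max(gmax, float(p))
    if gmax == 0.0:
        return MASPSeries(np.zeros(data.size, dtype=np.float32), fs, electrode)
    masp = np.empty(data.size, dtype=np.float32)
    for start, p in wavelets.cwt_power_chunked(data, fs, freqs, **kw):
        s = p / gmax
        if config.clip_mode == "saturate":
            s = np.clip(s, config.clip_lo, config.clip_hi)
        else:
            s = np.where((s < config.clip_lo) | (s > config.clip_hi), 0.0, s)
        masp[start : start + s.shape[1]] = s.mean(axis=0)
    win = max(1, int(round(config.smooth_ms * 1e-3 * fs)))
    masp = uniform_filter1d(masp, size=win, mode="nearest")
    peak = masp.max()
    if peak > 0:
        masp /= peak
    return MASPSeries(masp, fs, electrode)


def detect_events(masp: MASPSeries, config: CWTConfig = CWTConfig()) -> np.ndarray:
    """Event timestamps (s): MASP maxima above threshold, min-distance apart.

    Within an exclusion window the larger peak wins (the standard peak
    pruning of ``scipy.signal.find_peaks``).
    """
    dist = max(1, int(round(config.min_peak_distance_s * masp.fs)))
    idx, _ = find_peaks(masp.values, height=config.peak_threshold, distance=dist)
    return idx / masp.fs


def compute_iti(event_times: np.ndarray) -> np.ndarray:
    """Inter-tap intervals: successive differences of event timestamps."""
    t = np.asarray(event_times, dtype=float)
    if t.size < 2:
        return np.empty(0)
    return np.diff(t)


def events_from_session(record, config: CWTConfig = CWTConfig(), channel: str = "efferent"):
    """Detect neurotactile events on a session's MASP envelope.

    Events are taken from the efferent envelope by default -- the signal
    that elicits finger taps; pass ``channel='afferent'`` to override.
    Returns ``(event_times, masp)``.
    """
    trace = getattr(record, channel)
    masp = compute_masp(trace, config=config, electrode=trace.electrode)
    return detect_events(masp, config), masp


def event_table(session_id: str, event_times: np.ndarray) -> pd.DataFrame:
    """Tidy event/ITI table for CSV export."""
    itis = np.concatenate([[np.nan], compute_iti(event_times)]) if len(event_times) else []
    return pd.DataFrame(
        {"session_id": session_id, "timestamp_s": event_times, "iti_s": itis}
    )
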