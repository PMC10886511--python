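"""Wavelet coherence between efferent and afferent power envelopes, and its
rendering as time-frequency images (TFIs).

Magnitude-squared wavelet coherence of two series x, y:

    C^2(s, t) = |S(W_x W_y*)|^2 / ( S(|W_x|^2) * S(|W_y|^2) )

with the analytic (complex) Morlet transform W and a smoothing operator S
acting along time (Gaussian, width proportional to scale) and across
neighboring scales (moving mean).  Without S the ratio is identically 1;
the smoothing window sets the effective number of independent cross-spectral
samples.  A cone of influence (COI) masks the edge-contaminated region.

Two views are produced, both operating on the 50 ms-smoothed MASP envelopes
(the session-level procedure; raw-trace coherence is available via
``on_masp=False`` for the event-band variant):

* **micro**: a 1 s window per neurotactile event (300 ms before to 700 ms
  after the timestamp) at the native 20 kHz rate, rendered as a 227x227x3
  image for classification;
* **macro**: the whole session, envelopes first anti-aliased and
  downsampled from 20 kHz to 2 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d, zoom
from scipy.signal import filtfilt, firwin

from . import wavelets

__all__ = ["CoherenceConfig", "TFIImage", "wavelet_coherence", "micro_event_tfi",
           "macro_session_tfi", "render_tfi", "save_tfi_png", "downsample_envelope"]


@dataclass(frozen=True)
class CoherenceConfig:
    micro_pre: float = 0.3        # s before the event timestamp
    micro_post: float = 0.7       # s after
    #: micro band covers the envelope's information-bearing frequencies; the
    #: 50 ms-smoothed MASP carries little structure above ~10^2 Hz and the
    #: COI removes everything below ~4 Hz in a 1 s window
    micro_f_lo: float = 4.0
    micro_f_hi: float = 64.0
    micro_n_freqs: int = 32
    macro_rate: float = 2000.0    # Hz after downsampling
    macro_f_lo: float = 0.1
    macro_f_hi: float = 100.0
    macro_n_freqs: int = 32
    apply_coi: bool = True
    image_size: int = 227
    colormap: str = "viridis"
    smooth_time_scales: float = 1.0   # moving-mean half-width in units of scale
    smooth_n_scales: int = 5          # moving-mean width across scales
    power_floor: float = 1e-3         # denominator regularization, per scale
    wavelet_bandwidth: float = 1.5
    wavelet_center: float = 1.0

    def __post_init__(self):
        if not np.isclose(self.micro_pre + self.micro_post, 1.0):
            raise ValueError("the micro event window must span exactly 1 s")


@dataclass(frozen=True)
class TFIImage:
    """A rendered coherence image for one neurotactile event."""

    pixels: np.ndarray        # (size, size, 3) uint8
    event_time: float
    mode: str = ""
    encoding: str = ""
    div_label: str = ""
    event_id: int = -1

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("TFI pixels must be (H, W, 3)")
        object.__setattr__(self, "pixels", px.astype(np.uint8))


def _smooth(mat: np.ndarray, scales: np.ndarray, cfg: CoherenceConfig) -> np.ndarray:
    """Scale-dependent time smoothing then cross-scale moving mean.

    Time smoothing is a moving mean of width ~2x the scale (a running sum,
    so the cost is independent of the window width); scale smoothing is a
    moving mean over neighboring voices.
    """

    def box(row, win):
        return uniform_filter1d(row, size=win, mode="nearest")

    out = np.empty_like(mat)
    for i, s in enumerate(scales):
        win = max(3, int(round(2.0 * cfg.smooth_time_scales * s)))
        if np.iscomplexobj(mat):
            out[i] = box(mat[i].real, win) + 1j * box(mat[i].imag, win)
        else:
            out[i] = box(mat[i], win)
    if cfg.smooth_n_scales > 1:
        out = uniform_filter1d(out.real, size=cfg.smooth_n_scales, axis=0, mode="nearest") + (
            1j * uniform_filter1d(out.imag, size=cfg.smooth_n_scales, axis=0, mode="nearest")
            if np.iscomplexobj(out) else 0.0
        )
    return out


def coi_mask(n: int, fs: float, freqs: np.ndarray, cfg: CoherenceConfig) -> np.ndarray:
    """Boolean mask, True where (freq, time) is inside the cone of influence."""
    tcoi = wavelets.coi_time(freqs, fs, cfg.wavelet_bandwidth, cfg.wavelet_center)
    t = np.arange(n) / fs
    edge = np.minimum(t, (n - 1) / fs - t)
    return edge[None, :] >= tcoi[:, None]


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    config: CoherenceConfig = CoherenceConfig(),
):
    """Magnitude-squared wavelet coherence of two equal-length series.

    Returns ``(coherence, inside_coi)``: a matrix in [0, 1] of shape
    ``(len(freqs), len(x))`` and the COI validity mask.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("coherence inputs must have equal length")
    freqs = np.asarray(freqs, dtype=float)
    B, C = config.wavelet_bandwidth, config.wavelet_center
    wx = wavelets.cwt(x - x.mean(), fs, freqs, B, C)
    wy = wavelets.cwt(y - y.mean(), fs, freqs, B, C)
    scales = wavelets.morlet_scales(freqs, fs, C)
    sxy = _smooth((wx * np.conj(wy)).astype(np.complex64), scales, config)
    sxx = _smooth((np.abs(wx) ** 2).astype(np.float64), scales, config)
    syy = _smooth((np.abs(wy) ** 2).astype(np.float64), scales, config)
    # regularized estimator: a small per-scale power floor keeps segments
    # with no genuine signal (auto-spectra at numerical zero) at coherence
    # ~0 instead of an ill-conditioned 0/0
    eps_x = config.power_floor * sxx.max(axis=1, keepdims=True) + 1e-12
    eps_y = config.power_floor * syy.max(axis=1, keepdims=True) + 1e-12
    denom = (sxx + eps_x) * (syy + eps_y)
    coh = (np.abs(sxy) ** 2) / denom
    coh = np.clip(coh, 0.0, 1.0)
    return coh, coi_mask(x.size, fs, freqs, config)


def render_tfi(coh: np.ndarray, config: CoherenceConfig = CoherenceConfig(),
               inside_coi: np.ndarray | None = None) -> np.ndarray:
    """Render a coherence matrix as a fixed-colormap uint8 RGB image.

    The coherence color scale is pinned to [0, 1]; the frequency axis runs
    low-to-high from the bottom row up; no axes or labels.  COI-excluded
    pixels are zeroed before rendering when a mask is given.  Identical
    matrices render byte-identically.
    """
    import matplotlib

    m = np.asarray(coh, dtype=np.float64)
    if inside_coi is not None and config.apply_coi:
        m = np.where(inside_coi, m, 0.0)
    size = config.image_size
    zy = size / m.shape[0]
    zx = size / m.shape[1]
    img = zoom(m, (zy, zx), order=1, mode="nearest", grid_mode=True)
    img = np.clip(img[:size, :size], 0.0, 1.0)
    img = np.flipud(img)  # low frequency at the bottom
    cmap = matplotlib.colormaps[config.colormap]
    rgb = (cmap(img)[:, :, :3] * 255).round().astype(np.uint8)
    return rgb


def save_tfi_png(tfi: TFIImage, path) -> None:
    from PIL import Image

    Image.fromarray(tfi.pixels, mode="RGB").save(path, format="PNG")


def micro_event_tfi(
    masp_eff,
    masp_aff,
    event_time: float,
    config: CoherenceConfig = CoherenceConfig(),
    mode: str = "",
    encoding: str = "",
    div_label: str = "",
    event_id: int = -1,
) -> TFIImage | None:
    """Coherence TFI of one neurotactile event.

    Extracts the [t - 0.3 s, t + 0.7 s] window of both MASP envelopes at
    their native rate, computes the wavelet coherence, and renders the
    fixed-colormap image.  Events whose window is clipped by the session
    edge are skipped (``None``).
    """
    fs = masp_eff.fs
    if fs != masp_aff.fs:
        raise ValueError("envelope rates differ")
    i0 = int(round((event_time - config.micro_pre) * fs))
    i1 = i0 + int(round(fs))  # exactly 1 s of samples
    if i0 < 0 or i1 > len(masp_eff):
        return None
    freqs = np.geomspace(config.micro_f_lo, config.micro_f_hi, config.micro_n_freqs)
    coh, inside = wavelet_coherence(
        masp_eff.values[i0:i1], masp_aff.values[i0:i1], fs, freqs, config
    )
    rgb = render_tfi(coh, config, inside)
    return TFIImage(pixels=rgb, event_time=event_time, mode=mode,
                    encoding=encoding, div_label=div_label, event_id=event_id)


def downsample_envelope(values: np.ndarray, fs: float, target: float) -> np.ndarray:
    """Anti-aliased integer-factor downsampling (FIR low-pass at 0.8x the
    target Nyquist, zero-phase, then decimation)."""
    q = fs / target
    if abs(q - round(q)) > 1e-9:
        raise ValueError("downsampling requires an integer factor")
    q = int(round(q))
    if q == 1:
        return np.asarray(values, dtype=np.float64)
    taps = firwin(121, 0.8 * (target / 2), fs=fs)
    filt = filtfilt(taps, [1.0], np.asarray(values, dtype=np.float64))
    return filt[::q]


def macro_session_tfi(masp_eff, masp_aff, config: CoherenceConfig = CoherenceConfig()):
    """Whole-session coherence of the downsampled envelopes.

    Returns ``(freqs, coherence, inside_coi, rgb_image)``.
    """
    fs = masp_eff.fs
    x = downsample_envelope(masp_eff.values, fs, config.macro_rate)
    y = downsample_envelope(masp_aff.values, fs, config.macro_rate)
    freqs = np.geomspace(config.macro_f_lo, config.macro_f_hi, config.macro_n_freqs)
    coh, inside = wavelet_coherence(x, y, config.macro_rate, freqs, config)
    rgb = render_tfi(coh, config, inside)
    return freqs, coh, inside, rgb
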