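"""Fast complex-Morlet continuous wavelet transform.

Single-precision, frequency-domain implementation shared by the event
pipeline (scalograms of 20 kHz extracellular traces) and the coherence
module.  The wavelet is the complex Morlet ``cmorB-C``

    psi(t) = (pi*B)^(-1/2) * exp(2j*pi*C*t) * exp(-t**2 / B)

with bandwidth parameter ``B`` and center frequency ``C`` (both in wavelet
units).  Scales are chosen so that the wavelet's center frequency lands on
the requested analysis frequencies.  Coefficients use L1 normalization
(``psi/s``), so a unit-amplitude tone yields the same coefficient magnitude
at every analysis frequency -- convenient when averaging power across a
frequency band.

The transform is evaluated scale-by-scale in the frequency domain, reusing
one FFT of the (padded) signal across all scales.  For long signals
:func:`cwt_power_chunked` bounds memory by processing overlapping chunks.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

__all__ = [
    "morlet_scales",
    "morlet_support",
    "cwt",
    "cwt_power_chunked",
    "coi_time",
]

#: default complex Morlet shape parameters (matches pywt's 'cmor1.5-1.0')
DEFAULT_B = 1.5
DEFAULT_C = 1.0

# Half-support of the sampled wavelet, in units of the Gaussian envelope's
# standard deviation sqrt(B/2); 6 sigma truncates the envelope below 2e-8.
_SUPPORT_SIGMAS = 6.0


def morlet_scales(freqs: np.ndarray, fs: float, C: float = DEFAULT_C) -> np.ndarray:
    """Scales (in samples) putting the wavelet center frequency at ``freqs``."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs > fs / 2):
        raise ValueError("analysis frequencies must lie in (0, fs/2]")
    return C * fs / freqs


def morlet_support(scale: float, B: float = DEFAULT_B) -> int:
    """Half-length (samples) of the truncated wavelet at ``scale``."""
    return int(np.ceil(_SUPPORT_SIGMAS * np.sqrt(B / 2.0) * scale))


def _kernel_ffts(scales, nfft, B, C):
    kernels = []
    for s in scales:
        m = morlet_support(s, B)
        t = np.arange(-m, m + 1) / s
        psi = (np.pi * B) ** -0.5 * np.exp(2j * np.pi * C * t) * np.exp(-(t**2) / B)
        psi = (psi / s).astype(np.complex64)  # L1 normalization
        # correlation with psi == convolution with conj(reversed psi)
        kernels.append((m, sfft.fft(np.conj(psi[::-1]), nfft)))
    return kernels


def cwt(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    B: float = DEFAULT_B,
    C: float = DEFAULT_C,
) -> np.ndarray:
    """Complex Morlet CWT of ``x`` at analysis frequencies ``freqs``.

    Returns an array of shape ``(len(freqs), len(x))``, complex64.
    """
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("cwt expects a 1-D signal")
    scales = morlet_scales(freqs, fs, C)
    n = x.size
    if n < 2 * morlet_support(scales.min(), B):
        raise ValueError("signal shorter than the shortest wavelet support")
    pad = morlet_support(scales.max(), B)
    nfft = sfft.next_fast_len(n + 2 * pad, real=False)
    X = sfft.fft(x.astype(np.complex64), nfft)
    out = np.empty((len(scales), n), dtype=np.complex64)
    for i, (m, K) in enumerate(_kernel_ffts(scales, nfft, B, C)):
        y = sfft.ifft(X * K, nfft)
        out[i] = y[m : m + n]
    return out


def cwt_power_chunked(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    chunk: int = 1 << 20,
    B: float = DEFAULT_B,
    C: float = DEFAULT_C,
    reduce=None,
):
    """Yield ``(start, |W|**2)`` blocks of the scalogram of a long signal.

    Chunks overlap by the largest wavelet support so every returned sample
    is free of chunk-boundary error.  ``reduce`` may be a callable applied
    to each power block before yielding (e.g. a frequency-axis mean).
    """
    x = np.asarray(x)
    n = x.size
    scales = morlet_scales(freqs, fs, C)
    halo = morlet_support(scales.max(), B)
    if n <= chunk:
        p = np.abs(cwt(x, fs, freqs, B, C)) ** 2
        yield 0, (reduce(p) if reduce is not None else p)
        return
    start = 0
    while start < n:
        stop = min(start + chunk, n)
        lo = max(0, start - halo)
        hi = min(n, stop + halo)
        w = cwt(x[lo:hi], fs, freqs, B, C)
        p = np.abs(w[:, start - lo : stop - lo]) ** 2
        yield start, (reduce(p) if reduce is not None else p)
        start = stop


def coi_time(freqs: np.ndarray, fs: float, B: float = DEFAULT_B, C: float = DEFAULT_C) -> np.ndarray:
    """Cone-of-influence extent (seconds from the record edge) per frequency.

    Uses the e^-2 power folding time of the Gaussian envelope: power of an
    edge discontinuity decays by e^-2 at ``t = s*sqrt(B)`` samples.
    """
    scales = morlet_scales(np.asarray(freqs, dtype=float), fs, C)
    return scales * np.sqrt(B) / fs
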