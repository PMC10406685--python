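"""Shared FFT conventions.

Frequency axes run from high to low frequency with increasing index
(index 0 holds the highest-frequency bin), matching the usual display
orientation of NMR spectra.  All transforms are unitary ("ortho" norm),
so white noise keeps its standard deviation across a transform and
Parseval's identity holds without bookkeeping factors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spectrum_from_time",
    "time_from_spectrum",
    "freq_axis",
    "hz_to_index",
    "cos2_window",
    "gaussian_envelope",
    "symmetric_gaussian_envelope",
]


def spectrum_from_time(x: np.ndarray, n_out: int | None = None, axis: int = -1) -> np.ndarray:
    """Unitary FFT with the package's frequency ordering (high -> low Hz)."""
    X = np.fft.fft(x, n=n_out, axis=axis, norm="ortho")
    X = np.fft.fftshift(X, axes=axis)
    return np.flip(X, axis=axis)


def time_from_spectrum(X: np.ndarray, axis: int = -1) -> np.ndarray:
    """Exact inverse of :func:`spectrum_from_time` at matched length."""
    Y = np.flip(X, axis=axis)
    Y = np.fft.ifftshift(Y, axes=axis)
    return np.fft.ifft(Y, axis=axis, norm="ortho")


def freq_axis(n: int, spectral_width: float) -> np.ndarray:
    """Frequency (Hz, offset from carrier) of each spectral index."""
    df = spectral_width / n
    return spectral_width / 2.0 - df - np.arange(n) * df


def hz_to_index(f: float, n: int, spectral_width: float) -> int:
    """Nearest spectral index for a frequency offset in Hz."""
    df = spectral_width / n
    return int(round((spectral_width / 2.0 - df - f) / df))


def cos2_window(n: int) -> np.ndarray:
    """Cosine-squared apodization, 1 at t=0, approaching 0 at the last point."""
    return np.cos(np.pi * np.arange(n) / (2.0 * n)) ** 2


def gaussian_envelope(n: int, spectral_width: float, sigma_hz: float) -> np.ndarray:
    """Time-domain envelope whose spectral effect is convolution with a
    unit-area Gaussian of standard deviation ``sigma_hz``."""
    t = np.arange(n) / spectral_width
    return np.exp(-2.0 * np.pi**2 * sigma_hz**2 * t**2)


def symmetric_gaussian_envelope(n: int, spectral_width: float, sigma_hz: float) -> np.ndarray:
    """As :func:`gaussian_envelope` but on the circular time grid of an
    inverse-transformed spectrum, where index k > n/2 represents time -(n-k)."""
    k = np.arange(n)
    t = np.minimum(k, n - k) / spectral_width
    return np.exp(-2.0 * np.pi**2 * sigma_hz**2 * t**2)
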