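"""Classical single-number discriminators computed per 2-s window.

Four scores are compared against the CNN by ROC/AUC: the peak and average
rectified amplitudes, the power at the spectral fundamental ("central
frequency intensity"), and the width of the contiguous half-power band
around the fundamental.  The spectrum is a one-sided FFT power spectrum of
the mean-removed, un-tapered signal (0.5 Hz bins for a 2-s window); the
fundamental is the highest-power non-DC bin, ties broken toward the lowest
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import DUS_RATE_HZ
from .signals import Window

ArrayLike = Union[Window, np.ndarray, list]


class SilentWindowError(ValueError):
    """Raised when a spectral score is requested for an all-zero window."""


def _samples(w: ArrayLike) -> np.ndarray:
    x = w.samples if isinstance(w, Window) else np.asarray(w, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty window")
    return np.asarray(x, dtype=np.float64)


@dataclass
class SpectrumResult:
    """One-sided power spectrum; sum of per-bin power equals signal energy."""

    frequencies: np.ndarray
    power: np.ndarray


@dataclass
class BaselineScores:
    peak_amplitude: float
    average_amplitude: float
    central_frequency_intensity: Optional[float]
    half_power_band_width_hz: Optional[float]


def peak_amplitude(w: ArrayLike) -> float:
    """Maximum rectified amplitude of the window."""
    return float(np.max(np.abs(_samples(w))))


def average_amplitude(w: ArrayLike) -> float:
    """Mean rectified amplitude of the window."""
    return float(np.mean(np.abs(_samples(w))))


def power_spectrum(w: ArrayLike) -> SpectrumResult:
    """One-sided FFT power spectrum of the mean-removed signal.

    Normalised so that the power bins sum to the energy (sum of squares) of
    the mean-removed signal; no taper or detrending beyond mean removal.
    """
    x = _samples(w)
    x = x - x.mean()
    n = x.size
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n
    # double interior bins to fold the negative frequencies in
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / DUS_RATE_HZ)
    return SpectrumResult(frequencies=freqs, power=power)


def _fundamental_bin(spec: SpectrumResult) -> int:
    if not np.any(spec.power[1:] > 0):
        raise SilentWindowError("silent window: spectral scores are undefined")
    return 1 + int(np.argmax(spec.power[1:]))  # argmax takes the first (lowest) on ties


def central_frequency_intensity(w: ArrayLike) -> float:
    """Power at the fundamental: the highest-power non-DC spectral bin."""
    spec = power_spectrum(w)
    return float(spec.power[_fundamental_bin(spec)])


def half_power_band_width(w: ArrayLike) -> float:
    """Width (Hz) of the contiguous band around the fundamental with power
    at least half the central-frequency intensity.

    Band edges are located by linear interpolation of power between the last
    bin inside the band and the first bin outside it; the band is clamped to
    the spectrum's 0-500 Hz support.
    """
    spec = power_spectrum(w)
    k = _fundamental_bin(spec)
    return _half_power_width(spec.frequencies, spec.power, k)


def _half_power_width(freqs: np.ndarray, power: np.ndarray, k: int) -> float:
    half = power[k] / 2.0
    df = freqs[1] - freqs[0]
    lo = k
    while lo > 0 and power[lo - 1] >= half:
        lo -= 1
    hi = k
    last = len(power) - 1
    while hi < last and power[hi + 1] >= half:
        hi += 1
    if lo > 0:
        # interpolate between bins lo-1 (below half) and lo (at/above half)
        frac = (half - power[lo - 1]) / (power[lo] - power[lo - 1])
        left = freqs[lo - 1] + frac * df
    else:
        left = freqs[0]
    if hi < last:
        frac = (power[hi] - half) / (power[hi] - power[hi + 1])
        right = freqs[hi] + frac * df
    else:
        right = freqs[last]
    return float(right - left)


def score_window(w: ArrayLike) -> BaselineScores:
    """All four scores; spectral scores are None for a silent window."""
    x = _samples(w)
    try:
        cfi: Optional[float] = central_frequency_intensity(x)
        hpbw: Optional[float] = half_power_band_width(x)
    except SilentWindowError:
        cfi = hpbw = None
    return BaselineScores(
        peak_amplitude=peak_amplitude(x),
        average_amplitude=average_amplitude(x),
        central_frequency_intensity=cfi,
        half_power_band_width_hz=hpbw,
    )


SCORE_COLUMNS = ("peak", "avg", "cfi", "hpbw")


def score_matrix(x: np.ndarray) -> pd.DataFrame:
    """Vectorised scores for a stack of windows, one row per window."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a (n_windows, n_samples) matrix")
    n, length = x.shape
    absx = np.abs(x)
    peak = absx.max(axis=1)
    avg = absx.mean(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(xc, axis=1)) ** 2 / length
    if length % 2 == 0:
        spec[:, 1:-1] *= 2.0
    else:
        spec[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(length, d=1.0 / DUS_RATE_HZ)
    cfi = np.full(n, np.nan)
    hpbw = np.full(n, np.nan)
    for i in range(n):
        if np.any(spec[i, 1:] > 0):
            k = 1 + int(np.argmax(spec[i, 1:]))
            cfi[i] = spec[i, k]
            hpbw[i] = _half_power_width(freqs, spec[i], k)
    return pd.DataFrame({"peak": peak, "avg": avg, "cfi": cfi, "hpbw": hpbw})
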