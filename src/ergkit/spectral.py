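"""Discrete-Fourier-transform tools.

:func:`psd` is a plain rectangular-window periodogram of the mean-detrended
trace — ERG epochs are short, so no Welch segmenting or tapering by
default.  The normalization is Parseval-consistent: the power density
integrates (sum × Δf) to the trace variance.  :func:`flicker_fundamental`
measures the steady-state flicker response as the single-bin DFT at the
stimulus frequency over a whole number of stimulus cycles, which makes it
exactly orthogonal to harmonics and to any other integer-cycle component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .exceptions import ValidationError

__all__ = ["Spectrum", "psd", "peak_frequency", "flicker_fundamental"]


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density in µV²/Hz."""

    freqs_hz: np.ndarray
    power: np.ndarray
    n_samples: int
    sampling_rate_hz: float

    @property
    def df_hz(self) -> float:
        return self.sampling_rate_hz / self.n_samples

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"freq_hz": self.freqs_hz, "power": self.power})


def psd(trace: np.ndarray, sampling_rate_hz: float, window: str = "boxcar") -> Spectrum:
    """One-sided periodogram of the mean-detrended trace.

    ``sum(power) * Δf`` equals the sample variance of the trace (DC and
    Nyquist bins are not doubled).
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size < 8:
        raise ValidationError("trace must have at least 8 samples")
    if not np.isfinite(x).all():
        raise ValidationError("trace contains non-finite samples")
    freqs, pxx = periodogram(
        x,
        fs=sampling_rate_hz,
        window=window,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    return Spectrum(freqs, pxx, n_samples=x.size, sampling_rate_hz=float(sampling_rate_hz))


def peak_frequency(
    spectrum: Spectrum, fmin_hz: float = 0.0, fmax_hz: float | None = None
) -> tuple[float, float]:
    """Frequency and power of the strongest component in [fmin, fmax].

    Ties resolve to the lowest frequency.
    """
    fmax_hz = spectrum.freqs_hz[-1] if fmax_hz is None else fmax_hz
    sel = (spectrum.freqs_hz >= fmin_hz) & (spectrum.freqs_hz <= fmax_hz)
    if not sel.any():
        raise ValidationError(
            f"band [{fmin_hz}, {fmax_hz}] Hz contains no spectral bins"
        )
    f = spectrum.freqs_hz[sel]
    p = spectrum.power[sel]
    k = int(np.argmax(p))  # argmax returns the first (lowest-frequency) tie
    return float(f[k]), float(p[k])


def flicker_fundamental(
    trace: np.ndarray, sampling_rate_hz: float, stim_freq_hz: float
) -> tuple[float, float]:
    """Amplitude (µV) and phase (rad) of the response at the flicker rate.

    The analysis window is trimmed to a whole number of stimulus cycles,
    then a single-bin DFT at ``stim_freq_hz`` is evaluated: amplitude is
    ``2|X|/N`` (peak amplitude of the fundamental), phase is
    cosine-referenced in (−π, π].  Requires at least 2 full cycles.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if not (stim_freq_hz > 0):
        raise ValidationError("stim_freq_hz must be > 0")
    n_cycles = int(np.floor(x.size * stim_freq_hz / sampling_rate_hz))
    if n_cycles < 2:
        raise ValidationError(
            f"trace holds {n_cycles} full cycles of {stim_freq_hz} Hz; need >= 2"
        )
    n = int(np.floor(n_cycles * sampling_rate_hz / stim_freq_hz))
    seg = x[:n] - x[:n].mean()
    k = np.arange(n)
    phasor = np.exp(-2j * np.pi * stim_freq_hz * k / sampling_rate_hz)
    X = np.sum(seg * phasor)
    amplitude = 2.0 * np.abs(X) / n
    phase = float(np.angle(X))
    if phase <= -np.pi:
        phase += 2 * np.pi
    return float(amplitude), phase
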