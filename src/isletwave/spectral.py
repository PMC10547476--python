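"""Periodogram spectral summary of Ca2+ segments.

Complex oscillations often superimpose a metabolically driven slow
component and an electrically driven fast component.  The mean-removed
rectangular-window periodogram of each segment is reduced to the top two
component frequencies and their powers ("amplitudes"); a guard band keeps
the second component from being a leakage sidelobe of the first.

The estimator is normalised so total power equals the signal variance
(Parseval, population convention).  Powers are periodogram values at the
selected bin, not square-rooted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .traceio import Trace

__all__ = ["SpectralSummary", "power_spectrum", "top_components"]


@dataclass
class SpectralSummary:
    islet_id: str
    segment_label: str
    freq1: float  # 1/min
    amp1: float  # power units (signal units squared)
    freq2: float  # nan when no valid second bin
    amp2: float
    resolution: float  # bin spacing, 1/min


def power_spectrum(trace: Trace, welch: bool = False, nperseg: int | None = None):
    """One-sided power spectrum on the grid k/(N*dt), k = 1..N/2.

    The mean is removed (zero frequency excluded) and the estimator is
    scaled so ``sum(power) == var(values)`` (population variance) for the
    default rectangular-window periodogram.  ``welch=True`` switches to
    Welch averaging for long/noisy records at the cost of resolution.

    Returns ``(frequencies, power)``.
    """
    dt = trace.sampling_interval  # validates uniformity on construction
    x = trace.values.astype(float)
    n = x.size
    if n < 32:
        raise ValueError("need at least 32 frames for a spectrum")
    if welch:
        from scipy.signal import welch as _welch

        freqs, pxx = _welch(
            x, fs=1.0 / dt, nperseg=nperseg or min(n, 256), detrend="constant", scaling="spectrum"
        )
        return freqs[1:], pxx[1:]
    x = x - x.mean()
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    power[1 : (n + 1) // 2] *= 2.0  # one-sided doubling, Nyquist bin excluded
    freqs = np.arange(power.size) / (n * dt)
    return freqs[1:], power[1:]


def top_components(
    freqs: np.ndarray,
    power: np.ndarray,
    min_separation: int = 2,
    islet_id: str = "",
    segment_label: str = "",
) -> SpectralSummary:
    """Top two spectral components with a sidelobe guard band.

    freq1 is the argmax of power (ties resolve to the lower frequency);
    freq2 is the argmax over bins at least ``min_separation`` bins away
    from freq1.  When no valid second bin exists, freq2/amp2 are missing.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    if freqs.size == 0:
        raise ValueError("empty spectrum")
    resolution = float(freqs[1] - freqs[0]) if freqs.size > 1 else float(freqs[0])
    k1 = int(np.argmax(power))  # first max == lowest frequency on exact tie
    mask = np.abs(np.arange(power.size) - k1) >= min_separation
    if mask.any():
        cand = np.flatnonzero(mask)
        k2 = int(cand[np.argmax(power[cand])])
        freq2, amp2 = float(freqs[k2]), float(power[k2])
    else:
        freq2, amp2 = math.nan, math.nan
    return SpectralSummary(
        islet_id=islet_id,
        segment_label=segment_label,
        freq1=float(freqs[k1]),
        amp1=float(power[k1]),
        freq2=freq2,
        amp2=amp2,
        resolution=resolution,
    )
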