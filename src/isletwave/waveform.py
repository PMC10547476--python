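"""Waveform decomposition of islet Ca2+ condition segments.

Each detrended segment is decomposed into pulses (maximal runs above 50% of
the robust peak amplitude that contain a prominent local maximum) and
summarized by six parameters:

* peak        -- mean oscillation maximum (ratio units);
* period      -- mean spacing between consecutive complete pulses (min);
* A_D         -- active duration: mean per-pulse time above the 50% level;
* P_D         -- pulse duration: mean pulse width at a near-baseline level,
                 i.e. the active duration plus the Ca2+-extrusion tail;
* S_D         -- silent duration: period - A_D (exact, by construction);
* P_F         -- plateau fraction: A_D / period, the secretory-phase share.

Edge cases follow the standard assignment scheme: a segment that plateaus
(no pulses, elevated mean) gets P_F = 1, period = 0, A_D = P_D = the
segment length; a segment that is silent at baseline gets P_F = 0,
A_D = P_D = 0 and period = the segment length.  Oscillating segments are
classed fast (period < 2 min) or slow (2-10 min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .traceio import Trace

__all__ = [
    "DetrendSettings",
    "Pulse",
    "OscillationParams",
    "detrend_segment",
    "detect_oscillations",
    "compute_waveform_params",
    "classify_speed",
    "summarize_animal",
    "segment_baseline",
]

#: Crossing level for the active duration, as a fraction of peak amplitude.
THRESHOLD_FRAC = 0.5
#: Fast/slow period boundary (minutes).
FAST_CUTOFF = 2.0
#: Upper period bound for a 'slow' classification (minutes).
SLOW_UPPER = 10.0


@dataclass(frozen=True)
class DetrendSettings:
    """How to remove slow drift before pulse detection.

    ``moving_median`` estimates the trend with a centred rolling median
    (window defaulting to 3x the segment's dominant period, capped at half
    the segment) polished by a same-window rolling mean; ``linear`` removes
    a least-squares line.  ``preserve_mean`` restores the original segment
    mean so average-signal statistics stay comparable across segments.
    """

    method: str = "moving_median"
    window: float | None = None  # minutes; None = 3x dominant period (fallback 10)
    preserve_mean: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("linear", "moving_median"):
            raise ValueError(f"unknown detrend method {self.method!r}")


def _dominant_period(values: np.ndarray, dt: float) -> float | None:
    x = values - values.mean()
    n = x.size
    if n < 32 or np.allclose(x, 0):
        return None
    power = np.abs(np.fft.rfft(x)) ** 2
    power[0] = 0.0
    k = int(np.argmax(power))
    if k == 0 or power[k] <= 0:
        return None
    return n * dt / k


def detrend_segment(trace: Trace, settings: DetrendSettings | None = None) -> Trace:
    """Remove slow drift from one segment.

    Linear detrending is idempotent on its own output; moving-median
    detrending leaves a constant trace unchanged (with ``preserve_mean``).
    """
    settings = settings or DetrendSettings()
    t, x = trace.time, trace.values
    dt = trace.sampling_interval
    if settings.method == "linear":
        coef = np.polyfit(t, x, 1)
        detrended = x - np.polyval(coef, t)
    else:
        window = settings.window
        auto = window is None
        period = _dominant_period(x, dt)
        if auto:
            window = 3.0 * period if period is not None else 10.0
            window = max(window, 5.0 * dt)
        if window < 5.0 * dt:
            raise ValueError("moving-median window must span at least 5 sampling intervals")
        w = int(round(window / dt))
        if auto:
            w = min(w, x.size // 2)
        w = max(w - (w + 1) % 2, 5)  # odd, >= 5 frames
        if x.size < 2 * w:
            raise ValueError("segment too short for the moving-median window")
        # one-period moving average first: it cancels the oscillation itself
        # (any periodic component sums to a constant over a full period)
        # while preserving linear drift; the moving median then smooths the
        # residual cycle average robustly.  Applying the median directly to
        # the raw wave is unstable near duty 0.5, where the window's active
        # fraction hovers at 1/2 and the median flips between burst top and
        # baseline.
        if period is not None:
            w_mean = int(round(period / dt))
        else:
            w_mean = w // 3
        w_mean = int(np.clip(w_mean, 3, x.size // 2))
        # reflect-pad so the rolling windows stay full at the segment edges;
        # truncated windows would bias the trend over the first/last w/2
        # frames and leak into the percentile thresholds downstream
        pad = w
        s = pd.Series(np.pad(x, pad, mode="reflect"))
        trend = s.rolling(w_mean, center=True, min_periods=1).mean()
        trend = trend.rolling(w, center=True, min_periods=1).median().to_numpy()
        detrended = x - trend[pad : pad + x.size]
    if settings.preserve_mean:
        detrended = detrended + x.mean() - detrended.mean()
    return trace.with_values(detrended)


@dataclass(frozen=True)
class Pulse:
    """One supra-threshold oscillation."""

    start: float  # up-crossing time at the 50% level (min)
    end: float  # down-crossing time at the 50% level (min)
    peak_time: float
    peak_value: float
    base_start: float  # up-crossing at the near-baseline pulse level
    base_end: float
    complete: bool  # not clipped by a segment edge

    @property
    def active_duration(self) -> float:
        return self.end - self.start

    @property
    def pulse_duration(self) -> float:
        return self.base_end - self.base_start


def _noise_sigma(x: np.ndarray) -> float:
    """Robust white-noise sigma for a segment.

    Two estimators, take the smaller: the MAD of first differences (exact
    for slow signals, but inflated when a fast oscillation puts transitions
    in a large share of the diffs) and the median periodogram ordinate
    (immune to periodic signals, whose harmonics occupy sparse bins, but
    inflated by isolated transients whose power smears across the
    spectrum).  Each one alone over-estimates for a signal class the other
    handles.
    """
    mad = 1.4826 * float(np.median(np.abs(np.diff(x)))) / np.sqrt(2.0)
    if x.size < 32:
        return mad
    xc = x - x.mean()
    power = np.abs(np.fft.rfft(xc)) ** 2 / x.size**2
    power[1 : (x.size + 1) // 2] *= 2.0
    power = power[1:]
    spec = float(np.sqrt(np.median(power) * power.size / np.log(2.0)))
    return min(mad, spec)


def segment_baseline(values: np.ndarray) -> tuple[float, float, float]:
    """Robust (baseline, peak, amplitude) from the 10th/90th percentiles."""
    lo, hi = np.percentile(values, [10, 90])
    return float(lo), float(hi), float(hi - lo)


def _cross_time(t: np.ndarray, x: np.ndarray, i: int, level: float, rising: bool) -> float:
    """Linear-interpolated crossing time between frames i-1 and i (rising)
    or i and i+1 (falling)."""
    if rising:
        if i == 0:
            return float(t[0])
        x0, x1, t0, t1 = x[i - 1], x[i], t[i - 1], t[i]
    else:
        if i == x.size - 1:
            return float(t[-1])
        x0, x1, t0, t1 = x[i], x[i + 1], t[i], t[i + 1]
    if x1 == x0:
        return float(t1 if rising else t0)
    frac = (level - x0) / (x1 - x0)
    return float(t0 + np.clip(frac, 0.0, 1.0) * (t1 - t0))


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i, j] index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[k]), int(idx[k + 1] - 1)) for k in range(0, idx.size, 2)]


def detect_oscillations(
    trace: Trace,
    min_prominence_frac: float = 0.25,
    threshold_frac: float = THRESHOLD_FRAC,
    pulse_level_frac: float = 0.1,
    amplitude_floor: float = 0.05,
) -> list[Pulse]:
    """Find pulses in a detrended segment.

    A pulse is a maximal run of frames above ``threshold_frac`` of the
    robust amplitude (10th-90th percentile span) that contains at least one
    local maximum with prominence >= ``min_prominence_frac`` x amplitude.
    When several prominent maxima share one run, the run is a single pulse
    whose peak is the larger maximum (the earlier on an exact tie).  Runs
    clipped by a segment edge are marked incomplete.  Zero pulses is a
    valid outcome (plateau or silent segment).
    """
    t, x = trace.time, trace.values
    base, _, amp = segment_baseline(x)
    # detectability floor: a flat segment with measurement noise shows a
    # spurious percentile span of ~2.6 sigma, so require the span to clear
    # a robust noise estimate with margin before calling anything an
    # oscillation.  The noise sigma comes from the median periodogram
    # ordinate (white noise gives ~exponential bins with median
    # sigma^2 ln2 / n_bins; an oscillation and its harmonics occupy only a
    # sparse subset of bins and cannot move the median).
    sigma_hat = _noise_sigma(x)
    floor = max(amplitude_floor, 6.0 * sigma_hat)
    if amp < floor:
        return []
    # two-pass leveling: the global 10th/90th percentiles mis-place the
    # crossing level at extreme duty cycles (the 90th percentile can fall on
    # a burst edge), so refine baseline/peak from the frames below/above the
    # coarse midline before thresholding
    coarse = base + 0.5 * amp
    below, above = x[x < coarse], x[x >= coarse]
    if below.size and above.size:
        # median of the silent-phase frames is immune to residual detrending
        # dips near the edges, which drag a low percentile down and with it
        # the near-baseline pulse level
        base = float(np.median(below))
        peak_level = float(np.percentile(above, 90))
        amp = peak_level - base
        if amp < amplitude_floor:
            return []
    thr = base + threshold_frac * amp
    low = base + pulse_level_frac * amp
    peaks, _ = find_peaks(x, prominence=min_prominence_frac * amp)
    above = x >= thr
    pulses: list[Pulse] = []
    for i0, i1 in _runs_above(above):
        in_run = peaks[(peaks >= i0) & (peaks <= i1)]
        if in_run.size == 0:
            continue
        best = in_run[np.argmax(x[in_run])]  # argmax -> earlier index on tie
        start = _cross_time(t, x, i0, thr, rising=True)
        end = _cross_time(t, x, i1, thr, rising=False)
        # widen to the near-baseline level for the pulse duration
        j0 = i0
        while j0 > 0 and x[j0 - 1] >= low:
            j0 -= 1
        j1 = i1
        while j1 < x.size - 1 and x[j1 + 1] >= low:
            j1 += 1
        base_start = _cross_time(t, x, j0, low, rising=True)
        base_end = _cross_time(t, x, j1, low, rising=False)
        complete = j0 > 0 and j1 < x.size - 1
        pulses.append(
            Pulse(
                start=start,
                end=end,
                peak_time=float(t[best]),
                peak_value=float(x[best]),
                base_start=base_start,
                base_end=base_end,
                complete=complete,
            )
        )
    return pulses


@dataclass
class OscillationParams:
    """Per-islet, per-segment waveform summary."""

    islet_id: str
    segment_label: str
    regime: str  # oscillating | plateau | silent
    speed_class: str  # fast | slow | none
    n_pulses: int
    peak: float
    amplitude: float
    period: float
    active_duration: float
    pulse_duration: float
    silent_duration: float
    plateau_fraction: float
    avg_signal: float  # detrended segment mean (equals raw when mean-preserving)
    avg_signal_raw: float


def compute_waveform_params(
    pulses: list[Pulse],
    segment: Trace,
    segment_length: float | None = None,
    segment_label: str = "",
    basal_baseline: float | None = None,
    amplitude_floor: float = 0.05,
    raw_segment: Trace | None = None,
) -> OscillationParams:
    """Summarize a segment's pulses into the six waveform parameters.

    Oscillating (>= 2 complete pulses): period = mean onset-to-onset
    spacing, A_D/P_D = per-pulse means over complete pulses, S_D = period -
    A_D, P_F = A_D / period.  A single pulse leaves period, S_D and P_F
    missing (a period needs two reference points) while A_D/P_D come from
    that pulse.  With zero pulses the segment is a plateau when its mean
    sits at least half the amplitude floor above the basal baseline
    (``basal_baseline``, normally the islet's own 2G-segment baseline),
    else silent.
    """
    t, x = segment.time, segment.values
    if segment_length is None:
        # round away float accumulation so edge codes print cleanly (40.0)
        segment_length = float(
            np.round(segment.n_frames * segment.sampling_interval, 6)
        )
    raw_mean = float(raw_segment.values.mean()) if raw_segment is not None else float(x.mean())
    base, _, amp = segment_baseline(x)
    if basal_baseline is None:
        basal_baseline = base

    if not pulses:
        if x.mean() >= basal_baseline + 0.5 * amplitude_floor:
            return OscillationParams(
                islet_id=segment.islet_id,
                segment_label=segment_label,
                regime="plateau",
                speed_class="none",
                n_pulses=0,
                peak=float(x.mean()),
                amplitude=float(x.mean() - basal_baseline),
                period=0.0,
                active_duration=segment_length,
                pulse_duration=segment_length,
                silent_duration=0.0,
                plateau_fraction=1.0,
                avg_signal=float(x.mean()),
                avg_signal_raw=raw_mean,
            )
        return OscillationParams(
            islet_id=segment.islet_id,
            segment_label=segment_label,
            regime="silent",
            speed_class="none",
            n_pulses=0,
            peak=float(x.mean()),
            amplitude=0.0,
            period=segment_length,
            active_duration=0.0,
            pulse_duration=0.0,
            silent_duration=segment_length,
            plateau_fraction=0.0,
            avg_signal=float(x.mean()),
            avg_signal_raw=raw_mean,
        )

    complete = [p for p in pulses if p.complete]
    usable = complete if complete else pulses
    peak = float(np.mean([p.peak_value for p in usable]))
    a_d = float(np.mean([p.active_duration for p in usable]))
    p_d = float(np.mean([p.pulse_duration for p in usable]))
    if len(complete) >= 2:
        onsets = np.array([p.start for p in complete])
        period = float(np.mean(np.diff(onsets)))
        s_d = period - a_d
        p_f = a_d / period
    else:
        period = math.nan
        s_d = math.nan
        p_f = math.nan
    params = OscillationParams(
        islet_id=segment.islet_id,
        segment_label=segment_label,
        regime="oscillating",
        speed_class="none",
        n_pulses=len(pulses),
        peak=peak,
        amplitude=float(peak - base),
        period=period,
        active_duration=a_d,
        pulse_duration=p_d,
        silent_duration=s_d,
        plateau_fraction=p_f,
        avg_signal=float(x.mean()),
        avg_signal_raw=raw_mean,
    )
    params.speed_class = classify_speed(params)
    return params


def classify_speed(
    params: OscillationParams,
    fast_cutoff: float = FAST_CUTOFF,
    slow_upper: float = SLOW_UPPER,
) -> str:
    """Fast (period < 2 min), slow (2-10 min), or none (plateau/silent,
    missing period, or period beyond the slow bound)."""
    if params.regime != "oscillating" or not math.isfinite(params.period):
        return "none"
    if params.period < fast_cutoff:
        return "fast"
    if params.period <= slow_upper:
        return "slow"
    return "none"


_PARAM_COLS = [
    "peak",
    "amplitude",
    "period_min",
    "active_min",
    "pulse_min",
    "silent_min",
    "plateau_fraction",
    "avg_signal",
    "avg_signal_raw",
]


def summarize_animal(params_table: pd.DataFrame) -> pd.DataFrame:
    """Animal-level unweighted means over islets, per parameter x segment.

    Edge-case numeric codes (plateau fraction 0/1, period 0/segment-length)
    enter the mean as ordinary numbers; missing periods (single-pulse
    segments) are excluded from the period average.
    """
    cols = [c for c in _PARAM_COLS if c in params_table.columns]
    keys = [k for k in ("strain", "sex", "animal", "segment") if k in params_table.columns]
    return params_table.groupby(keys, sort=True)[cols].mean().reset_index()
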