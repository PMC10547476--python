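"""End-to-end orchestration: traces -> per-segment parameter tables.

Ties the segmentation, detrending, pulse detection, and spectral stages
together and emits the flat CSV-ready tables the integration and GWAS
stages consume.  Everything here is deterministic: identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import spectral, waveform
from .traceio import ChannelPair, SegmentSchedule, Trace, segment_trace

__all__ = ["AnalysisSettings", "extract_parameters", "animal_parameter_matrix"]


@dataclass(frozen=True)
class AnalysisSettings:
    detrend: waveform.DetrendSettings = waveform.DetrendSettings()
    min_prominence_frac: float = 0.25
    threshold_frac: float = waveform.THRESHOLD_FRAC
    pulse_level_frac: float = 0.1
    amplitude_floor: float = 0.05
    fast_cutoff: float = waveform.FAST_CUTOFF
    slow_upper: float = waveform.SLOW_UPPER
    basal_label: str = "2G"
    min_separation_bins: int = 2


def _as_trace(t: Trace | ChannelPair) -> Trace:
    return t.to_ratio() if isinstance(t, ChannelPair) else t


def extract_parameters(
    traces: list[Trace | ChannelPair],
    schedule: SegmentSchedule,
    settings: AnalysisSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-islet, per-segment waveform parameters and spectral summaries.

    The islet's basal (2G) segment supplies the reference baseline that
    separates plateaued from silent non-oscillating segments; when the
    schedule has no basal segment each segment falls back to its own
    robust baseline.

    Returns ``(params, spectra)`` data frames, one row per islet x segment.
    """
    settings = settings or AnalysisSettings()
    param_rows = []
    spec_rows = []
    for raw in traces:
        trace = _as_trace(raw)
        segments = segment_trace(trace, schedule)
        basal_baseline = None
        for label, seg in segments:
            if label == settings.basal_label:
                # median of the basal segment: robust central level of the
                # (normally quiescent) 2G condition
                basal_baseline = float(np.median(seg.values))
        for label, seg in segments:
            det = waveform.detrend_segment(seg, settings.detrend)
            pulses = waveform.detect_oscillations(
                det,
                min_prominence_frac=settings.min_prominence_frac,
                threshold_frac=settings.threshold_frac,
                pulse_level_frac=settings.pulse_level_frac,
                amplitude_floor=settings.amplitude_floor,
            )
            params = waveform.compute_waveform_params(
                pulses,
                det,
                segment_length=None,
                segment_label=label,
                basal_baseline=basal_baseline,
                amplitude_floor=settings.amplitude_floor,
                raw_segment=seg,
            )
            params.speed_class = waveform.classify_speed(
                params, settings.fast_cutoff, settings.slow_upper
            )
            d = asdict(params)
            d.update(strain=trace.strain, sex=trace.sex, animal=trace.animal)
            param_rows.append(d)
            freqs, power = spectral.power_spectrum(det)
            summ = spectral.top_components(
                freqs,
                power,
                min_separation=settings.min_separation_bins,
                islet_id=trace.islet_id,
                segment_label=label,
            )
            s = asdict(summ)
            s.update(strain=trace.strain, sex=trace.sex, animal=trace.animal)
            spec_rows.append(s)
    params_df = pd.DataFrame(param_rows).rename(
        columns={
            "segment_label": "segment",
            "period": "period_min",
            "active_duration": "active_min",
            "pulse_duration": "pulse_min",
            "silent_duration": "silent_min",
        }
    )
    order = [
        "islet_id",
        "strain",
        "sex",
        "animal",
        "segment",
        "regime",
        "speed_class",
        "n_pulses",
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
    params_df = params_df[order]
    spectra_df = pd.DataFrame(spec_rows).rename(
        columns={
            "segment_label": "segment",
            "freq1": "freq1_per_min",
            "freq2": "freq2_per_min",
            "resolution": "resolution_per_min",
        }
    )
    spectra_df = spectra_df[
        [
            "islet_id",
            "strain",
            "sex",
            "animal",
            "segment",
            "freq1_per_min",
            "amp1",
            "freq2_per_min",
            "amp2",
            "resolution_per_min",
        ]
    ]
    return params_df, spectra_df


def animal_parameter_matrix(params_df: pd.DataFrame) -> pd.DataFrame:
    """Wide animal x trait matrix (``<segment>_<parameter>`` columns).

    Animal-level means come from :func:`waveform.summarize_animal`; trait
    ids follow the ``8G_active_min`` naming used by the integration stage,
    with the basal segment's average signal as ``2G_avg``.
    """
    summary = waveform.summarize_animal(params_df)
    value_cols = [
        c for c in summary.columns if c not in ("strain", "sex", "animal", "segment")
    ]
    long = summary.melt(
        id_vars=["strain", "sex", "animal", "segment"], value_vars=value_cols
    )
    long["trait"] = long["segment"] + "_" + long["variable"]
    wide = long.pivot_table(index="animal", columns="trait", values="value", sort=True)
    wide.columns.name = None
    meta = summary[["animal", "strain", "sex"]].drop_duplicates().set_index("animal")
    out = meta.join(wide)
    if "2G_avg_signal_raw" in out.columns:
        out["2G_avg"] = out["2G_avg_signal_raw"]
    return out
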