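"""Reading, ratioing, and segmenting islet Ca2+ traces.

Ingestion starts at exported ROI intensity tables (one region of interest
per islet).  Two-channel recordings carry a Ca2+-bound and a Ca2+-free
fluorescence channel; their elementwise ratio (bound/free, rising with
Ca2+) is the working signal.  A segment schedule slices each trace into the
perifusion condition windows (e.g. 8G, 8G/QLA, 8G/QLA/GIP, 2G; 40 min
each at 6-s sampling by default).

All times are minutes.  Time grids must be uniform; missing frames are a
hard error because every duration statistic downstream is frame-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "ChannelPair",
    "Segment",
    "SegmentSchedule",
    "compute_fura_ratio",
    "segment_trace",
    "read_roi_table",
    "write_roi_table",
    "read_schedule",
    "write_schedule",
    "parse_islet_id",
]

_REL_TOL = 1e-9


def _check_uniform(time: np.ndarray) -> float:
    """Validate a strictly increasing uniform grid; return the step."""
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time grid needs at least two frames")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise ValueError("time grid must be strictly increasing")
    step = float(dt[0])
    if np.max(np.abs(dt - step)) > _REL_TOL * max(1.0, abs(step), float(abs(time[-1]))):
        raise ValueError("time grid is not uniform")
    return step


@dataclass
class Trace:
    """A single islet's signal on a uniform time grid (minutes)."""

    islet_id: str
    time: np.ndarray
    values: np.ndarray
    strain: str | None = None
    sex: str | None = None
    animal: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_uniform(self.time)
        if self.values.shape != self.time.shape:
            raise ValueError("time and values must have equal length")
        if np.any(~np.isfinite(self.values)):
            raise ValueError(f"trace {self.islet_id!r} contains missing values")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_frames(self) -> int:
        return int(self.time.size)

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class ChannelPair:
    """Raw two-channel ROI intensities prior to ratioing."""

    islet_id: str
    time: np.ndarray
    bound: np.ndarray
    free: np.ndarray
    strain: str | None = None
    sex: str | None = None
    animal: str | None = None

    def to_ratio(self) -> Trace:
        values = compute_fura_ratio(self.bound, self.free)
        return Trace(
            islet_id=self.islet_id,
            time=self.time,
            values=values,
            strain=self.strain,
            sex=self.sex,
            animal=self.animal,
            meta={"ratio": "bound/free"},
        )


def compute_fura_ratio(bound: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Elementwise bound/free dye ratio (rises with Ca2+).

    The bound channel is the 405-nm-excited emission, the free channel the
    488-nm-excited one; the orientation is recorded in output metadata since
    conventions differ between rigs.
    """
    bound = np.asarray(bound, dtype=float)
    free = np.asarray(free, dtype=float)
    if bound.shape != free.shape:
        raise ValueError("bound and free channels must have equal length")
    if np.any(free <= 0):
        raise ValueError("free-channel intensities must be positive")
    return bound / free


@dataclass(frozen=True)
class Segment:
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"segment {self.label!r}: end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start


class SegmentSchedule:
    """Ordered, non-overlapping condition windows (minutes)."""

    def __init__(self, segments: list[tuple[str, float, float]] | list[Segment]):
        segs = [s if isinstance(s, Segment) else Segment(*s) for s in segments]
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end - _REL_TOL:
                raise ValueError(f"segments {a.label!r} and {b.label!r} overlap")
        self.segments = segs

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    @classmethod
    def default_four_condition(cls, segment_length: float = 40.0) -> "SegmentSchedule":
        """The standard 8G / 8G_QLA / 8G_QLA_GIP / 2G protocol."""
        labels = ["8G", "8G_QLA", "8G_QLA_GIP", "2G"]
        return cls(
            [(lab, i * segment_length, (i + 1) * segment_length) for i, lab in enumerate(labels)]
        )


def segment_trace(trace: Trace, schedule: SegmentSchedule) -> list[tuple[str, Trace]]:
    """Slice a trace into (label, sub-trace) pairs by half-open membership.

    A frame at time t belongs to a segment iff start <= t < end, so a frame
    exactly on a boundary belongs to the later segment and concatenating the
    segments of a contiguous schedule reproduces the trace.
    """
    if len(schedule) == 0:
        return []
    dt = trace.sampling_interval
    span_lo = trace.time[0] - _REL_TOL
    span_hi = trace.time[-1] + dt + _REL_TOL
    out: list[tuple[str, Trace]] = []
    for seg in schedule:
        if seg.start < span_lo or seg.end > span_hi:
            raise ValueError(
                f"segment {seg.label!r} [{seg.start}, {seg.end}) outside trace span"
            )
        mask = (trace.time >= seg.start - _REL_TOL * max(1.0, seg.start)) & (
            trace.time < seg.end - _REL_TOL * max(1.0, seg.end)
        )
        if mask.sum() < 2:
            raise ValueError(f"segment {seg.label!r} covers fewer than two frames")
        out.append(
            (
                seg.label,
                replace(trace, time=trace.time[mask], values=trace.values[mask]),
            )
        )
    return out


def parse_islet_id(islet_id: str) -> dict:
    """Split a ``strain_sex_animal_islet`` id into its metadata fields.

    Returns empty fields when the id does not follow the convention.
    """
    parts = islet_id.split("_")
    if len(parts) >= 4:
        return {
            "strain": "_".join(parts[:-3]),
            "sex": parts[-3],
            "animal": "_".join(parts[:-1]),
        }
    return {"strain": None, "sex": None, "animal": None}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_roi_table(path, layout: str = "wide") -> list[Trace | ChannelPair]:
    """Read an exported ROI intensity table.

    ``wide``: first column ``time_min``, then one column per ROI.  Columns
    ending in ``_b`` / ``_f`` are paired into two-channel records; any other
    column is taken as an already-computed ratio.  ``long``: columns
    ``time_min, islet, channel, value`` with channel in {ratio, b, f}.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):  # pandas would silently mangle these
        raise ValueError("duplicated islet id in table")
    df = pd.read_csv(path, sep=sep)
    if layout == "wide":
        return _parse_wide(df)
    if layout == "long":
        wide = df.pivot_table(
            index="time_min", columns=["islet", "channel"], values="value", sort=False
        )
        if wide.isna().any().any():
            raise ValueError("long table has missing frames")
        cols = pd.DataFrame({"time_min": wide.index.to_numpy()})
        for islet, channel in wide.columns:
            name = islet if channel == "ratio" else f"{islet}_{channel}"
            cols[name] = wide[(islet, channel)].to_numpy()
        return _parse_wide(cols)
    raise ValueError(f"unknown layout {layout!r}")


def _parse_wide(df: pd.DataFrame) -> list[Trace | ChannelPair]:
    if "time_min" not in df.columns:
        raise ValueError("expected a 'time_min' column")
    time = df["time_min"].to_numpy(dtype=float)
    _check_uniform(time)
    roi_cols = [c for c in df.columns if c != "time_min"]
    if len(set(roi_cols)) != len(roi_cols):
        raise ValueError("duplicated islet id in table")
    traces: list[Trace | ChannelPair] = []
    seen_pairs: dict[str, dict[str, np.ndarray]] = {}
    for col in roi_cols:
        if col.endswith(("_b", "_f")):
            stem, chan = col[:-2], col[-1]
            seen_pairs.setdefault(stem, {})[chan] = df[col].to_numpy(dtype=float)
        else:
            meta = parse_islet_id(col)
            traces.append(Trace(islet_id=col, time=time, values=df[col].to_numpy(dtype=float), **meta))
    for stem, chans in seen_pairs.items():
        if set(chans) != {"b", "f"}:
            raise ValueError(f"islet {stem!r}: need both _b and _f channels")
        meta = parse_islet_id(stem)
        traces.append(
            ChannelPair(islet_id=stem, time=time, bound=chans["b"], free=chans["f"], **meta)
        )
    return traces


def write_roi_table(traces: list[Trace | ChannelPair], path, layout: str = "wide") -> None:
    """Write traces back to CSV/TSV; inverse of :func:`read_roi_table`."""
    if not traces:
        raise ValueError("nothing to write")
    time = traces[0].time
    for t in traces:
        if t.time.shape != time.shape or np.max(np.abs(t.time - time)) > _REL_TOL:
            raise ValueError("all traces must share one time grid")
    if layout == "wide":
        data = {"time_min": time}
        for t in traces:
            if isinstance(t, ChannelPair):
                data[f"{t.islet_id}_b"] = t.bound
                data[f"{t.islet_id}_f"] = t.free
            else:
                data[t.islet_id] = t.values
        pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)
        return
    if layout == "long":
        rows = []
        for t in traces:
            if isinstance(t, ChannelPair):
                for chan, vals in (("b", t.bound), ("f", t.free)):
                    rows.append(
                        pd.DataFrame(
                            {"time_min": time, "islet": t.islet_id, "channel": chan, "value": vals}
                        )
                    )
            else:
                rows.append(
                    pd.DataFrame(
                        {"time_min": time, "islet": t.islet_id, "channel": "ratio", "value": t.values}
                    )
                )
        pd.concat(rows, ignore_index=True)[["time_min", "islet", "channel", "value"]].to_csv(
            path, sep=_sep_for(path), index=False
        )
        return
    raise ValueError(f"unknown layout {layout!r}")


def read_schedule(path) -> SegmentSchedule:
    df = pd.read_csv(path, sep=_sep_for(path))
    df = df.sort_values("segment") if "segment" in df.columns else df
    return SegmentSchedule(list(zip(df["label"], df["start_min"], df["end_min"])))


def write_schedule(schedule: SegmentSchedule, path) -> None:
    pd.DataFrame(
        {
            "segment": range(len(schedule)),
            "label": [s.label for s in schedule],
            "start_min": [s.start for s in schedule],
            "end_min": [s.end for s in schedule],
        }
    ).to_csv(path, sep=_sep_for(path), index=False)
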