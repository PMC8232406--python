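"""Canonical cage-recording CSV dialect and validated trace containers.

Metabolic-cage systems export interval-stamped gas channels (VO2/VCO2,
normalized to body mass in ml/kg/hr, one row per 4-minute interval) and
beam-break activity channels (total and ambulatory counts per axis, one row
per 10-second bin).  Vendor export formats vary by firmware, so this module
defines a single normalized, documented schema and builds validated
in-memory traces from it:

gas      ``subject_id,group,timepoint,timestamp,vo2,vco2``
activity ``subject_id,timestamp,x_total,x_amb,y_total,y_amb,z_total``

Timestamps are timezone-naive ISO-8601 wall-clock times; all downstream
phase logic (light/dark) is clock-anchored.  Floats are written with fixed
6-decimal formatting so write -> read -> write is byte-stable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "TraceFormatError",
    "TraceValidationError",
    "PhaseSchedule",
    "CalorimetryTrace",
    "ActivityTrace",
    "read_trace_csv",
    "write_trace_csv",
    "GAS_COLUMNS",
    "ACTIVITY_COLUMNS",
]

GAS_COLUMNS = ["subject_id", "group", "timepoint", "timestamp", "vo2", "vco2"]
ACTIVITY_COLUMNS = [
    "subject_id",
    "timestamp",
    "x_total",
    "x_amb",
    "y_total",
    "y_amb",
    "z_total",
]

_COUNT_COLUMNS = ["x_total", "x_amb", "y_total", "y_amb", "z_total"]
_TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


class TraceFormatError(ValueError):
    """The file does not match the canonical dialect (e.g. missing column)."""


class TraceValidationError(ValueError):
    """The data violate a trace invariant (with row-indexed diagnostics)."""


@dataclass(frozen=True)
class PhaseSchedule:
    """12:12 light-dark schedule; light (inactive) phase is [light_on, light_off).

    Defaults to lights-on 06:00, lights-off 18:00: the mouse inactive phase is
    the light half of the day and the active phase the dark half.
    """

    light_on: _dt.time = _dt.time(6, 0)
    light_off: _dt.time = _dt.time(18, 0)

    def __post_init__(self) -> None:
        on = self.light_on.hour * 60 + self.light_on.minute
        off = self.light_off.hour * 60 + self.light_off.minute
        if (off - on) % 1440 != 720:
            raise ValueError(
                "light and dark phases must each span exactly 12 h; got "
                f"light_on={self.light_on}, light_off={self.light_off}"
            )


def _check_uniform_timestamps(ts: np.ndarray, step_seconds: int) -> None:
    if len(ts) < 2:
        return
    diffs = np.diff(ts).astype("timedelta64[s]").astype(np.int64)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise TraceValidationError(
            f"timestamps not strictly increasing at rows {[int(i) for i in bad[:5] + 1]}"
        )
    bad = np.nonzero(diffs != step_seconds)[0]
    if bad.size:
        raise TraceValidationError(
            f"timestamps not uniformly spaced at {step_seconds} s "
            f"at rows {[int(i) for i in bad[:5] + 1]}"
        )


@dataclass
class CalorimetryTrace:
    """One subject-day of VO2/VCO2 gas intervals (ml/kg/hr, 4-min default)."""

    subject_id: str
    group: str
    timepoint: str
    interval_start: np.ndarray  # datetime64[s], strictly increasing, uniform
    vo2: np.ndarray  # ml/kg/hr, > 0
    vco2: np.ndarray  # ml/kg/hr, > 0
    interval_width: int = 4  # minutes

    def __post_init__(self) -> None:
        self.interval_start = np.asarray(self.interval_start, dtype="datetime64[s]")
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if not (len(self.interval_start) == len(self.vo2) == len(self.vco2)):
            raise TraceValidationError("channel lengths differ")
        for name, arr in (("vo2", self.vo2), ("vco2", self.vco2)):
            bad = np.nonzero(~(arr > 0))[0]
            if bad.size:
                raise TraceValidationError(
                    f"non-positive {name} at rows {[int(i) for i in bad[:5]]}"
                )
        _check_uniform_timestamps(self.interval_start, self.interval_width * 60)

    def __len__(self) -> int:
        return len(self.interval_start)

    @property
    def intervals_per_day(self) -> int:
        return 1440 // self.interval_width

    def is_full_day(self) -> bool:
        return len(self) == self.intervals_per_day

    def equals(self, other: "CalorimetryTrace") -> bool:
        return (
            (self.subject_id, self.group, self.timepoint, self.interval_width)
            == (other.subject_id, other.group, other.timepoint, other.interval_width)
            and np.array_equal(self.interval_start, other.interval_start)
            and np.array_equal(self.vo2, other.vo2)
            and np.array_equal(self.vco2, other.vco2)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "timepoint": self.timepoint,
                "timestamp": self.interval_start,
                "vo2": self.vo2,
                "vco2": self.vco2,
            }
        )


@dataclass
class ActivityTrace:
    """One subject-day of per-10-s beam-break counts by axis and class."""

    subject_id: str
    bin_start: np.ndarray  # datetime64[s], uniform at 10 s
    x_total: np.ndarray
    x_amb: np.ndarray
    y_total: np.ndarray
    y_amb: np.ndarray
    z_total: np.ndarray
    bin_seconds: int = field(default=10, repr=False)

    def __post_init__(self) -> None:
        self.bin_start = np.asarray(self.bin_start, dtype="datetime64[s]")
        for name in _COUNT_COLUMNS:
            arr = np.asarray(getattr(self, name))
            if arr.dtype.kind == "f" and not np.all(arr == np.floor(arr)):
                raise TraceValidationError(f"non-integer counts in {name}")
            arr = arr.astype(np.int64)
            setattr(self, name, arr)
            if len(arr) != len(self.bin_start):
                raise TraceValidationError("channel lengths differ")
            bad = np.nonzero(arr < 0)[0]
            if bad.size:
                raise TraceValidationError(
                    f"negative counts in {name} at rows {[int(i) for i in bad[:5]]}"
                )
        for axis in ("x", "y"):
            amb = getattr(self, f"{axis}_amb")
            tot = getattr(self, f"{axis}_total")
            bad = np.nonzero(amb > tot)[0]
            if bad.size:
                raise TraceValidationError(
                    f"ambulatory exceeds total on {axis}-axis at rows {[int(i) for i in bad[:5]]}"
                )
        _check_uniform_timestamps(self.bin_start, self.bin_seconds)

    def __len__(self) -> int:
        return len(self.bin_start)

    @property
    def bins_per_day(self) -> int:
        return 86400 // self.bin_seconds

    def is_full_day(self) -> bool:
        return len(self) == self.bins_per_day

    def equals(self, other: "ActivityTrace") -> bool:
        return (
            self.subject_id == other.subject_id
            and np.array_equal(self.bin_start, other.bin_start)
            and all(
                np.array_equal(getattr(self, c), getattr(other, c))
                for c in _COUNT_COLUMNS
            )
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"subject_id": self.subject_id, "timestamp": self.bin_start}
        for c in _COUNT_COLUMNS:
            data[c] = getattr(self, c)
        return pd.DataFrame(data)


Trace = Union[CalorimetryTrace, ActivityTrace]


def _single_value(df: pd.DataFrame, column: str, path: Path) -> str:
    values = df[column].astype(str).unique()
    if len(values) > 1:
        raise TraceValidationError(
            f"{path}: expected a single {column}, found {sorted(values)}"
        )
    return values[0] if len(values) else ""


def read_trace_csv(path: Union[str, Path], kind: str) -> Trace:
    """Read a canonical gas or activity CSV into a validated trace.

    Parameters
    ----------
    path : file in the canonical dialect.
    kind : ``"gas"`` or ``"activity"``.
    """
    path = Path(path)
    if kind not in ("gas", "activity"):
        raise ValueError(f"kind must be 'gas' or 'activity', got {kind!r}")
    expected = GAS_COLUMNS if kind == "gas" else ACTIVITY_COLUMNS
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "timepoint": str})
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty file") from exc
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    try:
        ts = pd.to_datetime(df["timestamp"], format=_TIMESTAMP_FORMAT)
    except (ValueError, TypeError) as exc:
        raise TraceFormatError(f"{path}: unparseable timestamps: {exc}") from exc
    timestamps = ts.to_numpy(dtype="datetime64[s]")

    if kind == "gas":
        return CalorimetryTrace(
            subject_id=_single_value(df, "subject_id", path),
            group=_single_value(df, "group", path),
            timepoint=_single_value(df, "timepoint", path),
            interval_start=timestamps,
            vo2=df["vo2"].to_numpy(dtype=float),
            vco2=df["vco2"].to_numpy(dtype=float),
        )
    return ActivityTrace(
        subject_id=_single_value(df, "subject_id", path),
        bin_start=timestamps,
        **{c: df[c].to_numpy() for c in _COUNT_COLUMNS},
    )


def write_trace_csv(trace: Trace, path: Union[str, Path]) -> None:
    """Write a trace in the canonical dialect (bit-stable round trip).

    Canonical column order, ISO-8601 timestamps, fixed 6-decimal float
    formatting; two writes of the same trace produce identical bytes.
    """
    path = Path(path)
    if isinstance(trace, CalorimetryTrace):
        header = ",".join(GAS_COLUMNS)
        lines = [header]
        ts = pd.to_datetime(trace.interval_start)
        for i in range(len(trace)):
            lines.append(
                f"{trace.subject_id},{trace.group},{trace.timepoint},"
                f"{ts[i].strftime(_TIMESTAMP_FORMAT)},"
                f"{trace.vo2[i]:.6f},{trace.vco2[i]:.6f}"
            )
    elif isinstance(trace, ActivityTrace):
        header = ",".join(ACTIVITY_COLUMNS)
        lines = [header]
        ts = pd.to_datetime(trace.bin_start)
        for i in range(len(trace)):
            lines.append(
                f"{trace.subject_id},{ts[i].strftime(_TIMESTAMP_FORMAT)},"
                f"{trace.x_total[i]},{trace.x_amb[i]},"
                f"{trace.y_total[i]},{trace.y_amb[i]},{trace.z_total[i]}"
            )
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported trace type {type(trace)!r}")
    path.write_text("\n".join(lines) + "\n")
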