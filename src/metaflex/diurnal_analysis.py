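"""Diurnal binning, smoothing, AUC and metabolic-flexibility statistics.

The mouse day is split into a 12-h light (inactive) and a 12-h dark (active)
phase.  Per-interval metabolic channels are summarized in bins of 1, 6, 12
and 24 hours (6-h bins anchored at 06:00/12:00/18:00/00:00), smoothed with a
trailing hourly moving average (15 four-minute intervals), and integrated by
the trapezoidal rule with time in hours.  Metabolic-rate flux and metabolic
flexibility are quantified per subject-day as the active-minus-inactive 12-h
delta of energy expenditure and RER respectively, plus the AUC of the
smoothed curves (24-h and per 6-h bin).

A subject-day runs 06:00 -> 06:00 so each day contains one full inactive
phase followed by one full active phase.  Phase membership is half-open:
clock times in [light_on, light_off) are inactive.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Dict, Union

import numpy as np
import pandas as pd

from .calorimetry_io import PhaseSchedule
from .metabolic_metrics import MetabolicSeries

__all__ = [
    "VALID_BIN_WIDTHS",
    "MOVING_AVERAGE_WINDOW",
    "FlexibilityMetrics",
    "assign_phase",
    "phase_mask",
    "bin_series",
    "moving_average",
    "auc",
    "binned_auc",
    "flexibility_metrics",
]

VALID_BIN_WIDTHS = (1, 6, 12, 24)
MOVING_AVERAGE_WINDOW = 15  # 4-min intervals -> 60 min

_CHANNELS = ("rer", "cv", "ee", "carb_ox", "lipid_ox")


def _minutes_of_day(timestamps: np.ndarray) -> np.ndarray:
    ts = np.asarray(timestamps, dtype="datetime64[s]")
    seconds = (ts - ts.astype("datetime64[D]")).astype(np.int64)
    return seconds / 60.0


def phase_mask(timestamps: np.ndarray, schedule: PhaseSchedule) -> np.ndarray:
    """Boolean array, True where the clock time falls in the active (dark) phase."""
    minutes = _minutes_of_day(timestamps)
    on = schedule.light_on.hour * 60 + schedule.light_on.minute
    off = schedule.light_off.hour * 60 + schedule.light_off.minute
    inactive = (minutes >= on) & (minutes < off)
    return ~inactive


def assign_phase(
    timestamp: Union[_dt.datetime, _dt.time, np.datetime64], schedule: PhaseSchedule
) -> str:
    """``"inactive"`` if the clock time is in [light_on, light_off), else ``"active"``."""
    if isinstance(timestamp, _dt.time):
        t = timestamp
    elif isinstance(timestamp, np.datetime64):
        t = pd.Timestamp(timestamp).time()
    else:
        t = timestamp.time()
    minutes = t.hour * 60 + t.minute
    on = schedule.light_on.hour * 60 + schedule.light_on.minute
    off = schedule.light_off.hour * 60 + schedule.light_off.minute
    return "inactive" if on <= minutes < off else "active"


def _require_full_day(series: MetabolicSeries) -> None:
    if not series.is_full_day():
        raise ValueError(
            f"series must span exactly 24 h "
            f"({series.intervals_per_day} intervals); got {len(series)}"
        )


def _bin_index(timestamps: np.ndarray, bin_width: int, day_start_hour: int = 6) -> np.ndarray:
    """Index of the clock-anchored bin containing each interval start."""
    hours = _minutes_of_day(timestamps) / 60.0
    return (((hours - day_start_hour) % 24) // bin_width).astype(int)


def bin_series(
    series: MetabolicSeries,
    bin_width: int,
    schedule: PhaseSchedule | None = None,
) -> pd.DataFrame:
    """Summarize every channel of a full 24-h series in clock-anchored bins.

    Returns a tidy frame with one row per (bin, channel): columns
    ``bin_width, bin_start, phase, channel, mean, sd, n``.  Intervals are
    assigned to the bin containing their start; ``sd`` is the sample standard
    deviation (ddof=1).  12-h bins carry pure phase labels; the 24-h bin is
    ``mixed``.
    """
    if bin_width not in VALID_BIN_WIDTHS:
        raise ValueError(f"bin_width must be one of {VALID_BIN_WIDTHS}, got {bin_width}")
    _require_full_day(series)
    schedule = schedule or PhaseSchedule()
    idx = _bin_index(series.interval_start, bin_width)
    active = phase_mask(series.interval_start, schedule)
    start_clock = _minutes_of_day(series.interval_start)

    rows = []
    for b in range(24 // bin_width):
        in_bin = idx == b
        phases = set(np.where(active[in_bin], "active", "inactive"))
        phase = phases.pop() if len(phases) == 1 else "mixed"
        first = np.nonzero(in_bin)[0][0]
        clock = int(start_clock[first])
        bin_start = f"{clock // 60:02d}:{clock % 60:02d}"
        for channel in _CHANNELS:
            values = series.channel(channel)[in_bin]
            rows.append(
                {
                    "bin_width": bin_width,
                    "bin_start": bin_start,
                    "phase": phase,
                    "channel": channel,
                    "mean": float(np.mean(values)),
                    "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                    "n": int(len(values)),
                }
            )
    return pd.DataFrame(rows)


def moving_average(values: np.ndarray, window: int = MOVING_AVERAGE_WINDOW) -> np.ndarray:
    """Trailing moving average; output length = input length - window + 1.

    With the default window of 15 four-minute intervals this is the hourly
    moving average; the k-th output summarizes input intervals
    [k, k+window) and is stamped with the last interval's start time.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(values) < window:
        raise ValueError(f"series of length {len(values)} shorter than window {window}")
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def smoothed_timestamps(
    timestamps: np.ndarray, window: int = MOVING_AVERAGE_WINDOW
) -> np.ndarray:
    """Timestamps for :func:`moving_average` output (last interval of each window)."""
    timestamps = np.asarray(timestamps, dtype="datetime64[s]")
    if len(timestamps) < window:
        raise ValueError("series shorter than window")
    return timestamps[window - 1 :]


def auc(values: np.ndarray, spacing_hours: float = 4.0 / 60.0) -> float:
    """Trapezoidal area under a uniformly spaced curve, x in hours.

    4-min spacing = 1/15 h; a constant 1.0 over the 346 smoothed points of a
    24-h day integrates to 345/15 = 23.0.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("AUC requires at least 2 points")
    return float(np.trapezoid(values, dx=spacing_hours))


def binned_auc(
    values: np.ndarray,
    timestamps: np.ndarray,
    bin_width: int = 6,
    spacing_hours: float = 4.0 / 60.0,
) -> Dict[str, float]:
    """Trapezoidal AUC of the points falling within each clock-anchored bin.

    Points are assigned by their timestamp; no interpolation across bin
    edges, so the sub-AUCs do not exactly sum to the 24-h AUC.
    """
    values = np.asarray(values, dtype=float)
    idx = _bin_index(timestamps, bin_width)
    out: Dict[str, float] = {}
    for b in range(24 // bin_width):
        in_bin = idx == b
        if np.sum(in_bin) < 2:
            raise ValueError(f"fewer than 2 points in bin {b}")
        clock = (6 + b * bin_width) % 24
        out[f"{clock:02d}:00"] = float(np.trapezoid(values[in_bin], dx=spacing_hours))
    return out


@dataclass
class FlexibilityMetrics:
    """Per-subject-day diurnal flux/flexibility metrics.

    ``delta_*`` are active-minus-inactive 12-h bin means (metabolic-rate flux
    for EE, metabolic flexibility for RER); ``auc_*`` integrate the hourly
    moving-average curves with x in hours.
    """

    subject_id: str
    group: str
    timepoint: str
    delta_ee: float  # kcal/kg/hr
    delta_rer: float  # dimensionless
    auc_ee_24h: float  # kcal/kg/hr x hours
    auc_rer_24h: float  # dimensionless x hours
    auc_ee_6h: Dict[str, float]
    auc_rer_6h: Dict[str, float]
    mean_ee_24h: float
    mean_rer_24h: float
    mean_ee_active: float
    mean_ee_inactive: float
    mean_rer_active: float
    mean_rer_inactive: float

    def to_row(self) -> Dict[str, float]:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "timepoint": self.timepoint,
            "delta_ee": self.delta_ee,
            "delta_rer": self.delta_rer,
            "auc_ee_24h": self.auc_ee_24h,
            "auc_rer_24h": self.auc_rer_24h,
            "mean_ee_24h": self.mean_ee_24h,
            "mean_rer_24h": self.mean_rer_24h,
            "mean_ee_active": self.mean_ee_active,
            "mean_ee_inactive": self.mean_ee_inactive,
            "mean_rer_active": self.mean_rer_active,
            "mean_rer_inactive": self.mean_rer_inactive,
        }
        for clock, v in self.auc_ee_6h.items():
            row[f"auc_ee_{clock.replace(':', '')}"] = v
        for clock, v in self.auc_rer_6h.items():
            row[f"auc_rer_{clock.replace(':', '')}"] = v
        return row


def flexibility_metrics(
    series: MetabolicSeries, schedule: PhaseSchedule | None = None
) -> FlexibilityMetrics:
    """Deltas from 12-h bins and AUCs from hourly moving-average curves."""
    schedule = schedule or PhaseSchedule()
    _require_full_day(series)
    bins12 = bin_series(series, 12, schedule)

    def _phase_mean(channel: str, phase: str) -> float:
        sel = bins12[(bins12["channel"] == channel) & (bins12["phase"] == phase)]
        return float(sel["mean"].iloc[0])

    ee_active = _phase_mean("ee", "active")
    ee_inactive = _phase_mean("ee", "inactive")
    rer_active = _phase_mean("rer", "active")
    rer_inactive = _phase_mean("rer", "inactive")

    ee_smooth = moving_average(series.ee)
    rer_smooth = moving_average(series.rer)
    ts_smooth = smoothed_timestamps(series.interval_start)
    spacing = series.interval_width / 60.0

    return FlexibilityMetrics(
        subject_id=series.subject_id,
        group=series.group,
        timepoint=series.timepoint,
        delta_ee=ee_active - ee_inactive,
        delta_rer=rer_active - rer_inactive,
        auc_ee_24h=auc(ee_smooth, spacing),
        auc_rer_24h=auc(rer_smooth, spacing),
        auc_ee_6h=binned_auc(ee_smooth, ts_smooth, 6, spacing),
        auc_rer_6h=binned_auc(rer_smooth, ts_smooth, 6, spacing),
        mean_ee_24h=float(np.mean(series.ee)),
        mean_rer_24h=float(np.mean(series.rer)),
        mean_ee_active=ee_active,
        mean_ee_inactive=ee_inactive,
        mean_rer_active=rer_active,
        mean_rer_inactive=rer_inactive,
    )
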