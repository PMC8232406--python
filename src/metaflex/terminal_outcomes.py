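"""Derived metrics for terminal muscle function and histomorphometry.

Muscle-function inputs are per-subject tables of body mass (g), gastrocnemius
weight ratio (treated as an opaque printed quantity), passive torque, peak
twitch and peak tetanic torque (mN*m), optionally with a torque-by-frequency
profile.  Histology inputs are per-fiber records: region of the muscle
(lateral / mid / medial ROI), MyHC-based fiber type (I, IIa, IIb, IIx),
cross-sectional area (um^2), capillary count, and central-nucleus /
NADH-TR / SDH staining flags.

Counting rules:

* CSA is only quantified for fibers with 50 <= CSA <= 7500 um^2 (inclusive).
* Whole-muscle pooling sums fiber counts across the three ROIs (proportions
  recomputed from pooled counts; CSA pooled at the fiber level); subjects
  missing a region are excluded from whole-muscle pooling but kept in
  regional summaries.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CSA_LOWER_UM2",
    "CSA_UPPER_UM2",
    "REGIONS",
    "FIBER_TYPES",
    "percent_change",
    "twitch_tetani_ratio",
    "normalize_torque",
    "filter_fibers_by_csa",
    "summarize_histology",
    "capillary_histogram",
]

CSA_LOWER_UM2 = 50.0
CSA_UPPER_UM2 = 7500.0
REGIONS = ("lateral", "mid", "medial")
FIBER_TYPES = ("I", "IIa", "IIb", "IIx")

ArrayLike = Union[float, np.ndarray]


def percent_change(reference: ArrayLike, observed: ArrayLike) -> ArrayLike:
    """100 * (observed - reference) / reference; negative = reduction."""
    reference = np.asarray(reference, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any(reference == 0):
        raise ValueError("reference must be nonzero")
    out = 100.0 * (observed - reference) / reference
    return out if out.ndim else float(out)


def twitch_tetani_ratio(peak_twitch: ArrayLike, peak_torque: ArrayLike) -> ArrayLike:
    """Peak twitch torque / peak tetanic torque (excitation-contraction index)."""
    peak_twitch = np.asarray(peak_twitch, dtype=float)
    peak_torque = np.asarray(peak_torque, dtype=float)
    if np.any(peak_torque <= 0):
        raise ValueError("peak tetanic torque must be > 0")
    out = peak_twitch / peak_torque
    return out if out.ndim else float(out)


def normalize_torque(torque: ArrayLike, body_mass_g: ArrayLike) -> ArrayLike:
    """Torque per kg body mass (mN*m/kg) from torque in mN*m and mass in g."""
    torque = np.asarray(torque, dtype=float)
    body_mass_g = np.asarray(body_mass_g, dtype=float)
    if np.any(body_mass_g <= 0):
        raise ValueError("body mass must be > 0")
    out = torque / (body_mass_g / 1000.0)
    return out if out.ndim else float(out)


def filter_fibers_by_csa(
    records: pd.DataFrame,
    lower: float = CSA_LOWER_UM2,
    upper: float = CSA_UPPER_UM2,
) -> pd.DataFrame:
    """Keep fibers with lower <= CSA <= upper (inclusive bounds); idempotent."""
    return records[(records["csa"] >= lower) & (records["csa"] <= upper)].copy()


def _summarize(records: pd.DataFrame) -> dict:
    n = len(records)
    out: dict = {"n_fibers": n}
    type_counts = records["fiber_type"].value_counts()
    for t in FIBER_TYPES:
        out[f"prop_{t}"] = float(type_counts.get(t, 0)) / n
    for t in FIBER_TYPES:
        csa = records.loc[records["fiber_type"] == t, "csa"]
        out[f"mean_csa_{t}"] = float(csa.mean()) if len(csa) else np.nan
    out["pct_central_nuclei"] = 100.0 * float(records["central_nucleus"].mean())
    out["pct_nadh_positive"] = 100.0 * float(records["nadh_positive"].mean())
    out["pct_sdh_positive"] = 100.0 * float(records["sdh_positive"].mean())
    out["capillaries_per_fiber"] = float(records["capillaries"].mean())
    return out


def summarize_histology(records: pd.DataFrame, pooling: str = "per-region") -> pd.DataFrame:
    """Per-subject histmorphometry summaries at regional or whole-muscle level.

    Parameters
    ----------
    records : per-fiber table with columns ``subject_id, region, fiber_type,
        csa, capillaries, central_nucleus, nadh_positive, sdh_positive``
        (an optional ``group`` column is carried through).
    pooling : ``"per-region"`` (one row per subject x region) or
        ``"whole-muscle"`` (fiber-level pooling across the three ROIs;
        subjects missing any region are excluded).

    Fiber-type proportions are recomputed from (pooled) counts and sum to 1
    within each row.
    """
    if pooling not in ("per-region", "whole-muscle"):
        raise ValueError(f"pooling must be 'per-region' or 'whole-muscle', got {pooling!r}")
    unknown = set(records["region"]) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region labels {sorted(unknown)}")
    has_group = "group" in records.columns

    rows = []
    if pooling == "per-region":
        for (subject, region), sub in records.groupby(["subject_id", "region"], sort=True):
            row = {"subject_id": subject, "region": region}
            if has_group:
                row["group"] = sub["group"].iloc[0]
            row.update(_summarize(sub))
            rows.append(row)
    else:
        for subject, sub in records.groupby("subject_id", sort=True):
            if set(sub["region"]) != set(REGIONS):
                continue  # excluded from combined analysis, kept regionally
            row = {"subject_id": subject, "region": "whole"}
            if has_group:
                row["group"] = sub["group"].iloc[0]
            row.update(_summarize(sub))
            rows.append(row)
    return pd.DataFrame(rows)


def capillary_histogram(
    records: pd.DataFrame, by: str = "group", max_capillaries: int | None = None
) -> pd.DataFrame:
    """Counts of fibers by capillaries-per-fiber, one row per level of ``by``.

    Columns are capillary counts 0..max; suitable as input histograms for a
    chi-squared distribution comparison.
    """
    kmax = (
        int(records["capillaries"].max())
        if max_capillaries is None
        else int(max_capillaries)
    )
    levels = sorted(records[by].unique())
    data = {}
    for level in levels:
        caps = records.loc[records[by] == level, "capillaries"]
        data[level] = np.bincount(np.clip(caps, 0, kmax), minlength=kmax + 1)
    return pd.DataFrame(data, index=pd.RangeIndex(kmax + 1, name="capillaries")).T
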