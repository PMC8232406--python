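"""Per-interval indirect-calorimetry computations.

From the two gas channels VO2 and VCO2 (ml/kg/hr) the module derives:

* RER  = VCO2 / VO2                      (respiratory exchange ratio)
* CV   = 3.815 + 1.232 * RER             (Lusk calorific value, kcal per L O2)
* EE   = CV * VO2(L/kg/hr)               (energy expenditure / heat, kcal/kg/hr)
* carbohydrate oxidation = 4.585 * VCO2 - 3.226 * VO2   (Frayn-type linear form)
* lipid oxidation        = 1.695 * VO2  - 1.701 * VCO2

The two oxidation equations form a nonsingular 2x2 linear system, so the gas
volumes can be recovered exactly from the oxidation rates
(:func:`invert_substrate_oxidation`); this inversion is the consistency check
used to tie the reported 24-h oxidation rates back to the reported 24-h RER.

Scale convention: EE uses VO2 in L/kg/hr (so a mouse at RER 0.90 and VO2
~3860 ml/kg/hr expends ~19 kcal/kg/hr).  The oxidation forms are applied to
gas values expressed in L/kg/hr and the outputs carry the nominal unit string
"g/min"; the two scales are reported independently and are not mutually
consistent under any single VO2 unit (see docs/methods.md).  No clamping is
applied to negative oxidation values: the linear forms make the lipid channel
cross zero at RER = 1.695/1.701 ~= 0.99647 and the carbohydrate channel at
RER = 3.226/4.585 ~= 0.70359, and values outside those roots are reported as
computed, with counters on the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .calorimetry_io import CalorimetryTrace

__all__ = [
    "CV_INTERCEPT",
    "CV_SLOPE",
    "CARB_VCO2_COEF",
    "CARB_VO2_COEF",
    "LIPID_VO2_COEF",
    "LIPID_VCO2_COEF",
    "LIPID_ZERO_RER",
    "CARB_ZERO_RER",
    "MetabolicSeries",
    "compute_rer",
    "compute_cv",
    "compute_ee",
    "compute_substrate_oxidation",
    "invert_substrate_oxidation",
    "derive_metabolic_series",
]

# Lusk calorific value: kcal per liter O2 as an affine function of RER.
CV_INTERCEPT = 3.815
CV_SLOPE = 1.232

# Substrate-oxidation linear forms.
CARB_VCO2_COEF = 4.585
CARB_VO2_COEF = 3.226
LIPID_VO2_COEF = 1.695
LIPID_VCO2_COEF = 1.701

# Roots of the two linear forms in RER = VCO2/VO2.
LIPID_ZERO_RER = LIPID_VO2_COEF / LIPID_VCO2_COEF  # ~0.99647
CARB_ZERO_RER = CARB_VO2_COEF / CARB_VCO2_COEF  # ~0.70359

# Determinant of the 2x2 system mapping (vo2, vco2) -> (carb, lipid).
_DET = (-CARB_VO2_COEF) * (-LIPID_VCO2_COEF) - CARB_VCO2_COEF * LIPID_VO2_COEF

ArrayLike = Union[float, np.ndarray]


def compute_rer(vo2: ArrayLike, vco2: ArrayLike) -> ArrayLike:
    """Respiratory exchange ratio VCO2/VO2 (dimensionless).

    Raises ``ValueError`` if any VO2 is non-positive.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 <= 0):
        bad = np.nonzero(np.atleast_1d(vo2 <= 0))[0]
        raise ValueError(f"non-positive vo2 at indices {[int(i) for i in bad[:5]]}")
    out = vco2 / vo2
    return out if out.ndim else float(out)


def compute_cv(rer: ArrayLike) -> ArrayLike:
    """Lusk calorific value CV = 3.815 + 1.232 * RER (kcal per L O2)."""
    out = CV_INTERCEPT + CV_SLOPE * np.asarray(rer, dtype=float)
    return out if out.ndim else float(out)


def compute_ee(cv: ArrayLike, vo2: ArrayLike) -> ArrayLike:
    """Energy expenditure EE = CV * VO2 in kcal/kg/hr, with VO2 in ml/kg/hr."""
    out = np.asarray(cv, dtype=float) * np.asarray(vo2, dtype=float) / 1000.0
    return out if out.ndim else float(out)


def compute_substrate_oxidation(
    vo2: ArrayLike, vco2: ArrayLike
) -> Tuple[ArrayLike, ArrayLike]:
    """Carbohydrate and lipid oxidation rates from the two linear forms.

    carb  = 4.585 * VCO2 - 3.226 * VO2
    lipid = 1.695 * VO2  - 1.701 * VCO2

    Inputs are expected on the oxidation scale (L/kg/hr when fed from a gas
    trace); negative outputs are returned as computed, not clamped.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    carb = CARB_VCO2_COEF * vco2 - CARB_VO2_COEF * vo2
    lipid = LIPID_VO2_COEF * vo2 - LIPID_VCO2_COEF * vco2
    if carb.ndim == 0:
        return float(carb), float(lipid)
    return carb, lipid


def invert_substrate_oxidation(
    carb_ox: ArrayLike, lipid_ox: ArrayLike
) -> Tuple[ArrayLike, ArrayLike]:
    """Recover (VO2, VCO2) from (carbohydrate, lipid) oxidation rates.

    Exact solve of the 2x2 linear system; round-trips through
    :func:`compute_substrate_oxidation` to within 1e-9.
    """
    carb = np.asarray(carb_ox, dtype=float)
    lipid = np.asarray(lipid_ox, dtype=float)
    # [carb]   [-3.226  4.585] [vo2 ]
    # [lipid] = [ 1.695 -1.701] [vco2]   -> Cramer's rule
    vo2 = (carb * (-LIPID_VCO2_COEF) - CARB_VCO2_COEF * lipid) / _DET
    vco2 = ((-CARB_VO2_COEF) * lipid - LIPID_VO2_COEF * carb) / _DET
    if vo2.ndim == 0:
        return float(vo2), float(vco2)
    return vo2, vco2


@dataclass
class MetabolicSeries:
    """Parallel per-interval metabolic channels derived from one gas trace."""

    subject_id: str
    group: str
    timepoint: str
    interval_start: np.ndarray  # datetime64[s]
    rer: np.ndarray  # dimensionless
    cv: np.ndarray  # kcal per L O2
    ee: np.ndarray  # kcal/kg/hr
    carb_ox: np.ndarray  # nominal "g/min" scale (see module docstring)
    lipid_ox: np.ndarray  # nominal "g/min" scale
    interval_width: int = 4  # minutes
    n_negative_carb: int = 0
    n_negative_lipid: int = 0

    def __len__(self) -> int:
        return len(self.interval_start)

    @property
    def intervals_per_day(self) -> int:
        return 1440 // self.interval_width

    def is_full_day(self) -> bool:
        return len(self) == self.intervals_per_day

    def channel(self, name: str) -> np.ndarray:
        if name not in ("rer", "cv", "ee", "carb_ox", "lipid_ox"):
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per interval, all channels."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "timepoint": self.timepoint,
                "timestamp": self.interval_start,
                "rer": self.rer,
                "cv": self.cv,
                "ee": self.ee,
                "carb_ox": self.carb_ox,
                "lipid_ox": self.lipid_ox,
            }
        )


def derive_metabolic_series(trace: CalorimetryTrace) -> MetabolicSeries:
    """Compute all derived channels for one gas trace.

    RER/CV/EE use the trace's ml/kg/hr gas values directly (EE converts to
    L/kg/hr internally); the oxidation forms are fed L/kg/hr values.
    """
    try:
        rer = compute_rer(trace.vo2, trace.vco2)
    except ValueError as exc:
        raise ValueError(f"{trace.subject_id}: {exc}") from exc
    cv = compute_cv(rer)
    ee = compute_ee(cv, trace.vo2)
    carb, lipid = compute_substrate_oxidation(trace.vo2 / 1000.0, trace.vco2 / 1000.0)
    return MetabolicSeries(
        subject_id=trace.subject_id,
        group=trace.group,
        timepoint=trace.timepoint,
        interval_start=trace.interval_start,
        rer=np.asarray(rer, dtype=float),
        cv=np.asarray(cv, dtype=float),
        ee=np.asarray(ee, dtype=float),
        carb_ox=np.asarray(carb, dtype=float),
        lipid_ox=np.asarray(lipid, dtype=float),
        interval_width=trace.interval_width,
        n_negative_carb=int(np.sum(np.asarray(carb) < 0)),
        n_negative_lipid=int(np.sum(np.asarray(lipid) < 0)),
    )
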