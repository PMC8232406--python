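#!/usr/bin/env python
"""Baseline 24-h metabolic and physical-activity phenotype (n = 28).

Simulates the pre-allocation cohort of 28 subject-days under the baseline
preset, runs the full metric pipeline, and reports the headline numbers:
24-h metabolic rate (~19 kcal/kg/hr), phase delta (~4.5), RER by phase
(0.93 active / 0.87 inactive, 0.90 over 24 h), and ambulation (~1.3 km per
day, ~1.0 km in the dark phase).  Writes the per-subject metric table under
results/.
"""

from pathlib import Path

from metaflex.calorimetry_io import PhaseSchedule
from metaflex.pipeline import cohort_summary_table, subject_metrics_table
from metaflex.synthetic_data import CohortDesign, generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    design = CohortDesign(
        groups=(("all", 28),),
        timepoints=("pre",),
        presets={("all", "pre"): "baseline"},
        seed=SEED,
    )
    metrics = subject_metrics_table(generate_cohort(design), PhaseSchedule())
    RESULTS.mkdir(exist_ok=True)
    metrics.to_csv(RESULTS / "baseline_subject_metrics.csv", index=False,
                   float_format="%.6f")
    cohort_summary_table(metrics).to_csv(
        RESULTS / "baseline_cohort_summary.csv", index=False, float_format="%.6f"
    )

    mean = metrics.mean(numeric_only=True)
    print(f"Baseline cohort (n = {len(metrics)}, seed {SEED})")
    print(f"  24-h metabolic rate : {mean['mean_ee_24h']:.2f} kcal/kg/hr")
    print(f"  phase delta (flux)  : {mean['delta_ee']:.2f} kcal/kg/hr")
    print(f"  RER 24 h / active / inactive : {mean['mean_rer_24h']:.3f} / "
          f"{mean['mean_rer_active']:.3f} / {mean['mean_rer_inactive']:.3f}")
    print(f"  delta RER (flexibility)      : {mean['delta_rer']:.3f}")
    print(f"  ambulation 24 h / active     : {mean['distance_24h']:.2f} / "
          f"{mean['distance_active']:.2f} km")
    print(f"  AUC (h-based) EE / RER       : {mean['auc_ee_24h']:.0f} / "
          f"{mean['auc_rer_24h']:.1f}")


if __name__ == "__main__":
    main()
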