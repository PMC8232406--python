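"""Generator calibration, determinism, and parameter recovery."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from metaflex.activity_analysis import summarize_activity
from metaflex.diurnal_analysis import flexibility_metrics
from metaflex.metabolic_metrics import derive_metabolic_series
from metaflex.synthetic_data import (
    CohortDesign,
    GeneratorPreset,
    builtin_presets,
    generate_activity_trace,
    generate_calorimetry_trace,
    generate_cohort,
    generate_terminal_tables,
)


class TestPresets:
    def test_baseline_phase_means_solve_daily_targets(self, presets):
        """active = m + d/2, inactive = m - d/2 for m=19, d=4.5."""
        b = presets["baseline"]
        assert b.ee_active_mean == pytest.approx(21.25)
        assert b.ee_inactive_mean == pytest.approx(16.75)
        assert b.rer_active_mean == pytest.approx(0.93)
        assert b.rer_inactive_mean == pytest.approx(0.87)

    def test_week6_scales_daily_means_not_delta(self, presets):
        b, w6 = presets["baseline"], presets["vml_6wk"]
        ee24 = (w6.ee_active_mean + w6.ee_inactive_mean) / 2
        assert ee24 == pytest.approx(0.90 * 19.0)  # 17.1 kcal/kg/hr
        assert w6.ee_active_mean - w6.ee_inactive_mean == pytest.approx(
            b.ee_active_mean - b.ee_inactive_mean
        )
        rer24 = (w6.rer_active_mean + w6.rer_inactive_mean) / 2
        assert rer24 == pytest.approx(0.96 * 0.90)

    def test_week2_keeps_baseline_ee(self, presets):
        b, w2 = presets["baseline"], presets["vml_2wk"]
        assert w2.ee_active_mean == b.ee_active_mean
        assert w2.ee_inactive_mean == b.ee_inactive_mean
        # RER rhythm mildly blunted relative to baseline
        assert (w2.rer_active_mean + w2.rer_inactive_mean) / 2 < 0.90

    def test_baseline_ambulation_rates_match_published_distance(self, presets):
        b = presets["baseline"]
        # 1.0 km active = 1e5 cm / 1.27 cm per break ~= 78,740 breaks
        assert b.amb_rate_active * 4320 == pytest.approx(78740.16, abs=0.01)
        assert b.amb_rate_inactive * 4320 == pytest.approx(23622.05, abs=0.01)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("ee_active_mean", -1.0),
            ("rer_active_mean", 1.3),
            ("rer_inactive_mean", 0.5),
            ("ee_noise_sd", -0.1),
            ("ar_coefficient", 1.0),
            ("nonamb_fraction", 1.5),
        ],
    )
    def test_invalid_presets_rejected(self, presets, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(presets["baseline"], **{field: value})


class TestCalorimetryTrace:
    def test_noiseless_phase_means_exact(self, noiseless_series):
        """Generation followed by the metric pipeline reproduces the preset."""
        assert np.mean(noiseless_series.ee[180:]) == pytest.approx(21.25, abs=1e-12)
        assert np.mean(noiseless_series.ee[:180]) == pytest.approx(16.75, abs=1e-12)
        assert np.mean(noiseless_series.rer) == pytest.approx(0.90, abs=1e-12)

    def test_same_seed_identical_trace(self, baseline_preset):
        t1 = generate_calorimetry_trace(baseline_preset, seed=123)
        t2 = generate_calorimetry_trace(baseline_preset, seed=123)
        assert np.array_equal(t1.vo2, t2.vo2)
        assert np.array_equal(t1.vco2, t2.vco2)

    def test_different_seeds_differ(self, baseline_preset):
        t1 = generate_calorimetry_trace(baseline_preset, seed=1)
        t2 = generate_calorimetry_trace(baseline_preset, seed=2)
        assert not np.array_equal(t1.vo2, t2.vo2)

    def test_trace_shape_and_clock(self, noisy_trace):
        assert len(noisy_trace) == 360
        assert noisy_trace.is_full_day()
        assert str(noisy_trace.interval_start[0]).endswith("06:00:00")

    def test_rer_stays_in_physiologic_band(self, baseline_preset):
        for seed in range(5):
            trace = generate_calorimetry_trace(baseline_preset, seed=seed)
            rer = trace.vco2 / trace.vo2
            assert np.all(rer > 0) and np.all(rer <= 1.2)


class TestActivityTrace:
    def test_shape(self, activity_trace):
        assert len(activity_trace) == 8640
        assert activity_trace.is_full_day()

    def test_zero_rates_give_all_zero_trace(self, baseline_preset):
        silent = dataclasses.replace(
            baseline_preset, amb_rate_active=0.0, amb_rate_inactive=0.0
        )
        trace = generate_activity_trace(silent, seed=3)
        assert trace.x_total.sum() == 0
        assert trace.y_amb.sum() == 0
        assert trace.z_total.sum() == 0

    def test_poisson_variance_matches_mean(self, baseline_preset):
        """Per-bin ambulatory counts are Poisson: variance ~ mean."""
        trace = generate_activity_trace(baseline_preset, seed=5)
        active = trace.x_amb[4320:]  # 18:00 onward, constant rate
        ratio = active.var() / active.mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_expected_distance_recovers_target(self, baseline_preset):
        """Across seeded replicates the 24-h distance recovers 1.3 km (2 SE)."""
        dists = [
            summarize_activity(generate_activity_trace(baseline_preset, seed=s)).distance_24h
            for s in range(30)
        ]
        se = np.std(dists, ddof=1) / np.sqrt(len(dists))
        assert abs(np.mean(dists) - 1.3) <= 2 * se + 1e-4


class TestCohort:
    def _design(self, seed=0):
        return CohortDesign(
            groups=(("vml", 4),),
            timepoints=("pre", "2wk", "6wk"),
            presets={
                ("vml", "pre"): "baseline",
                ("vml", "2wk"): "vml_2wk",
                ("vml", "6wk"): "vml_6wk",
            },
            seed=seed,
        )

    def test_one_pair_per_subject_per_timepoint(self):
        recs = generate_cohort(self._design())
        assert len(recs) == 12
        assert len({(r.subject_id, r.timepoint) for r in recs}) == 12
        # repeated-measures: subjects persist across timepoints
        assert len({r.subject_id for r in recs}) == 4

    def test_same_design_seed_reproduces_cohort(self):
        r1 = generate_cohort(self._design(seed=9))
        r2 = generate_cohort(self._design(seed=9))
        for a, b in zip(r1, r2):
            assert a.calorimetry.equals(b.calorimetry)
            assert a.activity.equals(b.activity)

    def test_different_seeds_equal_in_expectation(self):
        """Noise differs across seeds but phase means agree within 2 SE."""
        ee_means = {seed: [] for seed in (1, 2)}
        for seed in ee_means:
            design = CohortDesign(
                groups=(("g", 25),),
                timepoints=("pre",),
                presets={("g", "pre"): "baseline"},
                seed=seed,
            )
            for rec in generate_cohort(design):
                series = derive_metabolic_series(rec.calorimetry)
                ee_means[seed].append(flexibility_metrics(series).mean_ee_24h)
        m1, m2 = (np.mean(ee_means[s]) for s in (1, 2))
        se = np.hypot(
            np.std(ee_means[1], ddof=1) / 5.0, np.std(ee_means[2], ddof=1) / 5.0
        )
        assert abs(m1 - m2) <= 3 * se

    def test_duplicate_group_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate group labels"):
            CohortDesign(
                groups=(("a", 2), ("a", 3)),
                timepoints=("pre",),
                presets={("a", "pre"): "baseline"},
            )

    def test_missing_preset_rejected(self):
        with pytest.raises(ValueError, match="no preset"):
            CohortDesign(groups=(("a", 2),), timepoints=("pre", "post"),
                         presets={("a", "pre"): "baseline"})


class TestTerminalTables:
    def test_sd_zero_gives_exact_group_means(self):
        func, fibers = generate_terminal_tables(seed=0, sd_scale=0.0)
        by_group = func.groupby("group")
        assert by_group["gastroc_weight_ratio"].mean()["control"] == pytest.approx(1.08)
        assert by_group["peak_torque"].mean()["vml_4wk"] == pytest.approx(12.3)
        assert func.groupby("group")["body_mass"].std().max() == pytest.approx(0.0)

    def test_control_medial_iib_proportion(self):
        """Type IIb share of medial control fibers ~ the published 59%."""
        _, fibers = generate_terminal_tables(seed=1)
        medial = fibers.query("group == 'control' and region == 'medial'")
        prop = (medial["fiber_type"] == "IIb").mean()
        assert prop == pytest.approx(0.59, abs=0.05)

    def test_fiber_table_schema_and_ranges(self):
        _, fibers = generate_terminal_tables(seed=2)
        assert set(fibers["region"]) == {"lateral", "mid", "medial"}
        assert set(fibers["fiber_type"]) <= {"I", "IIa", "IIb", "IIx"}
        assert (fibers["csa"] > 0).all()
        assert (fibers["capillaries"] >= 0).all()

    def test_torque_frequency_profile_is_monotone_to_peak(self):
        func, _ = generate_terminal_tables(seed=3, sd_scale=0.0)
        cols = [c for c in func.columns if c.startswith("torque_")]
        profile = func.iloc[0][cols].to_numpy(dtype=float)
        assert np.all(np.diff(profile) >= -1e-12)
        assert profile[-1] == pytest.approx(func.iloc[0]["peak_torque"])

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown terminal group"):
            generate_terminal_tables(group_sizes=[("sham", 3)])
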