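"""Phase logic, binning conservation, moving average, AUC, flexibility."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from metaflex.calorimetry_io import PhaseSchedule
from metaflex.diurnal_analysis import (
    assign_phase,
    auc,
    bin_series,
    binned_auc,
    flexibility_metrics,
    moving_average,
    smoothed_timestamps,
)
from metaflex.metabolic_metrics import MetabolicSeries

SCHEDULE = PhaseSchedule()


def _series_from_channel(values):
    """Wrap a 360-interval channel into a MetabolicSeries (all channels equal)."""
    values = np.asarray(values, dtype=float)
    ts = np.datetime64("2000-01-01T06:00:00", "s") + np.arange(len(values)) * np.timedelta64(
        240, "s"
    )
    return MetabolicSeries(
        subject_id="m",
        group="g",
        timepoint="pre",
        interval_start=ts,
        rer=values,
        cv=values,
        ee=values,
        carb_ox=values,
        lipid_ox=values,
    )


class TestAssignPhase:
    @pytest.mark.parametrize(
        "clock,expected",
        [
            (dt.time(10, 0), "inactive"),  # light hours: lowest metabolic values
            (dt.time(20, 0), "active"),  # dark hours: peak metabolic rate
            (dt.time(6, 0), "inactive"),  # half-open boundary: lights-on is light
            (dt.time(18, 0), "active"),
            (dt.time(5, 59), "active"),
        ],
    )
    def test_clock_assignment(self, clock, expected):
        assert assign_phase(clock, SCHEDULE) == expected

    def test_datetime_and_datetime64_agree(self):
        stamp = dt.datetime(2000, 1, 1, 20, 0)
        assert assign_phase(stamp, SCHEDULE) == assign_phase(np.datetime64(stamp), SCHEDULE)


class TestBinSeries:
    def test_constant_channel_any_width(self):
        series = _series_from_channel(np.full(360, 3.14))
        for width in (1, 6, 12, 24):
            table = bin_series(series, width)
            assert np.allclose(table["mean"], 3.14)
            assert len(table[table["channel"] == "ee"]) == 24 // width

    def test_noiseless_baseline_12h_bins(self, noiseless_series):
        table = bin_series(noiseless_series, 12)
        ee = table[table["channel"] == "ee"].set_index("phase")["mean"]
        assert ee["active"] == pytest.approx(21.25, abs=1e-12)
        assert ee["inactive"] == pytest.approx(16.75, abs=1e-12)

    def test_bin_mean_conservation(self, noisy_series):
        """24-h mean equals the mean of the 12-h and of the 6-h bin means."""
        for channel in ("ee", "rer"):
            mean24 = bin_series(noisy_series, 24).query("channel == @channel")["mean"].iloc[0]
            for width in (1, 6, 12):
                means = bin_series(noisy_series, width).query("channel == @channel")["mean"]
                assert np.mean(means) == pytest.approx(mean24, abs=1e-12)

    def test_six_hour_bins_anchored_and_pure_phase(self, noisy_series):
        table = bin_series(noisy_series, 6).query("channel == 'ee'")
        assert list(table["bin_start"]) == ["06:00", "12:00", "18:00", "00:00"]
        assert list(table["phase"]) == ["inactive", "inactive", "active", "active"]

    def test_partial_day_rejected(self):
        series = _series_from_channel(np.ones(100))
        with pytest.raises(ValueError, match="24 h"):
            bin_series(series, 12)

    def test_invalid_width_rejected(self, noisy_series):
        with pytest.raises(ValueError, match="bin_width"):
            bin_series(noisy_series, 3)


class TestMovingAverage:
    def test_constant_is_fixed_point(self):
        out = moving_average(np.full(100, 2.5))
        assert out.shape == (86,)
        assert np.allclose(out, 2.5)

    def test_linear_ramp_shifts_by_window_center(self):
        """Trailing mean of an arithmetic ramp lags by (window-1)/2 steps."""
        step = 0.3
        x = step * np.arange(100)
        out = moving_average(x, window=15)
        expected = x[14:] - 7 * step
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_full_day_yields_346_points(self, noisy_series):
        assert moving_average(noisy_series.ee).shape == (346,)
        assert smoothed_timestamps(noisy_series.interval_start).shape == (346,)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            moving_average(np.ones(10), window=15)

    def test_commutes_with_affine_transform(self, noisy_series):
        x = noisy_series.ee
        np.testing.assert_allclose(
            moving_average(3.0 * x + 1.0), 3.0 * moving_average(x) + 1.0, atol=1e-9
        )


class TestAuc:
    def test_constant_one_over_day_is_23(self):
        assert auc(np.ones(346)) == pytest.approx(23.0, abs=1e-12)

    def test_constant_zero(self):
        assert auc(np.zeros(50)) == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            auc(np.array([1.0]))

    def test_linearity(self):
        rng = np.random.default_rng(11)
        f, g = rng.normal(size=200), rng.normal(size=200)
        a, b = 2.5, -1.25
        assert auc(a * f + b * g) == pytest.approx(a * auc(f) + b * auc(g), abs=1e-9)

    def test_six_hour_sub_aucs(self, noisy_series):
        smooth = moving_average(noisy_series.ee)
        ts = smoothed_timestamps(noisy_series.interval_start)
        sub = binned_auc(smooth, ts)
        assert set(sub) == {"06:00", "12:00", "18:00", "00:00"}
        assert all(v > 0 for v in sub.values())


class TestFlexibilityMetrics:
    def test_noiseless_baseline_deltas(self, noiseless_series):
        flex = flexibility_metrics(noiseless_series)
        assert flex.delta_ee == pytest.approx(4.5, abs=1e-12)
        assert flex.delta_rer == pytest.approx(0.06, abs=1e-12)
        assert flex.mean_ee_24h == pytest.approx(19.0, abs=1e-12)

    def test_flat_series_has_zero_deltas(self):
        flex = flexibility_metrics(_series_from_channel(np.full(360, 1.0)))
        assert flex.delta_ee == 0.0
        assert flex.delta_rer == 0.0
        assert flex.auc_ee_24h == pytest.approx(23.0, abs=1e-12)

    def test_aucs_nonnegative_for_positive_channels(self, noisy_series):
        flex = flexibility_metrics(noisy_series)
        assert flex.auc_ee_24h > 0
        assert flex.auc_rer_24h > 0
        assert all(v > 0 for v in flex.auc_ee_6h.values())
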