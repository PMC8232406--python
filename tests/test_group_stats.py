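"""ANOVA family, Tukey HSD and chi-squared against independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metaflex.group_stats import (
    CHI2_CORRECTED_ALPHA,
    chi_squared_distribution_test,
    one_way_anova,
    pool_low_expected_bins,
    repeated_measures_anova,
    tukey_hsd,
    two_way_anova,
)


def _hand_one_way_f(groups):
    """Textbook sums-of-squares oracle, independent of scipy."""
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(all_values) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


class TestOneWayAnova:
    def test_equal_means_give_f_zero(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_sums_of_squares(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        f_hand, df_b, df_w = _hand_one_way_f([np.asarray(g, float) for g in groups])
        res = one_way_anova(groups)
        assert f_hand == pytest.approx(3.0, abs=1e-12)  # frozen oracle value
        assert res.statistic == pytest.approx(f_hand, abs=1e-12)
        assert res.df == (2, 6)

    def test_two_groups_reproduce_pooled_t_test(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p_t, rel=1e-10)

    def test_matches_permutation_oracle(self):
        """F-test p agrees with a label-permutation p on small normal samples."""
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 6), rng.normal(0.8, 1, 6), rng.normal(0.2, 1, 6)]
        observed = one_way_anova(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        n_perm, hits = 4000, 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            f_perm, _, _ = _hand_one_way_f(parts)
            hits += f_perm >= observed.statistic
        p_perm = hits / n_perm
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert observed.p_value == pytest.approx(p_perm, abs=3 * mc_se + 0.01)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            one_way_anova([[1.0], [2.0, 3.0]])

    def test_type_one_error_near_nominal(self):
        """Null rejection rate within 2 binomial SE of 0.05 (600 replicates)."""
        rng = np.random.default_rng(99)
        n_rep = 600
        rejections = sum(
            one_way_anova([rng.normal(size=8) for _ in range(3)]).significant
            for _ in range(n_rep)
        )
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 2 * se


class TestRepeatedMeasures:
    def test_constant_timepoints_give_f_zero(self):
        data = np.tile([[3.0], [5.0], [9.0]], (1, 4))  # subjects differ, time flat
        res = repeated_measures_anova(data)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_timepoints_equal_paired_t_squared(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(9, 2))
        data[:, 1] += 0.6
        res = repeated_measures_anova(data)
        t, p = sps.ttest_rel(data[:, 1], data[:, 0])
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_invariant_to_additive_subject_shifts(self):
        rng = np.random.default_rng(17)
        data = rng.normal(size=(8, 3))
        shifted = data + rng.normal(0, 50, size=(8, 1))
        res0 = repeated_measures_anova(data)
        res1 = repeated_measures_anova(shifted)
        assert res1.statistic == pytest.approx(res0.statistic, rel=1e-9)

    def test_df_structure(self):
        rng = np.random.default_rng(3)
        res = repeated_measures_anova(rng.normal(size=(12, 3)))
        assert res.df == (2, 22)

    def test_missing_cells_rejected(self):
        data = np.ones((3, 3))
        data[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            repeated_measures_anova(data)


def _two_way_frame(rng, n_per_cell, effect_b=0.0):
    rows = []
    for a in ("g1", "g2", "g3"):
        for b_idx, b in enumerate(("I", "IIa", "IIb", "IIx")):
            for _ in range(n_per_cell):
                rows.append(
                    {"y": rng.normal(b_idx * effect_b, 1.0), "grp": a, "ftype": b}
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_detects_injected_fiber_type_effect_only(self):
        """A 2-SD fiber-type effect: its main effect significant, interaction not."""
        rng = np.random.default_rng(8)
        frame = _two_way_frame(rng, n_per_cell=16, effect_b=2.0)
        res = two_way_anova(frame, "y", "grp", "ftype")
        assert res["ftype"].significant
        assert not res["interaction"].significant

    def test_balanced_matches_hand_main_effect(self):
        """On balanced data Type-II equals the textbook factor sum of squares."""
        rng = np.random.default_rng(15)
        frame = _two_way_frame(rng, n_per_cell=5, effect_b=0.8)
        res = two_way_anova(frame, "y", "grp", "ftype")
        grand = frame["y"].mean()
        n_b = len(frame) // frame["ftype"].nunique()
        ss_b = sum(
            n_b * (sub["y"].mean() - grand) ** 2
            for _, sub in frame.groupby("ftype")
        )
        cell_means = frame.groupby(["grp", "ftype"])["y"].transform("mean")
        ss_err = ((frame["y"] - cell_means) ** 2).sum()
        df_b = frame["ftype"].nunique() - 1
        df_err = len(frame) - frame["grp"].nunique() * frame["ftype"].nunique()
        f_hand = (ss_b / df_b) / (ss_err / df_err)
        assert res["ftype"].statistic == pytest.approx(f_hand, rel=1e-9)

    def test_null_f_near_one_in_expectation(self):
        rng = np.random.default_rng(4)
        f_values = [
            two_way_anova(_two_way_frame(rng, 4), "y", "grp", "ftype")["grp"].statistic
            for _ in range(120)
        ]
        # E[F(2, dfe)] = dfe / (dfe - 2) with dfe = 36
        expected = 36 / 34
        se = np.std(f_values, ddof=1) / np.sqrt(len(f_values))
        assert abs(np.mean(f_values) - expected) <= 3 * se

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(2)
        frame = _two_way_frame(rng, 3)
        frame = frame[~((frame["grp"] == "g1") & (frame["ftype"] == "IIx"))]
        with pytest.raises(ValueError, match="empty factor cells"):
            two_way_anova(frame, "y", "grp", "ftype")


class TestTukey:
    def test_identical_groups_adjusted_p_one(self):
        res = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.posthoc[0].adjusted_p == pytest.approx(1.0)
        assert not res.posthoc[0].significant

    def test_single_shifted_group_flags_its_two_pairs(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        c = rng.normal(10, 1, 10)  # shifted by 10 within-SDs
        res = tukey_hsd([a, b, c], labels=["a", "b", "c"])
        verdicts = {tuple(sorted(map(str, p.pair))): p.significant for p in res.posthoc}
        assert verdicts[("a", "c")] and verdicts[("b", "c")]
        assert not verdicts[("a", "b")]

    def test_adjusted_p_at_least_pairwise_t(self):
        rng = np.random.default_rng(23)
        groups = [rng.normal(0.3 * i, 1, 9) for i in range(3)]
        res = tukey_hsd(groups)
        for pair in res.posthoc:
            i, j = pair.pair
            _, p_t = sps.ttest_ind(groups[i], groups[j])
            assert pair.adjusted_p >= p_t - 1e-12


class TestChiSquared:
    def test_identical_histograms(self):
        res = chi_squared_distribution_test([10, 20, 30], [10, 20, 30])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_worked_2x2(self):
        """chi2 = N(ad-bc)^2 / (r1 r2 c1 c2) = 6.667 for [[10,20],[20,10]]."""
        res = chi_squared_distribution_test([10, 20], [20, 10], pool=False)
        assert res.statistic == pytest.approx(6.667, abs=1e-3)
        assert res.df == (1.0,)

    def test_corrected_alpha_is_bonferroni_over_three_pairs(self):
        assert CHI2_CORRECTED_ALPHA == pytest.approx(0.05 / 3, abs=2e-4)
        res = chi_squared_distribution_test([10, 20], [20, 10], pool=False)
        assert res.alpha == CHI2_CORRECTED_ALPHA

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            chi_squared_distribution_test([0, 0], [1, 2])

    def test_pooling_merges_sparse_bins(self):
        table = np.array([[50.0, 40.0, 1.0, 0.0], [45.0, 42.0, 0.0, 1.0]])
        pooled = pool_low_expected_bins(table)
        assert pooled.shape[1] < 4
        exp = np.outer(pooled.sum(axis=1), pooled.sum(axis=0)) / pooled.sum()
        assert (exp >= 1.0).all() and (exp >= 5.0).mean() >= 0.8

    def test_pooling_preserves_zero_statistic(self):
        """Proportional histograms stay chi2 = 0 through pooling."""
        a = np.array([40, 30, 3, 2])
        res = chi_squared_distribution_test(a, 2 * a, pool=True)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
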