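"""Bait normalization, fold enrichment, and the two-sample t-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apmstats.enrichment import (
    bait_normalize,
    condition_t_tests,
    fold_enrichment,
    homoscedastic_t_test,
    welch_t_test,
)
from apmstats.errors import InsufficientReplicatesError, NormalizationError
from apmstats.model import AbundanceMatrix, NormalizedMatrix
from tests.conftest import make_matrix

import pandas as pd


def norm_of(wt, var, layout):
    cols = layout.experimental_channels
    data = pd.DataFrame({"P": list(wt) + list(var)}, index=cols).T
    return NormalizedMatrix(data=data, bait_id="BAIT")


class TestBaitNormalize:
    def test_direct_ratio(self, layout9):
        matrix = make_matrix({"P": [250] * 6 + [1] * 3})
        norm = bait_normalize(matrix, layout9)
        assert norm.data.loc["P", "WT-1"] == pytest.approx(250 / 1000)

    def test_bait_row_is_identically_one(self, layout9):
        matrix = make_matrix({"P": [1] * 9})
        norm = bait_normalize(matrix, layout9)
        assert np.allclose(norm.data.loc["BAIT"], 1.0)

    def test_per_channel_scaling_cancels(self, layout9):
        matrix = make_matrix({"P": [250, 260, 240, 300, 310, 290, 5, 5, 5]})
        scaled = matrix.data.copy()
        scaled["VAR-2"] *= 7.0
        norm_a = bait_normalize(matrix, layout9)
        norm_b = bait_normalize(AbundanceMatrix(scaled, bait_id="BAIT"), layout9)
        assert np.allclose(norm_a.data, norm_b.data)

    def test_control_channels_absent_from_output(self, layout9):
        norm = bait_normalize(make_matrix({"P": [1] * 9}), layout9)
        assert set(norm.data.columns) == set(layout9.experimental_channels)

    @pytest.mark.parametrize("bad_value", [0.0, np.nan])
    def test_zero_or_missing_bait_names_channel(self, layout9, bad_value):
        matrix = make_matrix({"P": [1] * 9})
        matrix.data.loc["BAIT", "VAR-3"] = bad_value
        with pytest.raises(NormalizationError, match="VAR-3"):
            bait_normalize(matrix, layout9)

    def test_missing_prey_value_propagates(self, layout9):
        matrix = make_matrix({"P": [250, np.nan, 250, 250, 250, 250, 1, 1, 1]})
        norm = bait_normalize(matrix, layout9)
        assert math.isnan(norm.data.loc["P", "WT-2"])


class TestFoldEnrichment:
    def test_ratio_of_condition_means(self, layout9):
        norm = norm_of(wt=(0.10, 0.10, 0.10), var=(0.20, 0.25, 0.15), layout=layout9)
        assert fold_enrichment(norm, layout9)["P"] == pytest.approx(2.0)

    def test_identical_conditions_give_unity(self, layout9):
        norm = norm_of((0.3, 0.4, 0.5), (0.3, 0.4, 0.5), layout9)
        assert fold_enrichment(norm, layout9)["P"] == pytest.approx(1.0)

    def test_bait_fold_enrichment_exactly_one(self, layout9):
        matrix = make_matrix({"P": [250] * 6 + [1] * 3})
        fe = fold_enrichment(bait_normalize(matrix, layout9), layout9)
        assert fe["BAIT"] == 1.0

    def test_missing_values_excluded_from_means(self, layout9):
        norm = norm_of((0.1, np.nan, 0.1), (0.3, 0.3, np.nan), layout9)
        assert fold_enrichment(norm, layout9)["P"] == pytest.approx(3.0)

    def test_zero_wt_mean_flagged_undefined_but_retained(self, layout9):
        norm = norm_of((0.0, 0.0, 0.0), (0.3, 0.3, 0.3), layout9)
        fe = fold_enrichment(norm, layout9)
        assert "P" in fe.index and math.isnan(fe["P"])

    def test_all_missing_condition_flagged_undefined(self, layout9):
        norm = norm_of((np.nan,) * 3, (0.3, 0.3, 0.3), layout9)
        assert math.isnan(fold_enrichment(norm, layout9)["P"])

    def test_ratio_of_means_equals_ratio_of_sums_at_equal_n(self, layout9):
        rng = np.random.default_rng(42)
        wt, var = rng.uniform(0.01, 1, 3), rng.uniform(0.01, 1, 3)
        fe = fold_enrichment(norm_of(wt, var, layout9), layout9)["P"]
        assert fe == pytest.approx(var.sum() / wt.sum())

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.1, 50.0), min_size=6, max_size=6))
    def test_invariant_under_per_channel_rescaling_of_raw_abundances(
        self, layout9, scales
    ):
        matrix = make_matrix({"P": [250, 270, 230, 400, 390, 410, 5, 5, 5]})
        scaled = matrix.data.copy()
        for c, s in zip(layout9.experimental_channels, scales):
            scaled[c] *= s
        fe_a = fold_enrichment(bait_normalize(matrix, layout9), layout9)["P"]
        fe_b = fold_enrichment(
            bait_normalize(AbundanceMatrix(scaled, bait_id="BAIT"), layout9), layout9
        )["P"]
        assert fe_b == pytest.approx(fe_a, rel=1e-12)


class TestHomoscedasticT:
    def test_identical_groups(self):
        res = homoscedastic_t_test([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.degrees_of_freedom == 4

    def test_hand_computed_example(self):
        # means 4 vs 2, pooled variance 2.5, t = 2/sqrt(2.5*2/3)
        res = homoscedastic_t_test([2, 4, 6], [1, 2, 3])
        assert res.t_statistic == pytest.approx(1.549, abs=1e-3)
        assert res.degrees_of_freedom == 4
        assert res.p_value == pytest.approx(0.196, abs=1e-3)

    def test_zero_variance_policies(self):
        assert homoscedastic_t_test([5, 5, 5], [7, 7, 7]).p_value == 0.0
        assert homoscedastic_t_test([5, 5, 5], [5, 5, 5]).p_value == 1.0

    def test_log_transform_equals_test_on_logs(self):
        a, b = [2.0, 4.0, 8.0], [1.0, 2.0, 3.0]
        direct = homoscedastic_t_test(np.log2(a), np.log2(b))
        viaflag = homoscedastic_t_test(a, b, log_transform=True)
        assert viaflag.p_value == pytest.approx(direct.p_value)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            homoscedastic_t_test([1.0], [1.0, 2.0])

    def test_log_transform_rejects_nonpositive(self):
        with pytest.raises(InsufficientReplicatesError):
            homoscedastic_t_test([0.0, 1.0], [1.0, 2.0], log_transform=True)


class TestWelchT:
    def test_identical_groups(self):
        assert welch_t_test([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_clearly_separated_groups(self):
        res = welch_t_test([0.30, 0.35, 0.40, 0.33], [0.60, 0.62, 0.66, 0.70])
        assert res.p_value < 0.01
        # cross-check against scipy's own Welch p
        _, p_ref = stats.ttest_ind(
            [0.30, 0.35, 0.40, 0.33], [0.60, 0.62, 0.66, 0.70], equal_var=False
        )
        assert res.p_value == pytest.approx(float(p_ref))

    def test_satterthwaite_df_between_min_and_sum(self):
        res = welch_t_test([1.0, 2.0, 4.0], [10.0, 10.5, 11.0, 11.5])
        assert 2 <= res.degrees_of_freedom <= 5

    def test_near_agreement_with_pooled_at_equal_variance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        pooled = homoscedastic_t_test(a, b).p_value
        welch = welch_t_test(a, b).p_value
        assert welch == pytest.approx(pooled, rel=0.10)

    def test_zero_variance_policies(self):
        assert welch_t_test([5, 5, 5], [7, 7, 7]).p_value == 0.0
        assert welch_t_test([5, 5, 5], [5, 5, 5]).p_value == 1.0


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    st.lists(st.floats(-10, 10), min_size=2, max_size=8),
    st.lists(st.floats(-10, 10), min_size=2, max_size=8),
)
def test_swapping_groups_negates_t_and_preserves_p(a, b):
    for test in (homoscedastic_t_test, welch_t_test):
        fwd, rev = test(a, b), test(b, a)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9, abs=1e-12)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic, rel=1e-9, abs=1e-12)


class TestVectorizedTests:
    def test_matches_scalar_homoscedastic_test(self, layout9):
        rng = np.random.default_rng(11)
        matrix = make_matrix(
            {f"P{i}": list(rng.uniform(10, 500, 6)) + [1, 1, 1] for i in range(8)}
        )
        norm = bait_normalize(matrix, layout9)
        table = condition_t_tests(norm, layout9, log_transform=True)
        for pid in matrix.proteins:
            if pid == "BAIT":
                continue
            a = norm.data.loc[pid, layout9.variant_channels]
            b = norm.data.loc[pid, layout9.wt_channels]
            ref = homoscedastic_t_test(a, b, log_transform=True)
            assert table.loc[pid, "p"] == pytest.approx(ref.p_value)
            assert table.loc[pid, "t"] == pytest.approx(ref.t_statistic)

    def test_bait_gets_degenerate_p_of_one(self, layout9):
        norm = bait_normalize(make_matrix({"P": [1] * 9}), layout9)
        table = condition_t_tests(norm, layout9, log_transform=True)
        assert table.loc["BAIT", "p"] == 1.0

    def test_missing_values_yield_nan_p(self, layout9):
        matrix = make_matrix({"P": [250, np.nan, 250, 250, 250, 250, 1, 1, 1]})
        norm = bait_normalize(matrix, layout9)
        assert math.isnan(condition_t_tests(norm, layout9).loc["P", "p"])
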