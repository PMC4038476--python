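"""Cohort statistics: closed-form oracles, L_rel, proportions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from touchzap import (
    correlations,
    endpoint_proportions,
    l_rel,
    relative_access_resistance,
    summarize,
    two_proportion_z,
    two_sample_t,
)
from touchzap.reference import COHORT_COUNTS
from touchzap.stats import class_proportion, round_half_away


class TestLRel:
    def test_closed_form_two_cells(self):
        res = l_rel([100.0, 25.0])
        assert np.allclose(res.values, [2 / 3, 4 / 3])

    def test_equal_r_in_gives_all_ones(self):
        res = l_rel([80.0] * 6)
        assert np.allclose(res.values, 1.0)

    def test_normalization_mean_is_one_per_cohort(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(5, 300, 50)
        groups = ["neuron"] * 30 + ["glia"] * 20
        res = l_rel(r, groups)
        vals = pd.Series(res.values.to_numpy())
        for g in ("neuron", "glia"):
            sel = [i for i, x in enumerate(groups) if x == g]
            assert vals.iloc[sel].mean() == pytest.approx(1.0, abs=1e-12)

    @given(st.lists(st.floats(1.0, 1e4), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization_property(self, r_in):
        res = l_rel(r_in)
        assert float(np.mean(res.values)) == pytest.approx(1.0, rel=1e-9)

    def test_non_positive_r_in_rejected(self):
        with pytest.raises(ValueError):
            l_rel([100.0, -5.0])


class TestProportions:
    def test_reference_counts_reproduce_printed_percentages(self):
        counts = COHORT_COUNTS.groupby("cell_class").sum()
        props = endpoint_proportions(counts)
        assert round_half_away(100 * props.loc["neuron", "TZ"]) == 48
        assert round_half_away(100 * props.loc["glia", "TZ"]) == 61
        assert round_half_away(100 * props.loc["neuron", "TZS"]) == 40
        assert round_half_away(100 * props.loc["glia", "TZS"]) == 24
        # the source text prints 12% for neuron TS; the counts give 11.5%
        assert abs(100 * props.loc["neuron", "TS"] - 12) < 1.0
        assert round_half_away(100 * props.loc["glia", "TS"]) == 15

    def test_rows_sum_to_one_over_touch_endpoints(self):
        counts = COHORT_COUNTS.groupby("cell_class").sum()
        props = endpoint_proportions(counts)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_single_endpoint_table_gives_100_percent(self):
        counts = pd.DataFrame({"TZ": [7], "TZS": [0], "TS": [0]}, index=["neuron"])
        props = endpoint_proportions(counts)
        assert props.loc["neuron", "TZ"] == 1.0

    def test_zero_denominator_is_nan_not_zero(self):
        counts = pd.DataFrame({"TZ": [0], "TZS": [0], "TS": [0]}, index=["glia"])
        props = endpoint_proportions(counts)
        assert props.isna().all().all()

    def test_glia_yield_fractions(self):
        p_touch, x, n = class_proportion(COHORT_COUNTS, "glia")
        assert (x, n) == (46, 168)
        assert round_half_away(100 * p_touch) == 27
        p_ws, x, n = class_proportion(COHORT_COUNTS, "glia", endpoints=("WS",))
        assert (x, n) == (5, 33)
        assert round_half_away(100 * p_ws) == 15


class TestTwoProportionZ:
    def test_symmetry_gives_zero(self):
        z, p = two_proportion_z(5, 10, 5, 10)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_pooled_formula_textbook_oracle(self):
        x1, n1, x2, n2 = 46, 168, 5, 33
        z, p = two_proportion_z(x1, n1, x2, n2)
        pool = (x1 + x2) / (n1 + n2)
        z_hand = (x1 / n1 - x2 / n2) / math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert z == pytest.approx(z_hand, abs=1e-12)
        from statsmodels.stats.proportion import proportions_ztest
        z_sm, p_sm = proportions_ztest([x1, x2], [n1, n2])
        assert z == pytest.approx(z_sm, abs=1e-10)
        assert p == pytest.approx(p_sm, abs=1e-10)

    def test_extreme_counts_still_finite(self):
        z, p = two_proportion_z(10, 10, 0, 10)
        # pooled p = 0.5 -> z = 1 / sqrt(0.25 * 0.2)
        assert z == pytest.approx(1.0 / math.sqrt(0.05), abs=1e-12)

    def test_degenerate_pool_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_proportion_z(0, 10, 0, 10)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_calculation(self):
        t, df, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4

    @pytest.mark.parametrize("mode,equal_var", [("student", True), ("welch", False)])
    def test_matches_scipy_oracle_to_1e10(self, mode, equal_var):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1.6, 17)
        t, df, p = two_sample_t(a, b, mode=mode)
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        assert t == pytest.approx(res.statistic, abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-10)
        assert df == pytest.approx(res.df, abs=1e-10)

    def test_zero_variance_unequal_means_is_infinite(self):
        t, df, p = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert math.isinf(t) and t < 0 and p == 0.0

    def test_power_for_published_v_rest_difference(self):
        # V_rest -69 +/- 9.5 (n=28) vs -76 +/- 7.5 (n=105): a difference this
        # size should be significant in nearly every resample
        rng = np.random.default_rng(0)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(-69, 9.5, 28)
            b = rng.normal(-76, 7.5, 105)
            _, _, p = two_sample_t(a, b)
            hits += p < 0.05
        assert hits >= 0.95 * reps


class TestCorrelations:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = correlations(x, 2 * x)
        assert res.pearson_r2 == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_antimonotone_nonlinear(self):
        x = np.linspace(-2, 2, 15)
        res = correlations(x, -x**3)
        assert res.spearman_rho == pytest.approx(-1.0)
        assert res.pearson_r2 < 1.0

    def test_matches_scipy_oracles_to_1e10(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = -0.5 * x + rng.normal(size=40)
        res = correlations(x, y)
        assert res.pearson_r2 == pytest.approx(sps.pearsonr(x, y).statistic**2, abs=1e-10)
        assert res.spearman_rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-10)

    def test_estimator_covers_true_rho(self):
        # bivariate normal with rho = -0.45 at n = 28: the Fisher-z 95% CI
        # must cover the truth in >= 90% of replicates
        rng = np.random.default_rng(1)
        cover = 0
        reps = 500
        for _ in range(reps):
            z = rng.multivariate_normal([0, 0], [[1, -0.45], [-0.45, 1]], size=28)
            rho = correlations(z[:, 0], z[:, 1]).spearman_rho
            lo = math.tanh(math.atanh(rho) - 1.96 / math.sqrt(25))
            hi = math.tanh(math.atanh(rho) + 1.96 / math.sqrt(25))
            cover += lo <= -0.45 <= hi
        assert cover >= 0.90 * reps

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlations([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])


class TestHelpers:
    def test_relative_access_resistance_examples(self):
        assert relative_access_resistance(21, 102) == pytest.approx(0.206, abs=1e-3)
        assert relative_access_resistance(37, 26) == pytest.approx(1.423, abs=1e-3)

    def test_summarize_uses_sample_sd_and_counts(self):
        df = pd.DataFrame({
            "cell_class": ["neuron"] * 3 + ["glia"] * 2,
            "R_in": [90.0, 100.0, 110.0, 40.0, 60.0],
        })
        out = summarize(df, ["R_in"], by=("cell_class",)).set_index("cell_class")
        assert out.loc["neuron", "R_in_mean"] == pytest.approx(100.0)
        assert out.loc["neuron", "R_in_sd"] == pytest.approx(10.0)
        assert out.loc["neuron", "R_in_n"] == 3
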