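import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cvdprs.evaluation_stats import (
    PreventionInputs,
    ReclassTable,
    baseline_table,
    case_nri,
    chi2_test,
    expected_random_upclassification,
    paired_sensitivity_diff,
    percentile_enrichment,
    preventable_events,
    relative_increase,
    sensitivity_ci,
    upclass_odds_ratio,
)


class TestSensitivityCI:
    def test_clinical_sensitivity_of_the_main_comparison(self):
        pt, lo, hi = sensitivity_ci(120, 195)
        assert round(pt, 1) == 61.5
        assert (round(lo, 1), round(hi, 1)) == (54.3, 68.4)

    def test_zero_successes(self):
        pt, lo, hi = sensitivity_ci(0, 10)
        assert pt == 0.0 and lo == 0.0

    def test_clopper_pearson_equals_beta_quantile_inversion(self):
        k, n = 7, 25
        _, lo, hi = sensitivity_ci(k, n)
        # direct inversion of the binomial tails via beta quantiles
        lo_oracle = stats.beta.ppf(0.025, k, n - k + 1)
        hi_oracle = stats.beta.ppf(0.975, k + 1, n - k)
        assert lo == pytest.approx(100 * lo_oracle, rel=1e-10)
        assert hi == pytest.approx(100 * hi_oracle, rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_ci(5, 0)
        with pytest.raises(ValueError):
            sensitivity_ci(11, 10)


class TestPairedSensitivityDiff:
    @pytest.mark.parametrize(
        "b,c,n,diff,lo,hi",
        [
            (14, 0, 195, 7.2, 3.6, 10.8),  # all cases
            (14, 0, 173, 8.1, 4.0, 12.2),  # statin-free subset
        ],
    )
    def test_wald_interval_from_discordant_counts(self, b, c, n, diff, lo, hi):
        res = paired_sensitivity_diff(b, c, n)
        assert round(res.diff_pct, 1) == diff
        assert (round(res.ci_low_pct, 1), round(res.ci_high_pct, 1)) == (lo, hi)
        assert res.p < 0.001

    def test_symmetric_discordance_is_zero(self):
        res = paired_sensitivity_diff(5, 5, 100)
        assert res.diff_pct == 0.0 and res.p == pytest.approx(1.0)

    def test_degenerate_no_discordance(self):
        res = paired_sensitivity_diff(0, 0, 50)
        assert res.degenerate and res.p == 1.0

    def test_ci_contains_point_and_shrinks_with_n(self):
        widths = []
        for n in (100, 1000, 10000):
            b, c = int(0.10 * n), int(0.02 * n)
            res = paired_sensitivity_diff(b, c, n)
            assert res.ci_low_pct <= res.diff_pct <= res.ci_high_pct
            widths.append(res.ci_high_pct - res.ci_low_pct)
        assert widths == sorted(widths, reverse=True)

    def test_agrees_with_paired_bootstrap(self):
        # nonparametric bootstrap of the paired indicators for (b=14, c=0,
        # n=195): CI width within 10% of the Wald width
        b, c, n = 14, 0, 195
        res = paired_sensitivity_diff(b, c, n)
        rng = np.random.default_rng(71)
        x = np.zeros(n)
        x[:b] = 1.0  # per-case contribution to the sensitivity difference
        idx = rng.integers(0, n, size=(10000, n))
        boot = x[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        wald_width = res.ci_high_pct - res.ci_low_pct
        assert 100 * (hi - lo) == pytest.approx(wald_width, rel=0.10)


class TestRatiosAndNRI:
    def test_relative_increase_headline(self):
        assert round(relative_increase(14, 120), 1) == 11.7

    def test_relative_increase_young_subgroup_from_counts(self):
        # raw counts give 47.4%; rounded-percentage arithmetic prints 47.7%
        assert round(relative_increase(9, 19), 1) == 47.4

    def test_case_nri_from_counts(self):
        assert round(case_nri(14, 12, 195), 1) == 1.0
        assert case_nri(5, 5, 50) == 0.0

    def test_case_nri_equals_diff_when_no_downclassification(self):
        assert case_nri(14, 0, 195) == pytest.approx(paired_sensitivity_diff(14, 0, 195).diff_pct)


def _or_enumeration_oracle(a, b, c, d):
    """Exact conditional CI by direct tail enumeration over the 2x2 support."""
    M, nrow, ncol = a + b + c + d, a + b, a + c
    lo_s, hi_s = max(0, nrow + ncol - M), min(nrow, ncol)
    support = np.arange(lo_s, hi_s + 1)
    logw = np.array(
        [
            math.lgamma(nrow + 1) - math.lgamma(x + 1) - math.lgamma(nrow - x + 1)
            + math.lgamma(M - nrow + 1) - math.lgamma(ncol - x + 1) - math.lgamma(M - nrow - ncol + x + 1)
            for x in support
        ]
    )

    def tail(psi, upper):
        ex = logw + support * math.log(psi)
        w = np.exp(ex - ex.max())
        w /= w.sum()
        return w[support >= a].sum() if upper else w[support <= a].sum()

    from scipy.optimize import brentq

    lo = 0.0 if a == lo_s else math.exp(brentq(lambda g: tail(math.exp(g), True) - 0.025, -40, 40))
    hi = math.inf if a == hi_s else math.exp(brentq(lambda g: tail(math.exp(g), False) - 0.025, -40, 40))
    return lo, hi


class TestUpclassOddsRatio:
    def test_equal_proportions_give_unity(self):
        res = upclass_odds_ratio(3, 30, 3, 30)
        assert res.oddsratio == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        a = upclass_odds_ratio(2, 12, 2, 12)
        assert a.oddsratio == pytest.approx(1.0)
        assert a.ci_low == pytest.approx(1 / a.ci_high, rel=1e-6)

    def test_cross_product_and_enumeration_ci(self):
        res = upclass_odds_ratio(14, 75, 16, 187)
        assert res.oddsratio == pytest.approx((14 / 61) / (16 / 171), rel=1e-12)
        lo, hi = _or_enumeration_oracle(14, 61, 16, 171)
        assert res.ci_low == pytest.approx(lo, rel=1e-4)
        assert res.ci_high == pytest.approx(hi, rel=1e-4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            upclass_odds_ratio(0, 0, 1, 10)


class TestEnrichment:
    def test_null_folds_near_one(self):
        rng = np.random.default_rng(72)
        ref = rng.standard_normal(200_000)
        cases = rng.standard_normal(100_000)
        enr = percentile_enrichment(cases, ref)
        assert np.allclose(enr["fold"], 1.0, atol=0.1)

    def test_all_cases_above_cut_saturate_fold(self):
        ref = np.linspace(-3, 3, 10001)
        thr = np.quantile(ref, 0.8)
        cases = np.full(100, thr + 1.0)
        enr = percentile_enrichment(cases, ref, cuts=(0.20,))
        assert enr["fold"].iloc[0] == pytest.approx(5.0, rel=1e-6)

    def test_shifted_normal_matches_closed_form(self):
        rng = np.random.default_rng(73)
        ref = rng.standard_normal(400_000)
        cases = rng.standard_normal(150_000) + 0.5
        enr = percentile_enrichment(cases, ref)
        for _, row in enr.iterrows():
            expected = stats.norm.sf(stats.norm.isf(row["cut"]) - 0.5) / row["cut"]
            assert row["fold"] == pytest.approx(expected, rel=0.08)

    def test_observed_fraction_non_increasing_in_cut(self):
        rng = np.random.default_rng(74)
        enr = percentile_enrichment(rng.standard_normal(5000), rng.standard_normal(5000))
        fracs = enr.sort_values("cut", ascending=False)["case_fraction"].to_numpy()
        assert (np.diff(fracs) <= 0).all()

    def test_invalid_cut_rejected(self):
        with pytest.raises(ValueError):
            percentile_enrichment(np.zeros(5), np.zeros(5), cuts=(1.5,))


class TestBaselineTable:
    def test_df2_chisquare_reproduces_printed_pvalues(self):
        # three-level tables use plain Pearson chi-square (no correction)
        q = [[120, 209], [42, 102], [33, 85]]
        s = [[67, 116], [39, 74], [89, 206]]
        assert round(chi2_test(q), 3) == 0.128
        assert round(chi2_test(s), 3) == 0.322

    def test_identical_groups_p_one(self):
        g = pd.DataFrame({"x": [1.0, 2.0, 3.0] * 10, "cat": ["a", "b"] * 15})
        out = baseline_table(g, g.copy(), continuous=("x",), categorical=("cat",))
        crow = out[out.variable == "cat"].iloc[0]
        assert crow["p"] == pytest.approx(1.0)

    def test_reclass_table_from_flags_and_invariants(self):
        df = pd.DataFrame(
            {
                "clinical_high": [True, True, False, False, True],
                "irt_high": [True, False, True, False, True],
            }
        )
        rt = ReclassTable.from_assessment(df)
        assert (rt.a, rt.b, rt.c, rt.d, rt.n) == (2, 1, 1, 1, 5)
        with pytest.raises(ValueError):
            ReclassTable(n=5, a=1, b=1, c=1, d=1)

    def test_constant_column_skipped_with_note(self):
        a = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        b = pd.DataFrame({"x": [1.0, 1.0]})
        out = baseline_table(a, b, continuous=("x",))
        assert math.isnan(out["p"].iloc[0]) and "skipped" in out["note"].iloc[0]


class TestPrevention:
    def test_hand_product(self):
        inp = PreventionInputs(0.05, 1.0, 0.25, 0.005)
        assert preventable_events(inp) == pytest.approx(6.25)

    def test_zero_uplift_zero_events(self):
        assert preventable_events(PreventionInputs(0.0, 0.5, 0.25, 0.01)) == 0.0

    def test_linear_in_uptake(self):
        full = preventable_events(PreventionInputs(0.05, 1.0, 0.25, 0.005))
        quarter = preventable_events(PreventionInputs(0.05, 0.25, 0.25, 0.005))
        assert full == pytest.approx(4 * quarter)

    def test_random_upclassification_expectation(self):
        assert round(expected_random_upclassification(0.385, 0.064), 1) == 2.5
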