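import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from votkit.group_stats import (
    FAMILIES,
    StatsError,
    bonferroni_adjust,
    cohens_d,
    cohens_d_from_summary,
    hotelling_t2,
    normality_check,
    pairwise_compare,
    run_family_analysis,
)
from votkit.vot_features import FEATURE_NAMES


class TestHotelling:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 3))
        res = hotelling_t2(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)
        assert res.effect == pytest.approx(0.0, abs=1e-12)

    def test_univariate_equals_squared_pooled_t(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.standard_normal((9, 1)) + 0.4
            b = rng.standard_normal((12, 1))
            res = hotelling_t2(a, b)
            t, p = stats.ttest_ind(a[:, 0], b[:, 0], equal_var=True)
            assert res.statistic == pytest.approx(t**2, rel=1e-10)
            assert res.p_raw == pytest.approx(p, rel=1e-10)

    def test_agrees_with_independent_multivariate_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        a = rng.standard_normal((14, 4)) + [0.5, 0, -0.3, 0]
        b = rng.standard_normal((11, 4))
        res = hotelling_t2(a, b)
        ref = pingouin.multivariate_ttest(a, b)
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.p_raw == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-8)
        assert res.df == (float(ref["df1"].iloc[0]), float(ref["df2"].iloc[0]))

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((16, 4)) + 0.3
        b = rng.standard_normal((13, 4))
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        shift = rng.standard_normal(4)
        base = hotelling_t2(a, b)
        trans = hotelling_t2(a @ A + shift, b @ A + shift)
        assert trans.statistic == pytest.approx(base.statistic, rel=1e-8)

    def test_collinear_variables_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((8, 1))
        a = np.hstack([x, 2 * x])
        b = np.hstack([x + 1, 2 * x + 2])
        with pytest.raises(StatsError, match="collinear"):
            hotelling_t2(a, b)

    def test_too_many_variables_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(StatsError, match="too few subjects"):
            hotelling_t2(rng.standard_normal((4, 8)), rng.standard_normal((4, 8)))


class TestEffectSizes:
    def test_equal_means_give_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [2.0, 1.0, 3.0]) == pytest.approx(0.0)

    def test_pooled_formula_from_summaries(self):
        # closed-form recomputation of the pooled-SD definition
        m1, s1, n1, m2, s2, n2 = 16.6, 3.9, 17, 11.3, 4.4, 15
        sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        assert cohens_d_from_summary(m1, s1, n1, m2, s2, n2) == pytest.approx(
            (m1 - m2) / sp, rel=1e-12
        )

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 2.0, 8)
        b = rng.normal(0.0, 1.5, 6)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), rel=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(StatsError, match="pooled"):
            cohens_d([2.0, 2.0, 2.0], [2.0, 2.0])


def exact_mw_p(a, b):
    """Enumeration oracle: two-sided p of the Mann-Whitney U statistic."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mean_u = n1 * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestPairwise:
    def test_identical_samples_p_one(self):
        res = pairwise_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_raw == pytest.approx(1.0)

    def test_mann_whitney_extreme_separation(self):
        res = pairwise_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], "mann_whitney")
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.1)
        assert math.isnan(res.effect)

    def test_mann_whitney_matches_enumeration(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0.4, 1, 5), rng.normal(0, 1, 4)
        res = pairwise_compare(a, b, "mann_whitney")
        assert res.p_raw == pytest.approx(exact_mw_p(a, b), abs=1e-10)

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0.5, 1, 8), rng.normal(0, 1, 8)
        exact = stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
        approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(exact - approx) <= 0.02

    def test_log_policy_on_nonpositive_values_rejected(self):
        with pytest.raises(StatsError, match="log transform undefined"):
            pairwise_compare([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], "log")

    def test_log_policy_tested_on_log_scale(self):
        rng = np.random.default_rng(9)
        a = np.exp(rng.normal(1.0, 0.3, 10))
        b = np.exp(rng.normal(0.5, 0.3, 10))
        res = pairwise_compare(a, b, "log")
        t, p = stats.ttest_ind(np.log(a), np.log(b), equal_var=True)
        assert res.p_raw == pytest.approx(p, rel=1e-12)
        assert res.effect == pytest.approx(cohens_d(np.log(a), np.log(b)))


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01], 5) == [pytest.approx(0.05)]
        assert bonferroni_adjust([0.3], 5) == [1.0]
        assert bonferroni_adjust([], 0) == []

    @settings(derandomize=True, max_examples=30)
    @given(ps=st.lists(st.floats(0, 1), max_size=10), extra=st.integers(0, 5))
    def test_monotone_and_order_preserving(self, ps, extra):
        m = len(ps) + extra
        adj = bonferroni_adjust(ps, m)
        assert all(a >= p for a, p in zip(adj, ps))
        for i in range(len(ps)):
            for j in range(len(ps)):
                if ps[i] <= ps[j]:
                    assert adj[i] <= adj[j] + 1e-15

    def test_family_smaller_than_pvalues_rejected(self):
        with pytest.raises(StatsError):
            bonferroni_adjust([0.1, 0.2], 1)


class TestNormalityCheck:
    def test_normal_sample_accepted_at_nominal_rate(self):
        rng = np.random.default_rng(10)
        decisions = [
            normality_check(rng.standard_normal(100))[2] for _ in range(1000)
        ]
        rate = decisions.count("normal") / 1000
        assert 0.92 <= rate <= 0.98  # ~0.95 by construction

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(11)
        decisions = [
            normality_check(rng.exponential(size=50))[2] for _ in range(500)
        ]
        assert decisions.count("non-normal") / 500 > 0.9

    def test_constant_sample_fails(self):
        with pytest.raises(StatsError, match="constant"):
            normality_check(np.full(10, 3.0))


class TestFamilyAnalysis:
    def test_families_partition_the_feature_set(self):
        all_vars = [v for fam in FAMILIES.values() for v in fam]
        assert sorted(all_vars) == sorted(FEATURE_NAMES)
        assert len(FAMILIES["oc_nirs"]) == 9
        assert len(FAMILIES["hy_nirs"]) == 12
        assert len(FAMILIES["hy_dcs"]) == 4

    def test_report_shape_and_adjustment(self, noisy_cohort):
        _, _, features = noisy_cohort
        report = run_family_analysis(features)
        assert len(report.table) == len(FEATURE_NAMES)
        assert set(report.family_tests) == {"oc_nirs", "hy_nirs", "hy_dcs",
                                            "oc_dcs"}
        tab = report.table.set_index("variable")
        ok = tab["p_adj"].notna()
        assert (tab.loc[ok, "p_adj"] >= tab.loc[ok, "p_raw"] - 1e-12).all()
        # adjustment uses the family size
        row = tab.loc["hy_d_o2hb_max"]
        assert row["p_adj"] == pytest.approx(
            min(1.0, 12 * row["p_raw"]), rel=1e-9
        )
        assert tab.loc["hy_rbf_htr", "test"] == "mann_whitney"
        assert tab.loc["oc_rbf_min", "transform"] == "log"

    def test_null_cohorts_rarely_reject(self):
        # both groups drawn from the same distribution -> family tests at
        # their nominal level; with 10 seeds expect mostly non-significant
        import dataclasses

        from votkit.pipeline import extract_cohort
        from votkit.synthetic_vot import CLIMBER_PARAMS, simulate_cohort

        equal = dataclasses.replace(CLIMBER_PARAMS, group="nonclimber", n=15)
        rejections = 0
        total = 0
        for seed in range(10):
            recs, _ = simulate_cohort(CLIMBER_PARAMS, equal, seed=100 + seed)
            rep = run_family_analysis(extract_cohort(recs))
            for fam in ("oc_nirs", "hy_nirs", "hy_dcs"):
                total += 1
                rejections += rep.family_tests[fam].p_raw < 0.05
        assert rejections / total <= 0.10

    def test_observed_group_parameters_power_the_o2hb_peak(self):
        # two groups at their observed parameters: the hyperemic O2Hb peak
        # difference (d ~ 1.3) should be detected in most draws
        from votkit.pipeline import extract_cohort
        from votkit.synthetic_vot import simulate_cohort

        wins = 0
        for seed in range(10):
            recs, _ = simulate_cohort(seed=200 + seed)
            rep = run_family_analysis(extract_cohort(recs))
            tab = rep.table.set_index("variable")
            wins += tab.loc["hy_d_o2hb_max", "p_raw"] < 0.05
        assert wins > 5

    def test_single_variable_family_matches_pairwise(self, noisy_cohort):
        _, _, features = noisy_cohort
        report = run_family_analysis(features)
        g1 = features[features["group"] == "climber"]["oc_rbf_min"]
        g2 = features[features["group"] == "nonclimber"]["oc_rbf_min"]
        lone = pairwise_compare(g1.to_numpy(), g2.to_numpy(), "log")
        assert report.family_tests["oc_dcs"].p_raw == pytest.approx(lone.p_raw)
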