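"""Normality gate, test selection, effect sizes, clinical summary."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maddwi.group_stats import (
    ClinicalSummary,
    clinical_summary,
    cohens_d,
    compare_groups,
    comparisons_to_dataframe,
    ks_normality,
    summarize_comparisons,
    variance_equality,
)
from maddwi.model import DegenerateInputError, ValidationError
from maddwi.synthetic import make_cohort

# pooled-SD Cohen's d for the published hindered-diffusivity moments,
# evaluated by hand: |1.360-1.254| / sqrt((29*0.112^2 + 23*0.134^2)/52)
POOLED_D_DH = 0.8672873108342287


def _ks_stat_brute(x):
    """Max |ECDF - CDF| against N(mean, sd) by exhaustive enumeration."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    cdf = stats.norm.cdf(x, loc=x.mean(), scale=x.std(ddof=1))
    return max(
        max(abs((i + 1) / n - c), abs(i / n - c)) for i, c in enumerate(cdf)
    )


def _mannwhitney_exact_p(low, high):
    """Two-sided p by exhaustive permutation over all group assignments."""
    pooled = np.concatenate([low, high])
    n_low = len(low)
    u_obs = stats.mannwhitneyu(low, high, alternative="two-sided").statistic
    m = len(pooled)

    def u_stat(idx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        ranks = stats.rankdata(pooled)
        ra = ranks[list(idx)].sum()
        return ra - n_low * (n_low + 1) / 2

    n_pos = len(high)
    mu = n_low * n_pos / 2
    d_obs = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(m), n_low):
        u = u_stat(idx)
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            count += 1
    return count / total


class TestKSNormality:
    def test_normal_sample_flagged_normal(self):
        x = np.random.default_rng(1).normal(size=200)
        assert ks_normality(x).normal

    def test_scaled_uniform_flagged_non_normal(self):
        # parameter estimation makes the KS check conservative, so a clearly
        # non-normal shape needs a decent n before the flag flips
        x = 100.0 * np.random.default_rng(2).uniform(size=2000)
        res = ks_normality(x)
        assert not res.normal
        assert res.statistic == pytest.approx(_ks_stat_brute(x), abs=1e-10)

    def test_statistic_matches_brute_force_ecdf_at_n10(self):
        x = np.random.default_rng(3).normal(2.0, 1.5, size=10)
        assert ks_normality(x).statistic == pytest.approx(_ks_stat_brute(x), abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            ks_normality([2.0] * 10)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        x = np.random.default_rng(5).normal(size=30)
        res = compare_groups(x, x.copy(), "D_h")
        assert not res.significant
        assert res.p_value > 0.9
        assert res.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_match_exact_permutation(self):
        low = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        high = np.array([6.0, 7.0, 8.0, 9.0, 10.0])
        p_scipy = stats.mannwhitneyu(low, high, alternative="two-sided",
                                     method="exact").pvalue
        assert p_scipy == pytest.approx(_mannwhitney_exact_p(low, high), abs=1e-12)
        # U = 0: most extreme assignment, both tails => 2 / C(10,5)
        assert p_scipy == pytest.approx(2.0 / 252.0, rel=1e-9)

    def test_mannwhitney_matches_permutation_for_small_groups(self):
        rng = np.random.default_rng(17)
        for n1, n2 in [(4, 4), (5, 6), (8, 7)]:
            low = rng.normal(size=n1)
            high = rng.normal(0.8, 1.0, size=n2)
            p_scipy = stats.mannwhitneyu(low, high, alternative="two-sided",
                                         method="exact").pvalue
            assert p_scipy == pytest.approx(_mannwhitney_exact_p(low, high), abs=1e-10)

    def test_gate_routes_uneven_variances_to_mannwhitney(self):
        rng = np.random.default_rng(6)
        low = rng.normal(0.0, 1.0, size=40)
        high = rng.normal(0.2, 6.0, size=40)
        res = compare_groups(low, high, "x")
        assert res.variance_p < 0.05
        assert res.test_used == "mann-whitney"
        assert res.low.style == "median_iqr"

    def test_gate_routes_normal_even_to_t(self):
        rng = np.random.default_rng(7)
        low = rng.normal(0.0, 1.0, size=40)
        high = rng.normal(0.5, 1.0, size=40)
        res = compare_groups(low, high, "x")
        assert res.test_used == "t"
        assert res.low.style == "mean_sd"


class TestCohensD:
    def test_reproduces_published_restricted_fraction_effect(self):
        assert cohens_d(0.060, 0.005, 30, 0.080, 0.009, 24) == pytest.approx(
            2.835, abs=5e-4
        )

    def test_pooled_formula_hand_evaluation(self):
        assert cohens_d(1.360, 0.112, 30, 1.254, 0.134, 24) == pytest.approx(
            POOLED_D_DH, rel=1e-12
        )

    def test_equal_means_give_zero(self):
        assert cohens_d(1.0, 0.5, 10, 1.0, 0.7, 12) == 0.0

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            m1, m2 = rng.uniform(0, 5, 2)
            s1, s2 = rng.uniform(0.1, 2, 2)
            d = cohens_d(m1, s1, 12, m2, s2, 9)
            assert d == pytest.approx(cohens_d(m2, s2, 9, m1, s1, 12), rel=1e-12)
            c = 7.3
            assert d == pytest.approx(
                cohens_d(c * m1, c * s1, 12, c * m2, c * s2, 9), rel=1e-12
            )

    def test_degenerate_sds_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohens_d(1.0, 0.0, 10, 2.0, 0.0, 10)


class TestSummarizeComparisons:
    def test_nine_rows_on_synthetic_cohort(self):
        cohort = make_cohort(12, 12, seed=2)
        results = summarize_comparisons(cohort)
        assert len(results) == 9
        assert {r.parameter for r in results} == {
            "D_r", "D_h", "D_f", "f_r", "f_h", "f_ui", "f_f", "alpha_h", "ADC"
        }

    def test_reproducible_bit_exact(self):
        a = comparisons_to_dataframe(summarize_comparisons(make_cohort(15, 12, seed=4)))
        b = comparisons_to_dataframe(summarize_comparisons(make_cohort(15, 12, seed=4)))
        assert a.equals(b)

    def test_bonferroni_only_tightens(self):
        cohort = make_cohort(20, 16, seed=6)
        raw = summarize_comparisons(cohort)
        adj = summarize_comparisons(cohort, correction="bonferroni")
        for r, a in zip(raw, adj):
            assert (not a.significant) or r.significant


def _study_metadata() -> pd.DataFrame:
    """Reconstruct the per-subject clinical table from its published counts."""
    low = pd.DataFrame({
        "grade": ["low"] * 30,
        "sex": ["male"] * 18 + ["female"] * 12,
        "who_grade": ["1"] * 1 + ["2"] * 29,
        "t_stage": ["T1"] * 26 + ["T3"] * 3 + ["T4"] * 1,
        "age": np.linspace(38, 76, 30),
    })
    high = pd.DataFrame({
        "grade": ["high"] * 24,
        "sex": ["male"] * 20 + ["female"] * 4,
        "who_grade": ["3"] * 21 + ["4"] * 3,
        "t_stage": ["T1"] * 8 + ["T2"] * 3 + ["T3"] * 11 + ["T4"] * 2,
        "age": np.linspace(42, 74, 24),
    })
    return pd.concat([low, high], ignore_index=True)


class TestClinicalSummary:
    def test_published_percentages(self):
        summary = clinical_summary(_study_metadata())
        assert summary.group_totals == {"all": 54, "low": 30, "high": 24}
        assert summary.percentages["who_grade"]["2"]["all"] == 53.7
        assert summary.percentages["who_grade"]["2"]["high"] == 0.0
        assert summary.percentages["sex"]["male"]["all"] == 70.4
        assert summary.percentages["t_stage"]["T3"]["high"] == 45.8

    def test_percentages_sum_to_100_per_category(self):
        summary = clinical_summary(_study_metadata())
        for cat, levels in summary.percentages.items():
            for g in ("all", "low", "high"):
                total = sum(levels[lvl][g] for lvl in levels)
                assert total == pytest.approx(100.0, abs=0.2)

    def test_unknown_grade_label_rejected(self):
        df = _study_metadata()
        df.loc[0, "grade"] = "intermediate"
        with pytest.raises(ValidationError):
            clinical_summary(df)
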