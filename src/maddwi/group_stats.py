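"""Two-group comparison of ROI-mean diffusion parameters.

The comparison route mirrors common radiology practice: a Kolmogorov-
Smirnov normality check per group, an F-test for variance equality, then
either the pooled-variance independent-samples t-test (both groups normal,
variances even) or the two-sided Mann-Whitney U test. Cohen's d from the
pooled SD is always reported as the effect size, and summaries follow the
test route (mean +/- SD for t, median with quartiles for Mann-Whitney).

No multiple-comparison correction is applied by default — the parameter
screen is exploratory — but Bonferroni and Benjamini-Hochberg options are
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import DegenerateInputError, ValidationError
from .roi import STAT_PARAMS, CohortTable

__all__ = [
    "NormalityResult",
    "GroupSummary",
    "GroupComparisonResult",
    "ClinicalSummary",
    "ks_normality",
    "variance_equality",
    "cohens_d",
    "compare_groups",
    "summarize_comparisons",
    "clinical_summary",
]

ALPHA = 0.05


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float

    @property
    def normal(self) -> bool:
        return self.p_value >= ALPHA


@dataclass(frozen=True)
class GroupSummary:
    """Either mean +/- SD or median (Q1, Q3), depending on the test route."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    style: str  # "mean_sd" | "median_iqr"

    def __str__(self) -> str:
        if self.style == "mean_sd":
            return f"{self.mean:.3f} ± {self.sd:.3f}"
        return f"{self.median:.3f} ({self.q1:.3f}, {self.q3:.3f})"


@dataclass(frozen=True)
class GroupComparisonResult:
    parameter: str
    low: GroupSummary
    high: GroupSummary
    normality_p_low: float
    normality_p_high: float
    variance_p: float
    test_used: str  # "t" | "mann-whitney"
    p_value: float
    cohens_d: float
    significant: bool


def ks_normality(values) -> NormalityResult:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample SD).

    Estimating the reference parameters from the sample makes the test
    conservative (the classical Lilliefors caveat); this matches the common
    software default and is accepted as-is.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DegenerateInputError(f"need n >= 4 for normality testing, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant sample: normality undefined")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return NormalityResult(statistic=float(stat), p_value=float(p))


def variance_equality(a, b) -> float:
    """Two-sided F-test p-value for equality of variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateInputError("both groups constant: variance test undefined")
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p_upper = stats.f.sf(f, dfa, dfb)
    p = 2.0 * min(p_upper, 1.0 - p_upper)
    return float(min(p, 1.0))


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d with the pooled standard deviation.

    d = |mean1 - mean2| / sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2))
    """
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("need n >= 2 per group for Cohen's d")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("SDs must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both SDs zero: effect size undefined")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return float(abs(mean1 - mean2) / pooled)


def _summary(x: np.ndarray, style: str) -> GroupSummary:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupSummary(
        n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)),
        median=float(med), q1=float(q1), q3=float(q3), style=style,
    )


def compare_groups(low, high, parameter: str = "", alpha: float = ALPHA) -> GroupComparisonResult:
    """Gated two-group comparison of one parameter.

    Pooled t-test when both groups pass the KS normality check and the
    F-test finds even variances; two-sided Mann-Whitney U otherwise.
    """
    x = np.asarray(low, dtype=float)
    y = np.asarray(high, dtype=float)
    if x.size < 4 or y.size < 4:
        raise DegenerateInputError("need n >= 4 per group")
    norm_low = ks_normality(x)
    norm_high = ks_normality(y)
    var_p = variance_equality(x, y)
    parametric = norm_low.normal and norm_high.normal and var_p >= alpha
    if parametric:
        _, p = stats.ttest_ind(x, y, equal_var=True)
        test, style = "t", "mean_sd"
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        test, style = "mann-whitney", "median_iqr"
    d = cohens_d(x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size)
    return GroupComparisonResult(
        parameter=parameter,
        low=_summary(x, style),
        high=_summary(y, style),
        normality_p_low=norm_low.p_value,
        normality_p_high=norm_high.p_value,
        variance_p=var_p,
        test_used=test,
        p_value=float(p),
        cohens_d=d,
        significant=bool(p < alpha),
    )


def summarize_comparisons(
    cohort: CohortTable, correction: str | None = None, alpha: float = ALPHA
) -> list[GroupComparisonResult]:
    """One gated comparison per parameter (8 MAD quantities + ADC).

    ``correction``: None (default, exploratory screen), "bonferroni" or
    "fdr_bh"; when set, the significance flags are recomputed on adjusted
    p-values (reported p-values stay raw).
    """
    if cohort.grades_present() != {"low", "high"}:
        raise ValidationError("cohort must contain both grade groups")
    results = []
    for p in STAT_PARAMS:
        lo, hi = cohort.group_values(p)
        results.append(compare_groups(lo, hi, parameter=p, alpha=alpha))
    if correction is not None:
        reject, _, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method=correction
        )
        results = [
            GroupComparisonResult(**{**r.__dict__, "significant": bool(rej)})
            for r, rej in zip(results, reject)
        ]
    return results


def comparisons_to_dataframe(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low_summary": str(r.low),
                "high_summary": str(r.high),
                "test": r.test_used,
                "p_value": r.p_value,
                "cohens_d": r.cohens_d,
                "significant": r.significant,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class ClinicalSummary:
    """Counts and percentages per category, per group, plus age summaries."""

    counts: dict[str, dict[str, dict[str, int]]]       # category -> level -> group -> n
    percentages: dict[str, dict[str, dict[str, float]]]
    group_totals: dict[str, int]
    age: dict[str, dict[str, float]]                    # group -> {median, min, max}


def clinical_summary(
    metadata: pd.DataFrame,
    categories: tuple[str, ...] = ("sex", "who_grade", "t_stage"),
    group_col: str = "grade",
    age_col: str = "age",
) -> ClinicalSummary:
    """Cohort characteristics table: n (%) per category level, by grade group.

    Percentages are relative to the group total and rounded to 1 decimal.
    Groups: 'all' plus each level of ``group_col``.
    """
    if group_col not in metadata.columns:
        raise ValidationError(f"metadata lacks group column {group_col!r}")
    unknown = set(metadata[group_col].unique()) - {"low", "high"}
    if unknown:
        raise ValidationError(f"unknown grade labels: {sorted(unknown)}")
    groups = {"all": metadata, "low": metadata[metadata[group_col] == "low"],
              "high": metadata[metadata[group_col] == "high"]}
    totals = {g: int(len(df)) for g, df in groups.items()}
    counts: dict = {}
    percentages: dict = {}
    for cat in categories:
        if cat not in metadata.columns:
            raise ValidationError(f"metadata lacks category column {cat!r}")
        counts[cat] = {}
        percentages[cat] = {}
        for level in sorted(metadata[cat].astype(str).unique()):
            counts[cat][level] = {}
            percentages[cat][level] = {}
            for g, df in groups.items():
                n = int((df[cat].astype(str) == level).sum())
                counts[cat][level][g] = n
                pct = 0.0 if totals[g] == 0 else round(100.0 * n / totals[g], 1)
                percentages[cat][level][g] = pct
    age = {}
    if age_col in metadata.columns:
        for g, df in groups.items():
            if len(df):
                age[g] = {
                    "median": float(df[age_col].median()),
                    "min": float(df[age_col].min()),
                    "max": float(df[age_col].max()),
                }
    return ClinicalSummary(
        counts=counts, percentages=percentages, group_totals=totals, age=age
    )
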