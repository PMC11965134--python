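"""Diagnostic evaluation: per-parameter ROC analysis and the combined
logistic biomarker.

Each candidate marker is scored by its empirical ROC curve against the
grade label (high grade = positive class). Orientation is chosen
automatically so AUC >= 0.5 and recorded, since some markers fall with
grade (D_h, ADC) while others rise (f_r). The operating point maximizes
Youden's J = sensitivity + specificity - 1, the 95% AUC interval uses
DeLong's nonparametric variance estimator, and the combined marker is the
in-sample predicted probability of a multiple logistic regression on
D_h, f_r and alpha_h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

from .model import ValidationError
from .roi import CohortTable

__all__ = [
    "ROCResult",
    "LogisticModel",
    "roc_curve",
    "auc_ci",
    "youden_operating_point",
    "fit_logistic",
    "evaluate_combined",
    "evaluate_parameters",
    "COMBINED_FEATURES",
]

COMBINED_FEATURES: tuple[str, ...] = ("D_h", "f_r", "alpha_h")


@dataclass(frozen=True)
class ROCResult:
    name: str
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float
    higher_is_positive: bool
    ci_low: float | None = None
    ci_high: float | None = None
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None

    def with_fields(self, **changes) -> "ROCResult":
        d = dict(self.__dict__)
        d.update(changes)
        return ROCResult(**d)


@dataclass(frozen=True)
class LogisticModel:
    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    converged: bool
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.coefficients):
            raise ValidationError("feature and coefficient counts differ")


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    y = y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("labels must contain both classes (0 and 1)")
    return s, y


def roc_curve(scores, labels, name: str = "") -> ROCResult:
    """Empirical ROC over all distinct thresholds, AUC by the trapezoid rule.

    If the raw AUC is below 0.5, the score is negated (lower raw values
    indicate the positive class) and ``higher_is_positive=False`` recorded.
    """
    s, y = _check_binary(scores, labels)
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    higher = True
    if auc < 0.5:
        fpr, tpr, _ = _sk_roc_curve(y, -s, drop_intermediate=False)
        auc = float(np.trapezoid(tpr, fpr))
        higher = False
    return ROCResult(
        name=name, fpr=tuple(map(float, fpr)), tpr=tuple(map(float, tpr)),
        auc=auc, higher_is_positive=higher,
    )


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via placement values (midranks)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa, ties = 1/2
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong 95% confidence interval for the AUC, clipped to [0, 1].

    Computed on the oriented scores (AUC >= 0.5 side), matching the point
    estimate returned by :func:`roc_curve`.
    """
    s, y = _check_binary(scores, labels)
    if min(np.sum(y == 0), np.sum(y == 1)) < 5:
        raise ValidationError("need >= 5 subjects per class for a CI")
    auc, var = _delong_variance(s, y)
    if auc < 0.5:
        auc, var = _delong_variance(-s, y)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def youden_operating_point(scores, labels, roc: ROCResult | None = None):
    """Threshold maximizing Youden's J; ties resolved toward higher specificity.

    The decision rule is oriented-score >= threshold => positive (high
    grade). Returns an ROCResult carrying threshold, sensitivity,
    specificity and accuracy (plus the CI fields if present on ``roc``).
    """
    s, y = _check_binary(scores, labels)
    if roc is None:
        roc = roc_curve(s, y)
    oriented = s if roc.higher_is_positive else -s
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    # candidate thresholds: distinct scores plus one above the maximum
    cands = np.append(np.unique(oriented), np.max(oriented) + 1.0)
    best = None
    for t in cands:
        pred = oriented >= t
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        key = (j, spec)  # tie toward higher specificity
        if best is None or key > best[0]:
            best = (key, float(t), sens, spec, (tp + tn) / y.size)
    _, thr, sens, spec, acc = best
    return roc.with_fields(
        threshold=thr if roc.higher_is_positive else -thr,
        sensitivity=float(sens), specificity=float(spec), accuracy=float(acc),
    )


def fit_logistic(features: np.ndarray, labels, feature_names=None) -> LogisticModel:
    """Maximum-likelihood multiple logistic regression.

    Features are standardized internally for numerical stability;
    coefficients are mapped back to the original scale. On (quasi-)perfect
    separation the ML fit diverges, and a ridge-stabilized fit is returned
    with ``converged=False``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _, y = _check_binary(X[:, 0], labels)
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    feature_names = tuple(feature_names)
    if len(feature_names) != X.shape[1]:
        raise ValidationError("feature_names length != number of columns")
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [n for n, s in zip(feature_names, sds) if s == 0]
        raise ValidationError(f"constant feature(s): {bad}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValidationError("collinear feature matrix (rank-deficient)")
    mus = X.mean(axis=0)
    Z = (X - mus) / sds

    converged = True
    beta_z = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(Z)).fit(disp=0, maxiter=200)
            beta_z = np.asarray(fit.params)
            if not fit.mle_retvals.get("converged", False) or np.any(
                np.abs(beta_z) > 50
            ):
                converged = False
        except Exception:
            converged = False
    if not converged or beta_z is None:
        # weak L2 penalty keeps the separated fit finite
        lr = LogisticRegression(C=100.0, max_iter=2000)
        lr.fit(Z, y)
        beta_z = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        converged = False

    coef = beta_z[1:] / sds
    intercept = beta_z[0] - float(np.sum(beta_z[1:] * mus / sds))
    logits = intercept + X @ coef
    probs = 1.0 / (1.0 + np.exp(-logits))
    probs = np.clip(probs, 1e-12, 1 - 1e-12)
    return LogisticModel(
        feature_names=feature_names,
        coefficients=tuple(map(float, coef)),
        intercept=float(intercept),
        converged=converged,
        probabilities=tuple(map(float, probs)),
    )


def _cohort_matrix(cohort: CohortTable, names) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[r[n] for n in names] for r in cohort.records])
    y = np.array([1 if r.grade == "high" else 0 for r in cohort.records])
    return X, y


def evaluate_combined(
    cohort: CohortTable, feature_names=COMBINED_FEATURES
) -> ROCResult:
    """In-sample ROC of the multiple-logistic combination of MAD markers.

    Predicted probabilities from :func:`fit_logistic` are scored with the
    full ROC pipeline (AUC, DeLong CI, Youden operating point). In-sample
    evaluation mirrors the single-cohort study design; it is optimistic
    relative to cross-validation.
    """
    X, y = _cohort_matrix(cohort, feature_names)
    model = fit_logistic(X, y, feature_names)
    probs = np.asarray(model.probabilities)
    roc = roc_curve(probs, y, name="+".join(feature_names))
    roc = youden_operating_point(probs, y, roc)
    ci = auc_ci(probs, y)
    return roc.with_fields(ci_low=ci[0], ci_high=ci[1])


def evaluate_parameters(
    cohort: CohortTable,
    parameters=("ADC", "D_h", "f_r", "alpha_h"),
    include_combined: bool = True,
) -> list[ROCResult]:
    """Diagnostic-performance table: one full ROC row per marker + combined."""
    results = []
    for p in parameters:
        scores = np.array([r[p] for r in cohort.records])
        y = np.array([1 if r.grade == "high" else 0 for r in cohort.records])
        roc = roc_curve(scores, y, name=p)
        roc = youden_operating_point(scores, y, roc)
        ci = auc_ci(scores, y)
        results.append(roc.with_fields(ci_low=ci[0], ci_high=ci[1]))
    if include_combined:
        results.append(evaluate_combined(cohort))
    return results


def roc_table(results: list[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "accuracy": r.accuracy,
                "auc": r.auc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "higher_is_positive": r.higher_is_positive,
            }
            for r in results
        ]
    )
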