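"""ROC analysis, DeLong intervals, Youden operating points, logistic combination."""

import itertools

import numpy as np
import pytest
from scipy import stats

from maddwi.classification import (
    auc_ci,
    evaluate_combined,
    evaluate_parameters,
    fit_logistic,
    roc_curve,
    youden_operating_point,
)
from maddwi.model import ValidationError
from maddwi.synthetic import make_cohort


def _auc_concordance(scores, labels):
    """Pairwise concordance AUC (ties count 1/2), by exhaustive enumeration."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return conc / total


class TestROCCurve:
    def test_perfect_separation(self):
        res = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_interleaved_equals_concordance(self):
        res = roc_curve([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.75, abs=1e-12)
        assert res.auc == pytest.approx(
            _auc_concordance([1, 2, 3, 4], [0, 1, 0, 1]), abs=1e-12
        )

    def test_orientation_flag_flips_with_labels(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [0, 0, 0, 1, 1, 1]
        fwd = roc_curve(scores, labels)
        rev = roc_curve(scores, [1 - y for y in labels])
        assert fwd.auc == pytest.approx(rev.auc, abs=1e-12)
        assert fwd.higher_is_positive and not rev.higher_is_positive

    def test_trapezoid_equals_concordance_exhaustively(self):
        # oracle equivalence across random small instances including ties
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            scores = rng.integers(0, 5, size=n).astype(float)  # many ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            res = roc_curve(scores, labels)
            oracle = _auc_concordance(scores, labels)
            oracle = max(oracle, 1.0 - oracle)  # orientation handling
            assert res.auc == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=30)
        labels = (rng.uniform(size=30) < 0.4).astype(int)
        a = roc_curve(scores, labels)
        b = roc_curve(np.exp(3.0 * scores), labels)
        assert a.fpr == b.fpr and a.tpr == b.tpr and a.auc == pytest.approx(b.auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestAUCCI:
    def test_perfect_separation_clips_to_one(self):
        scores = list(range(10))
        labels = [0] * 5 + [1] * 5
        lo, hi = auc_ci(scores, labels)
        assert hi == 1.0

    def test_contains_point_auc(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            scores = rng.normal(size=40)
            labels = np.array([0] * 20 + [1] * 20)
            scores[labels == 1] += rng.uniform(0, 1.5)
            res = roc_curve(scores, labels)
            lo, hi = auc_ci(scores, labels)
            assert lo <= res.auc <= hi

    def test_coverage_of_binormal_truth(self):
        # theoretical binormal AUC = Phi(delta/sqrt(2)); DeLong 95% interval
        # should cover it in >= 93 of 100 seeded replicates at n=500/500
        delta = 0.5
        truth = stats.norm.cdf(delta / np.sqrt(2.0))
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            neg = rng.normal(0.0, 1.0, 500)
            pos = rng.normal(delta, 1.0, 500)
            scores = np.concatenate([neg, pos])
            labels = np.array([0] * 500 + [1] * 500)
            lo, hi = auc_ci(scores, labels)
            covered += int(lo <= truth <= hi)
        assert covered >= 93


class TestYoudenOperatingPoint:
    def test_perfect_separation(self):
        res = youden_operating_point([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.sensitivity == res.specificity == res.accuracy == 1.0

    def test_matches_exhaustive_threshold_scan(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        res = youden_operating_point(scores, labels)
        # brute force over all distinct thresholds (rule: score >= t)
        best = None
        for t in [1, 2, 3, 4, 5]:
            pred = scores >= t
            sens = np.sum(pred & (labels == 1)) / 2
            spec = np.sum(~pred & (labels == 0)) / 2
            key = (sens + spec - 1, spec)
            if best is None or key > best[0]:
                best = (key, sens, spec)
        assert res.sensitivity == best[1] and res.specificity == best[2]

    def test_self_consistent_confusion_matrix(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=40)
        labels = np.array([0] * 22 + [1] * 18)
        scores[labels == 1] += 1.0
        res = youden_operating_point(scores, labels)
        pred = scores >= res.threshold if res.higher_is_positive else scores <= res.threshold
        tp = np.sum(pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        assert res.sensitivity == pytest.approx(tp / 18)
        assert res.specificity == pytest.approx(tn / 22)
        assert res.accuracy == pytest.approx((tp + tn) / 40)


class TestFitLogistic:
    def test_single_feature_preserves_roc(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=60)
        y = (rng.uniform(size=60) < 1 / (1 + np.exp(-x))).astype(int)
        model = fit_logistic(x[:, None], y, ["x"])
        raw = roc_curve(x, y)
        prob = roc_curve(np.array(model.probabilities), y)
        assert prob.auc == pytest.approx(raw.auc, abs=1e-12)

    def test_null_labels_give_small_effects(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(200, 3))
        y = (rng.uniform(size=200) < 0.5).astype(int)
        model = fit_logistic(X, y)
        assert all(abs(c) < 0.5 for c in model.coefficients)
        assert roc_curve(np.array(model.probabilities), y).auc < 0.65

    def test_constant_feature_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        y = np.array([0, 1] * 10)
        with pytest.raises(ValidationError):
            fit_logistic(X, y)

    def test_duplicated_feature_rejected(self):
        x = np.arange(20.0)
        y = np.array([0, 1] * 10)
        with pytest.raises(ValidationError):
            fit_logistic(np.column_stack([x, x]), y)

    def test_perfect_separation_falls_back_flagged(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(int)
        model = fit_logistic(x[:, None], y)
        assert not model.converged
        assert np.all(np.isfinite(model.coefficients))
        assert roc_curve(np.array(model.probabilities), y).auc == 1.0


class TestEvaluateCombined:
    def test_perfect_single_feature_gives_auc_one(self):
        cohort = make_cohort(10, 10, seed=20)
        # overwrite f_r so it alone separates the grades
        for i, rec in enumerate(cohort.records):
            rec.values["f_r"] = 0.9 if rec.grade == "high" else 0.1
        res = evaluate_combined(cohort)
        assert res.auc == 1.0

    def test_combined_at_least_best_single(self):
        for seed in range(5):
            cohort = make_cohort(30, 24, seed=seed)
            combined = evaluate_combined(cohort)
            singles = evaluate_parameters(
                cohort, parameters=("D_h", "f_r", "alpha_h"), include_combined=False
            )
            assert combined.auc >= max(s.auc for s in singles) - 1e-9

    def test_deterministic(self):
        a = evaluate_combined(make_cohort(20, 20, seed=21))
        b = evaluate_combined(make_cohort(20, 20, seed=21))
        assert a == b
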