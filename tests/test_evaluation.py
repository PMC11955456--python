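"""ROC/AUC, DeLong inference, confusion metrics, calibration, DCA, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from habitatrx.evaluation import (
    calibration_curve,
    confusion_metrics,
    decision_curve,
    delong_test,
    evaluate_model,
    repeated_cv,
    repeated_cv_table,
    roc_auc,
)


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_four_case_hand_example(self):
        scores = np.array([0.8, 0.6, 0.7, 0.2])
        labels = np.array([1, 1, 0, 0])
        auc, ci = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)
        assert ci[0] <= auc <= ci[1]

    def test_all_tied_scores(self):
        auc, _ = roc_auc(np.full(10, 0.4), np.repeat([0, 1], 5))
        assert auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        auc, ci = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert auc == 1.0
        assert ci[1] <= 1.0

    def test_matches_brute_force_and_sklearn(self, rng):
        scores = rng.random(60)
        scores[rng.random(60) < 0.3] = 0.5  # inject ties
        labels = rng.integers(0, 2, 60)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_equals_normalised_mann_whitney(self, rng):
        scores = rng.normal(0, 1, 80)
        labels = rng.integers(0, 2, 80)
        auc, _ = roc_auc(scores, labels)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / ((labels == 1).sum() * (labels == 0).sum()))

    def test_ci_width_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 200, 800):
            labels = np.repeat([0, 1], n // 2)
            scores = rng.normal(labels * 0.8, 1.0)
            _, (lo, hi) = roc_auc(scores, labels)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        # roughly 1/sqrt(n): quadrupling n halves the width (loose factor)
        assert widths[0] / widths[2] > 2.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.2, 0.4]), np.array([1, 1]))


class TestDelong:
    def test_identical_scores(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_sign_symmetry(self, rng):
        a, b = rng.random(50), rng.random(50)
        y = rng.integers(0, 2, 50)
        z1, p1 = delong_test(a, b, y)
        z2, p2 = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test(np.ones(3), np.ones(4), np.array([0, 1, 0]))

    def test_agrees_with_paired_bootstrap(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.repeat([0, 1], n // 2)
        a = y + rng.normal(0, 1.0, n)
        b = y + rng.normal(0, 1.4, n)
        _, p = delong_test(a, b, y)
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            diffs.append(brute_force_auc(a[idx], y[idx])
                         - brute_force_auc(b[idx], y[idx]))
        diffs = np.asarray(diffs)
        # two-sided bootstrap p for the AUC difference
        frac = min((diffs <= 0).mean(), (diffs >= 0).mean())
        p_boot = min(1.0, 2 * frac)
        assert abs(p - p_boot) <= 0.05


class TestConfusion:
    def test_printed_two_by_two(self):
        # TP 30, FN 3, FP 2, TN 65
        labels = np.array([1] * 33 + [0] * 67)
        scores = np.array([1.0] * 30 + [0.0] * 3 + [1.0] * 2 + [0.0] * 65)
        m = confusion_metrics(scores, labels, threshold=0.5)
        assert m["sensitivity"] == pytest.approx(30 / 33)
        assert m["specificity"] == pytest.approx(65 / 67)
        assert m["accuracy"] == pytest.approx(95 / 100)

    def test_all_positive_predictor(self):
        labels = np.array([1] * 25 + [0] * 75)
        m = confusion_metrics(np.ones(100), labels, threshold=0.5)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == 0.25

    def test_perfect_classifier(self):
        labels = np.array([0, 0, 1, 1])
        m = confusion_metrics(np.array([0.1, 0.2, 0.9, 0.8]), labels, 0.5)
        assert m["sensitivity"] == m["specificity"] == m["f1"] == 1.0

    def test_single_class_flagged_nan(self):
        m = confusion_metrics(np.array([0.9, 0.1]), np.array([1, 1]), 0.5)
        assert np.isnan(m["specificity"])
        assert m["sensitivity"] == 0.5


class TestCalibration:
    def test_constant_scores_single_bin(self):
        scores = np.full(100, 0.5)
        labels = np.repeat([0, 1], 50)
        bins = calibration_curve(scores, labels)
        assert len(bins) == 1
        assert bins.loc[0, "mean_predicted"] == 0.5
        assert bins.loc[0, "observed_rate"] == 0.5
        assert bins["count"].sum() == 100

    def test_bernoulli_scores_lie_on_diagonal(self, rng):
        scores = rng.uniform(0.05, 0.95, 10_000)
        labels = (rng.random(10_000) < scores).astype(int)
        bins = calibration_curve(scores, labels)
        assert (bins["mean_predicted"].diff().dropna() > 0).all()
        assert (bins["observed_rate"] - bins["mean_predicted"]).abs().max() < 0.05

    def test_few_cases_reduces_bins(self):
        with pytest.warns(UserWarning):
            bins = calibration_curve(np.array([0.1, 0.9]), np.array([0, 1]))
        assert bins["count"].sum() == 2


class TestDecisionCurve:
    def test_hand_computed_net_benefit(self):
        # N=100, TP=30, FP=10 at t=0.2: NB = 0.3 - 0.1 * 0.25 = 0.275
        labels = np.array([1] * 40 + [0] * 60)
        scores = np.concatenate([
            np.full(30, 0.9), np.full(10, 0.05),  # positives
            np.full(10, 0.9), np.full(50, 0.05),  # negatives
        ])
        curve = decision_curve(scores, labels, thresholds=np.array([0.2]))
        assert curve.loc[0, "net_benefit"] == pytest.approx(0.275)
        assert curve.loc[0, "treat_none"] == 0.0

    def test_treat_all_limits(self, rng):
        labels = rng.integers(0, 2, 500)
        scores = rng.random(500)
        curve = decision_curve(scores, labels)
        prev = labels.mean()
        # treat-all tends to the prevalence as t -> 0
        assert curve.iloc[0]["treat_all"] == pytest.approx(
            prev - (1 - prev) * 0.01 / 0.99
        )
        # and crosses zero at t = prevalence
        signs = np.sign(curve["treat_all"].to_numpy())
        crossing = curve["threshold"].to_numpy()[np.argmax(signs < 0)]
        assert abs(crossing - prev) < 0.02

    def test_perfect_scores_net_benefit_is_prevalence(self):
        labels = np.array([1] * 30 + [0] * 70)
        scores = labels.astype(float)
        curve = decision_curve(scores, labels)
        assert np.allclose(curve["net_benefit"], 0.3)

    def test_threshold_one_excluded(self):
        with pytest.raises(ValueError):
            decision_curve(np.array([0.5]), np.array([1]),
                           thresholds=np.array([1.0]))


class TestRepeatedCv:
    def test_twenty_entries_and_determinism(self, rng):
        y = np.repeat([0, 1], 30)
        x = pd.DataFrame({"f": y + rng.normal(0, 1, 60),
                          "g": rng.normal(0, 1, 60)})

        aucs1 = repeated_cv_table(x, y, "logistic_regression",
                                  repeats=5, folds=4, seed=0)
        aucs2 = repeated_cv_table(x, y, "logistic_regression",
                                  repeats=5, folds=4, seed=0)
        assert len(aucs1) == 20
        assert np.array_equal(aucs1, aucs2)
        assert aucs1.mean() > 0.5

    def test_fold_pipeline_receives_disjoint_indices(self):
        y = np.repeat([0, 1], 20)
        seen = []

        def fold(tr, te, seed):
            seen.append((set(tr), set(te)))
            return np.random.default_rng(seed).random(len(te))

        repeated_cv(y, fold, repeats=1, folds=4, seed=0)
        for tr, te in seen:
            assert not tr & te
            assert len(tr | te) == len(y)


class TestEvaluateModel:
    def test_report_fields_consistent(self, rng):
        y = rng.integers(0, 2, 120)
        scores = np.clip(y * 0.5 + rng.normal(0.3, 0.2, 120), 0, 1)
        ev = evaluate_model(scores, y, threshold=0.5)
        assert ev.ci[0] <= ev.auc <= ev.ci[1]
        assert ev.calibration["count"].sum() == 120
        assert (ev.dca["treat_none"] == 0).all()
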