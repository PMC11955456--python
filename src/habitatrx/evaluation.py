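"""Model evaluation: ROC/AUC with DeLong inference, confusion metrics,
calibration curves, decision-curve analysis and repeated cross-validation.

AUC is the normalised Mann-Whitney statistic (ties count half); its
confidence interval and the paired model comparison use DeLong's
placement-value covariance estimator with a normal approximation.  Decision
curves report the net benefit NB(t) = TP/N - (FP/N) * t/(1-t) against the
treat-all and treat-none references.  Repeated cross-validation re-runs a
caller-supplied fold pipeline (so feature selection and habitat clustering
can be refitted inside each training fold, leakage-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong normal-approximation confidence interval.

    Ties between a positive and a negative score count 1/2.  The CI is
    truncated to [0, 1]; with a degenerate DeLong variance it collapses to
    the point estimate.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes are required to compute an AUC")
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if len(pos) > 1:
        var += np.var(v10, ddof=1) / len(pos)
    if len(neg) > 1:
        var += np.var(1.0 - v01, ddof=1) / len(neg)
    z = norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Two-sided DeLong comparison of two paired AUCs; returns (z, p).

    Identical score vectors give z = 0, p = 1; swapping A and B negates z.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(y)):
        raise ValueError("paired scores must share one case list")
    pos_mask, neg_mask = y == 1, y == 0
    if not pos_mask.any() or not neg_mask.any():
        raise ValueError("both classes are required")
    vas, vbs = [], []
    for s in (scores_a, scores_b):
        v10, v01 = _placements(s[pos_mask], s[neg_mask])
        vas.append(v10)
        vbs.append(1.0 - v01)
    auc_a, auc_b = vas[0].mean(), vas[1].mean()
    m, n = pos_mask.sum(), neg_mask.sum()
    s10 = np.cov(np.vstack([vas[0], vas[1]]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([vbs[0], vbs[1]]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    var_diff = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    diff = float(auc_a - auc_b)
    if var_diff <= 1e-16:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (np.sign(diff) * np.inf, 0.0)
    z = diff / np.sqrt(var_diff)
    return float(z), float(2.0 * norm.sf(abs(z)))


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 at ``score >= threshold``.

    With a single-class input the undefined rate is returned as NaN (the
    caller sees which via the NaN itself; accuracy is still defined).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and prec + sens > 0 else np.nan)
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


def calibration_curve(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-frequency calibration bins: mean predicted vs observed rate."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < n_bins:
        import warnings

        warnings.warn(f"only {n} cases; reducing calibration bins to {n}")
        n_bins = max(1, n)
    order = np.argsort(scores, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        if len(chunk) == 0:
            continue
        rows.append({
            "mean_predicted": float(scores[chunk].mean()),
            "observed_rate": float(y[chunk].mean()),
            "count": int(len(chunk)),
        })
    out = pd.DataFrame(rows)
    # merge identical-score bins so edges stay monotone
    merged = []
    for mp, g in out.groupby("mean_predicted", sort=True):
        merged.append({
            "mean_predicted": float(mp),
            "observed_rate": float(np.average(g["observed_rate"], weights=g["count"])),
            "count": int(g["count"].sum()),
        })
    return pd.DataFrame(merged)


def decision_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none references.

    NB(t) = TP/N - (FP/N) * t/(1-t) with "treat" meaning score >= t;
    treat-none is identically 0 and treat-all crosses 0 at t = prevalence.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = ((pred) & (y == 1)).sum() / n
        fp = ((pred) & (y == 0)).sum() / n
        odds = t / (1.0 - t)
        rows.append({
            "threshold": t,
            "net_benefit": tp - fp * odds,
            "treat_all": prev - (1 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


FoldPipeline = Callable[[np.ndarray, np.ndarray, int], np.ndarray]


def repeated_cv(
    labels: np.ndarray,
    fold_pipeline: FoldPipeline,
    repeats: int = 5,
    folds: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Repeated stratified k-fold AUCs of a full fold-refitted pipeline.

    ``fold_pipeline(train_idx, test_idx, fold_seed)`` must refit everything
    on the training fold (selection, clustering, learner) and return test
    scores.  Returns ``repeats * folds`` AUC values.
    """
    y = np.asarray(labels).astype(int)
    aucs = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for fi, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                raise RuntimeError("stratified fold produced a single class")
            scores = fold_pipeline(tr, te, seed * 1000 + r * folds + fi)
            aucs.append(roc_auc(scores, y[te])[0])
    return np.asarray(aucs)


def repeated_cv_table(
    table: pd.DataFrame,
    labels: np.ndarray,
    learner: str = "random_forest",
    repeats: int = 5,
    folds: int = 4,
    seed: int = 0,
    selection_config=None,
) -> np.ndarray:
    """Repeated CV where the selection cascade + learner refit per fold."""
    from .models import train_classifier
    from .selection import run_selection_cascade

    y = np.asarray(labels).astype(int)

    def fold(tr, te, fold_seed):
        sel = run_selection_cascade(table.iloc[tr], y[tr], selection_config, fold_seed)
        bundle = train_classifier(table.iloc[tr][sel.kept], y[tr], learner, fold_seed)
        return bundle.predict_proba(table.iloc[te])

    return repeated_cv(y, fold, repeats, folds, seed)


@dataclass
class ModelEval:
    """Held-out evaluation of one model."""

    auc: float
    ci: tuple[float, float]
    metrics: dict[str, float]
    calibration: pd.DataFrame
    dca: pd.DataFrame
    threshold: float


@dataclass
class EvalReport:
    """Per-model test-set evaluations plus pairwise DeLong comparisons."""

    models: dict[str, ModelEval] = field(default_factory=dict)
    delong: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    cv_aucs: dict[str, np.ndarray] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = {}
        for name, ev in self.models.items():
            rows[name] = {
                "auc": ev.auc, "ci_low": ev.ci[0], "ci_high": ev.ci[1],
                "accuracy": ev.metrics["accuracy"],
                "sensitivity": ev.metrics["sensitivity"],
                "specificity": ev.metrics["specificity"],
                "f1": ev.metrics["f1"],
                "threshold": ev.threshold,
            }
        return pd.DataFrame.from_dict(rows, orient="index")


def evaluate_model(
    scores: np.ndarray, labels: np.ndarray, threshold: float, n_calib_bins: int = 10
) -> ModelEval:
    """Bundle all single-model test-set evaluations."""
    auc, ci = roc_auc(scores, labels)
    return ModelEval(
        auc=auc,
        ci=ci,
        metrics=confusion_metrics(scores, labels, threshold),
        calibration=calibration_curve(scores, labels, n_calib_bins),
        dca=decision_curve(scores, labels),
        threshold=threshold,
    )
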