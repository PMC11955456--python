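"""Four-stage feature-selection cascade: MI filter -> mRMR -> LASSO -> Pearson.

Stage 1 ranks features by plug-in mutual information with the class label
(10 equal-frequency bins) and keeps the top block.  Stage 2 applies greedy
minimum-redundancy-maximum-relevance: the next feature maximises
``I(f; y) - mean_{s in S} I(f; s)``.  Stage 3 fits a squared-loss LASSO on
the 0/1 label over a 100-point log-spaced lambda grid, picking lambda by
10-fold cross-validated MSE (the stated selection criterion), and keeps the
features with non-zero coefficients.  Stage 4 prunes residual collinearity:
walking features by descending |LASSO coefficient|, any later feature with
|Pearson r| > 0.8 to an already-kept one is dropped.

All stages must be fitted on training rows only; the resulting
:class:`SelectionResult` records a complete audit of every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold

from .config import SelectionConfig


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile binning to codes 0..B-1 (B <= n_bins after tie merging)."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in MI (nats) between a continuous feature and discrete labels.

    ``x`` is discretised into ``n_bins`` equal-frequency bins, so the
    estimate is invariant to strictly monotone transforms of ``x``.
    Constant ``x`` gives 0 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if x.std() == 0:
        return 0.0
    bx = _equal_frequency_bins(x, n_bins)
    return discrete_mi(bx, y)


def discrete_mi(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) of two discrete code vectors via the contingency table."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1.0)
    n = table.sum()
    p = table / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def feature_feature_mi(x1: np.ndarray, x2: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in MI between two continuous features on a BxB quantile grid."""
    if np.std(x1) == 0 or np.std(x2) == 0:
        return 0.0
    return discrete_mi(_equal_frequency_bins(x1, n_bins),
                       _equal_frequency_bins(x2, n_bins))


def mi_filter(
    table: pd.DataFrame, labels: np.ndarray, keep_top: int = 300, n_bins: int = 10
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep the min(keep_top, ceil(p/2)) columns with highest label MI.

    Ties break by column name, so the result is order-stable under column
    permutation.  Returns (filtered table, full MI score series).
    """
    if table.shape[1] == 0:
        raise ValueError("empty feature table")
    scores = pd.Series(
        {c: mutual_information(table[c].to_numpy(), labels, n_bins) for c in table.columns}
    )
    n_keep = min(keep_top, int(np.ceil(table.shape[1] / 2)))
    order = sorted(table.columns, key=lambda c: (-scores[c], c))
    kept = order[:n_keep]
    return table[kept], scores


def mrmr_select(
    table: pd.DataFrame, labels: np.ndarray, m: int = 30, n_bins: int = 10
) -> list[str]:
    """Greedy mRMR ordering of up to ``m`` features.

    First pick maximises relevance I(f; y); each later pick maximises
    relevance minus mean redundancy to the already selected set.  Ties
    break by column name.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    cols = list(table.columns)
    x = {c: table[c].to_numpy() for c in cols}
    relevance = {c: mutual_information(x[c], labels, n_bins) for c in cols}
    selected: list[str] = []
    redundancy_sum = {c: 0.0 for c in cols}
    while len(selected) < min(m, len(cols)):
        remaining = [c for c in cols if c not in selected]
        if selected:
            last = selected[-1]
            for c in remaining:
                redundancy_sum[c] += feature_feature_mi(x[c], x[last], n_bins)
            score = {c: relevance[c] - redundancy_sum[c] / len(selected)
                     for c in remaining}
        else:
            score = {c: relevance[c] for c in remaining}
        selected.append(min(remaining, key=lambda c: (-score[c], c)))
    return selected


def lasso_cv_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_decades: float = 4.0,
) -> tuple[list[str], float, dict]:
    """Squared-loss LASSO with lambda chosen by stratified CV-MSE.

    Columns are standardised internally; the grid runs from lambda_max (the
    smallest penalty that zeroes every coefficient) down ``lambda_decades``
    decades.  Returns (kept features, lambda*, audit dict with the lambda
    path, CV-MSE curve and final coefficients).
    """
    y = np.asarray(labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    x = table.to_numpy(dtype=np.float64)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    xs = (x - mu) / sd
    n = len(y)
    lambda_max = float(np.max(np.abs(xs.T @ (y - y.mean()))) / n)
    if lambda_max <= 0:
        lambda_max = 1.0
    lambdas = np.logspace(np.log10(lambda_max), np.log10(lambda_max) - lambda_decades,
                          n_lambda)
    min_class = int(min(np.sum(y == u) for u in np.unique(y)))
    folds = min(folds, min_class)  # small samples: fall back to fewer folds
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    mse = np.zeros((folds, n_lambda))
    for fi, (tr, te) in enumerate(skf.split(xs, y)):
        model = Lasso(alpha=lambdas[0], warm_start=True, max_iter=5000)
        xtr, ytr = xs[tr], y[tr]
        for li, lam in enumerate(lambdas):
            model.set_params(alpha=lam)
            model.fit(xtr, ytr)
            pred = model.predict(xs[te])
            mse[fi, li] = float(np.mean((pred - y[te]) ** 2))
    mean_mse = mse.mean(axis=0)
    best = int(np.argmin(mean_mse))
    lam_star = float(lambdas[best])
    final = Lasso(alpha=lam_star, max_iter=50000, tol=1e-10).fit(xs, y)
    coef = final.coef_
    kept = [c for c, b in zip(table.columns, np.abs(coef) > 1e-10) if b]
    audit = {
        "lambdas": lambdas,
        "cv_mse": mean_mse,
        "lambda_star": lam_star,
        "coefficients": dict(zip(table.columns, coef)),
    }
    return kept, lam_star, audit


def pearson_prune(
    table: pd.DataFrame,
    kept: list[str],
    threshold: float = 0.8,
    priority: dict[str, float] | None = None,
) -> list[str]:
    """Greedy |r| pruning: walk by priority, drop features correlated > t.

    ``priority`` maps feature -> |LASSO coefficient| (higher walks first);
    ties break by name.  A feature is dropped when its absolute Pearson
    correlation with any already-retained feature exceeds ``threshold``.
    """
    priority = priority or {}
    order = sorted(kept, key=lambda c: (-abs(priority.get(c, 0.0)), c))
    retained: list[str] = []
    for c in order:
        xc = table[c].to_numpy(dtype=np.float64)
        drop = False
        for r in retained:
            xr = table[r].to_numpy(dtype=np.float64)
            if xc.std() == 0 or xr.std() == 0:
                corr = 1.0 if xc.std() == xr.std() == 0 else 0.0
            else:
                corr = abs(float(np.corrcoef(xc, xr)[0, 1]))
            if corr > threshold:
                drop = True
                break
        if not drop:
            retained.append(c)
    return retained


@dataclass
class SelectionResult:
    """Outcome and audit trail of the four-stage cascade."""

    kept: list[str]
    mi_scores: pd.Series
    mi_kept: list[str]
    mrmr_order: list[str]
    lasso_kept: list[str]
    lambda_star: float
    lasso_audit: dict = field(default_factory=dict)
    seed: int = 0


def run_selection_cascade(
    table: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig | None = None,
    seed: int = 0,
) -> SelectionResult:
    """MI filter -> mRMR -> LASSO(CV) -> Pearson pruning, on training rows.

    Each stage sees only the survivors of the previous one, so the final
    set is nested inside every intermediate set.
    """
    cfg = config or SelectionConfig()
    filtered, mi_scores = mi_filter(table, labels, cfg.mi_keep_top, cfg.mi_bins)
    mrmr = mrmr_select(filtered, labels, cfg.mrmr_m, cfg.mi_bins)
    lasso_kept, lam, audit = lasso_cv_select(
        filtered[mrmr], labels, cfg.lasso_folds, seed,
        cfg.lasso_n_lambda, cfg.lasso_lambda_decades,
    )
    if not lasso_kept:  # fully sparse solution: fall back to the top mRMR pick
        lasso_kept = mrmr[:1]
    priority = {c: abs(audit["coefficients"].get(c, 0.0)) for c in lasso_kept}
    final = pearson_prune(table, lasso_kept, cfg.pearson_threshold, priority)
    return SelectionResult(
        kept=final,
        mi_scores=mi_scores,
        mi_kept=list(filtered.columns),
        mrmr_order=mrmr,
        lasso_kept=lasso_kept,
        lambda_star=lam,
        lasso_audit=audit,
        seed=seed,
    )
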