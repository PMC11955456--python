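"""Classifier construction for the clinical, radiomics and habitat models.

The clinical model screens its candidate factors with per-factor
(univariable) logistic regression and keeps those with Wald p < 0.05; all
three models are then fitted with a learner from a registry of eleven
standard classifiers (random forest being the constructed default, the
rest retained for learner-screening comparisons).  Every bundle exposes the
same fit/predict-probability contract with feature-name schema checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLINICAL_FACTORS = ["age", "PV", "tPSA", "fPSA", "f_t_ratio", "PSAD"]


# ---------------------------------------------------------------------------
# univariable logistic screen
# ---------------------------------------------------------------------------

def _logistic_wald_p(x: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> float:
    """Wald p-value of the slope of a 1-factor logistic fit (Newton).

    ``ridge`` adds an L2 penalty on the slope so the Wald statistic stays
    defined under complete separation.
    """
    from scipy.stats import norm

    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    design = np.column_stack([np.ones_like(xs), xs])
    beta = np.zeros(2)
    pen = np.diag([0.0, ridge])
    for _ in range(100):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1 - p)
        grad = design.T @ (y - p) - pen @ beta
        hess = (design * w[:, None]).T @ design + pen
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return np.nan
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
        if np.max(np.abs(beta)) > 1e4:  # diverging: separation
            return np.nan
    # |slope| > 10 on a standardised factor means (near-)complete
    # separation: the Wald statistic degenerates (Hauck-Donner), so defer
    # to the penalised refit
    if ridge == 0.0 and abs(beta[1]) > 10:
        return np.nan
    cov = np.linalg.inv(hess)
    se = np.sqrt(cov[1, 1])
    if not np.isfinite(se) or se == 0:
        return np.nan
    z = beta[1] / se
    return float(2.0 * norm.sf(abs(z)))


def univariable_logistic_screen(
    clinical_table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    factors: Optional[list[str]] = None,
) -> tuple[list[str], pd.Series]:
    """Per-factor logistic regression; keep factors with Wald p < alpha.

    Constant factors are excluded (p = NaN, flagged by exclusion).  Under
    complete separation the unpenalised Wald statistic degenerates, so a
    small-ridge refit supplies the p-value instead.
    """
    factors = factors or [f for f in CLINICAL_FACTORS if f in clinical_table.columns]
    y = np.asarray(labels, dtype=np.float64)
    pvals = {}
    for f in factors:
        x = clinical_table[f].to_numpy(dtype=np.float64)
        if x.std() == 0:
            pvals[f] = np.nan
            continue
        p = _logistic_wald_p(x, y)
        if not np.isfinite(p):
            p = _logistic_wald_p(x, y, ridge=1.0)
        pvals[f] = p
    series = pd.Series(pvals)
    kept = [f for f in factors if np.isfinite(series[f]) and series[f] < alpha]
    return kept, series


# ---------------------------------------------------------------------------
# learner registry
# ---------------------------------------------------------------------------

class _LinearProbability:
    """Linear regression on the 0/1 label with scores clipped to [0, 1]."""

    def __init__(self) -> None:
        self._model = LinearRegression()

    def fit(self, x, y):
        self._model.fit(x, y)
        return self

    def predict_proba(self, x):
        p = np.clip(self._model.predict(x), 0.0, 1.0)
        return np.column_stack([1 - p, p])

    def get_params(self, deep=True):  # sklearn clone support
        return {}

    def set_params(self, **kw):
        return self


def _make_learner(name: str, seed: int, hyper: dict):
    scale = lambda est: Pipeline([("scale", StandardScaler()), ("est", est)])
    if name == "logistic_regression":
        return scale(LogisticRegression(max_iter=2000, random_state=seed, **hyper))
    if name == "linear_regression":
        return _LinearProbability()
    if name == "knn":
        return scale(KNeighborsClassifier(**(hyper or {"n_neighbors": 5})))
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hyper)
    if name == "svm":
        return scale(SVC(probability=True, random_state=seed, **hyper))
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            random_state=seed, verbosity=0, **hyper,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=500, max_features="sqrt", class_weight="balanced",
            random_state=seed, **hyper,
        )
    if name == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=200, random_state=seed, verbose=-1,
            deterministic=True, force_row_wise=True, **hyper,
        )
    if name == "neural_network":
        return scale(MLPClassifier(hidden_layer_sizes=(32,), max_iter=2000,
                                   random_state=seed, **hyper))
    if name == "gbm":
        return GradientBoostingClassifier(random_state=seed, **hyper)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hyper)
    raise ValueError(f"unknown learner {name!r}; choose from {sorted(LEARNERS)}")


LEARNERS = {
    "logistic_regression", "linear_regression", "knn", "decision_tree", "svm",
    "xgboost", "random_forest", "lightgbm", "neural_network", "gbm", "adaboost",
}


@dataclass
class ModelBundle:
    """A fitted classifier plus its feature schema and decision threshold."""

    kind: str  # clinical | radiomics | habitat
    learner: str
    estimator: object
    feature_names: list[str]
    seed: int
    threshold: float = 0.5
    train_scores: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing {missing}")
        x = table[self.feature_names].to_numpy(dtype=np.float64)
        return np.asarray(self.estimator.predict_proba(x))[:, 1]


def train_classifier(
    table: pd.DataFrame,
    labels: np.ndarray,
    learner: str = "random_forest",
    seed: int = 0,
    hyper: dict | None = None,
    kind: str = "radiomics",
) -> ModelBundle:
    """Fit one learner from the registry; deterministic under ``seed``."""
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; choose from {sorted(LEARNERS)}")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_learner(learner, seed, hyper or {})
    x = table.to_numpy(dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x, y)
    scores = np.asarray(est.predict_proba(x))[:, 1]
    bundle = ModelBundle(
        kind=kind, learner=learner, estimator=est,
        feature_names=list(table.columns), seed=seed, train_scores=scores,
    )
    bundle.threshold = choose_threshold(scores, y)
    return bundle


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Training threshold maximising Youden's J; ties go to the lowest cut."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to choose a threshold")
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)
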