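"""Feature-selection cascade: MI, mRMR, LASSO and Pearson pruning."""

import numpy as np
import pandas as pd
import pytest

from habitatrx.config import SelectionConfig
from habitatrx.selection import (
    feature_feature_mi,
    lasso_cv_select,
    mi_filter,
    mrmr_select,
    mutual_information,
    pearson_prune,
    run_selection_cascade,
)


class TestMutualInformation:
    def test_perfect_predictor_balanced(self):
        y = np.repeat([0, 1], 500)
        x = y.astype(float)
        assert mutual_information(x, y) == pytest.approx(np.log(2), rel=1e-9)

    def test_contingency_table_matches_direct_sum(self):
        # 2x2 table [[30,10],[10,30]]: MI = sum p log(p/(px py))
        x = np.concatenate([np.zeros(40), np.ones(40)])
        y = np.concatenate([np.zeros(30), np.ones(10), np.zeros(10), np.ones(30)])
        p = np.array([[30, 10], [10, 30]]) / 80
        px, py = p.sum(1, keepdims=True), p.sum(0, keepdims=True)
        expected = float(np.sum(p * np.log(p / (px @ py))))
        assert mutual_information(x, y) == pytest.approx(expected, rel=1e-12)

    def test_constant_feature_zero(self):
        assert mutual_information(np.ones(50), np.repeat([0, 1], 25)) == 0.0

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, 400)
        y = (x + rng.normal(0, 1, 400) > 0).astype(int)
        assert mutual_information(np.exp(x), y) == pytest.approx(
            mutual_information(x, y), rel=1e-12
        )

    def test_independent_near_zero(self, rng):
        x = rng.normal(0, 1, 5000)
        y = rng.integers(0, 2, 5000)
        assert mutual_information(x, y) < 0.01

    def test_estimator_consistency(self, rng):
        # balanced x == y on n = 1e5: plug-in estimate within 2% of ln 2
        y = rng.integers(0, 2, 100_000)
        x = y + rng.uniform(0, 0.01, len(y))
        assert mutual_information(x, y) == pytest.approx(np.log(2), rel=0.02)


class TestMiFilter:
    def test_keeps_half_of_ten(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (60, 10)),
                             columns=[f"f{i}" for i in range(10)])
        y = rng.integers(0, 2, 60)
        kept, scores = mi_filter(table, y, keep_top=300)
        assert kept.shape[1] == 5
        assert len(scores) == 10

    def test_signal_outranks_noise(self, rng):
        wins = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            y = r.integers(0, 2, 100)
            table = pd.DataFrame({
                "signal": y + r.normal(0, 0.3, 100),
                "noise": r.normal(0, 1, 100),
            })
            _, scores = mi_filter(table, y)
            wins += scores["signal"] > scores["noise"]
        assert wins >= 99

    def test_stable_under_column_permutation(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (80, 8)),
                             columns=[f"f{i}" for i in range(8)])
        y = rng.integers(0, 2, 80)
        a, _ = mi_filter(table, y)
        b, _ = mi_filter(table[list(reversed(table.columns))], y)
        assert sorted(a.columns) == sorted(b.columns)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mi_filter(pd.DataFrame(index=range(5)), np.zeros(5))


class TestMrmr:
    def test_first_pick_is_top_relevance(self, rng):
        y = rng.integers(0, 2, 200)
        table = pd.DataFrame({
            "best": y + rng.normal(0, 0.2, 200),
            "ok": y + rng.normal(0, 1.0, 200),
            "noise": rng.normal(0, 1, 200),
        })
        order = mrmr_select(table, y, m=3)
        assert order[0] == "best"

    def test_duplicate_of_first_selected_last(self, rng):
        y = rng.integers(0, 2, 300)
        best = y + rng.normal(0, 0.2, 300)
        table = pd.DataFrame({
            "a_best": best,
            "b_copy": best.copy(),  # redundant duplicate
            "c_indep": y + rng.normal(0, 1.5, 300),
            "d_indep2": y + rng.normal(0, 1.5, 300),
        })
        order = mrmr_select(table, y, m=4)
        assert order[0] == "a_best"
        assert order[-1] == "b_copy"

    def test_exhaustive_greedy_criterion(self, rng):
        # every pick maximises relevance - mean redundancy, checked by
        # brute-force evaluation of the criterion at each step
        y = rng.integers(0, 2, 150)
        table = pd.DataFrame(rng.normal(0, 1, (150, 5)),
                             columns=list("abcde"))
        table["a"] += y
        table["b"] += 0.5 * y
        order = mrmr_select(table, y, m=5)
        x = {c: table[c].to_numpy() for c in table.columns}
        rel = {c: mutual_information(x[c], y) for c in table.columns}
        selected = []
        for pick in order:
            remaining = [c for c in table.columns if c not in selected]
            if selected:
                scores = {
                    c: rel[c] - np.mean([feature_feature_mi(x[c], x[s])
                                         for s in selected])
                    for c in remaining
                }
            else:
                scores = {c: rel[c] for c in remaining}
            best = min(remaining, key=lambda c: (-scores[c], c))
            assert pick == best
            selected.append(pick)

    def test_m_equals_p_returns_permutation(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (50, 4)), columns=list("wxyz"))
        y = rng.integers(0, 2, 50)
        assert sorted(mrmr_select(table, y, m=4)) == list("wxyz")

    def test_invalid_m(self, rng):
        with pytest.raises(ValueError):
            mrmr_select(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0, 1]), m=0)


def naive_coordinate_descent(x, y, lam, n_iter=5000, tol=1e-12):
    """Textbook cyclic coordinate descent for the standardised LASSO."""
    n, p = x.shape
    beta = np.zeros(p)
    intercept = y.mean()
    r = y - intercept - x @ beta
    for _ in range(n_iter):
        max_step = 0.0
        for j in range(p):
            r += x[:, j] * beta[j]
            rho = x[:, j] @ r / n
            zj = (x[:, j] ** 2).mean()
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / zj
            max_step = max(max_step, abs(new - beta[j]))
            beta[j] = new
            r -= x[:, j] * beta[j]
        if max_step < tol:
            break
    return beta


class TestLasso:
    def test_lambda_max_zeroes_everything(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (40, 6)),
                             columns=[f"f{i}" for i in range(6)])
        y = rng.integers(0, 2, 40)
        kept, lam, audit = lasso_cv_select(table, y, folds=5, seed=0)
        beta_at_max = naive_coordinate_descent(
            (table.to_numpy() - table.to_numpy().mean(0)) / table.to_numpy().std(0),
            y.astype(float), audit["lambdas"][0],
        )
        assert np.allclose(beta_at_max, 0.0, atol=1e-8)

    def test_single_true_predictor_kept(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 300
            signal = r.normal(0, 1, n)
            y = (signal > 0).astype(float)
            table = pd.DataFrame(
                {"signal": signal,
                 **{f"n{i}": r.normal(0, 1, n) for i in range(5)}}
            )
            kept, _, _ = lasso_cv_select(table, y, folds=5, seed=seed)
            assert "signal" in kept

    def test_coefficients_match_naive_coordinate_descent(self, rng):
        n, p = 20, 5
        x = rng.normal(0, 1, (n, p))
        y = (x[:, 0] + 0.5 * x[:, 1] + rng.normal(0, 0.5, n) > 0).astype(float)
        table = pd.DataFrame(x, columns=[f"f{i}" for i in range(p)])
        kept, lam, audit = lasso_cv_select(table, y, folds=4, seed=1)
        xs = (x - x.mean(0)) / x.std(0)
        oracle = naive_coordinate_descent(xs, y, lam)
        got = np.array([audit["coefficients"][f"f{i}"] for i in range(p)])
        assert np.allclose(got, oracle, atol=1e-6)

    def test_single_class_rejected(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            lasso_cv_select(table, np.zeros(10), folds=3, seed=0)


class TestPearsonPrune:
    def test_exact_duplicate_dropped(self, rng):
        a = rng.normal(0, 1, 50)
        table = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(0, 1, 50)})
        kept = pearson_prune(table, ["a", "b", "c"], priority={"a": 2, "b": 1, "c": 0.5})
        assert kept == ["a", "c"]

    def test_negated_feature_dropped(self, rng):
        a = rng.normal(0, 1, 50)
        table = pd.DataFrame({"a": a, "neg": -a})
        kept = pearson_prune(table, ["a", "neg"], priority={"a": 1, "neg": 0.9})
        assert kept == ["a"]

    def test_mutually_correlated_triple_keeps_one(self, rng):
        base = rng.normal(0, 1, 500)
        table = pd.DataFrame({
            "x1": base + rng.normal(0, 0.25, 500),
            "x2": base + rng.normal(0, 0.25, 500),
            "x3": base + rng.normal(0, 0.25, 500),
        })
        corr = table.corr().abs().to_numpy()
        assert (corr[np.triu_indices(3, 1)] > 0.8).all()
        kept = pearson_prune(table, list(table.columns),
                             priority={"x1": 3, "x2": 2, "x3": 1})
        assert kept == ["x1"]


@pytest.fixture(scope="module")
def cascade_data():
    rng = np.random.default_rng(12)
    n = 120
    y = rng.integers(0, 2, n)
    cols = {f"noise{i}": rng.normal(0, 1, n) for i in range(30)}
    cols["signal_a"] = y + rng.normal(0, 0.5, n)
    cols["signal_b"] = y + rng.normal(0, 0.8, n)
    cols["signal_a_copy"] = cols["signal_a"] + rng.normal(0, 0.05, n)
    return pd.DataFrame(cols), y


class TestCascade:
    def test_stage_nesting(self, cascade_data):
        table, y = cascade_data
        res = run_selection_cascade(table, y, SelectionConfig(mrmr_m=10), seed=0)
        assert set(res.kept) <= set(res.lasso_kept)
        assert set(res.lasso_kept) <= set(res.mrmr_order)
        assert set(res.mrmr_order) <= set(res.mi_kept)
        assert set(res.mi_kept) <= set(table.columns)

    def test_finds_signal_and_drops_duplicate(self, cascade_data):
        table, y = cascade_data
        res = run_selection_cascade(table, y, SelectionConfig(mrmr_m=10), seed=0)
        assert "signal_a" in res.kept or "signal_a_copy" in res.kept
        assert not ("signal_a" in res.kept and "signal_a_copy" in res.kept)

    def test_deterministic_under_seed(self, cascade_data):
        table, y = cascade_data
        a = run_selection_cascade(table, y, seed=3)
        b = run_selection_cascade(table, y, seed=3)
        assert a.kept == b.kept
        assert a.lambda_star == b.lambda_star
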