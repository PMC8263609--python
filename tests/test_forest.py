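"""Random survival forest: splitting rule, routing, importance, determinism."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from proxsurv.forest import (
    SurvivalTree,
    fit_survival_forest,
    forest_from_json,
    forest_to_json,
    predict_forest_risk,
    terminal_node_ids,
    variable_importance_frequency,
)


def _two_group_data(rng, n=200, hr=10.0):
    """One feature perfectly ordering two hazard-separated groups."""
    group = np.repeat([0, 1], n // 2)
    x_inform = group + 0.1 * rng.random(n)  # group 1 values all above group 0
    X = np.column_stack([x_inform, rng.normal(size=n), rng.normal(size=n)])
    t = rng.exponential(1.0 / (0.01 * hr**group))
    e = np.ones(n, dtype=int)
    return X, t, e, group


def test_root_splits_on_perfectly_ordering_feature(rng):
    X, t, e, _ = _two_group_data(rng)
    forest = fit_survival_forest(X, t, e, n_trees=60, mtry=3, min_node_size=5, seed=8)
    roots = np.array([tree.feature[0] for tree in forest.trees])
    assert (roots == 0).mean() >= 0.95


def test_min_node_size_n_gives_single_node_trees(rng):
    X, t, e, _ = _two_group_data(rng, n=60)
    forest = fit_survival_forest(X, t, e, n_trees=10, min_node_size=60, seed=1)
    assert all(tree.n_nodes == 1 for tree in forest.trees)
    risk = predict_forest_risk(forest, X)
    assert np.allclose(risk, risk[0])  # single-node forest: identical risk


def test_same_seed_bit_identical_forest(rng):
    X, t, e, _ = _two_group_data(rng, n=80)
    a = fit_survival_forest(X, t, e, n_trees=12, min_node_size=5, seed=5)
    b = fit_survival_forest(X, t, e, n_trees=12, min_node_size=5, seed=5)
    c = fit_survival_forest(X, t, e, n_trees=12, min_node_size=5, seed=6)
    for ta, tb in zip(a.trees, b.trees):
        np.testing.assert_array_equal(ta.feature, tb.feature)
        np.testing.assert_array_equal(ta.threshold, tb.threshold)
        np.testing.assert_array_equal(ta.inbag_counts, tb.inbag_counts)
    assert any(
        not np.array_equal(ta.inbag_counts, tc.inbag_counts) for ta, tc in zip(a.trees, c.trees)
    )


def test_hand_built_tree_routes_manually():
    """2-split tree on 3 samples matches a hand trace."""
    tree = SurvivalTree(
        feature=np.array([0, -1, 1, -1, -1], dtype=np.int32),
        threshold=np.array([0.5, np.nan, 2.0, np.nan, np.nan]),
        left=np.array([1, -1, 3, -1, -1], dtype=np.int32),
        right=np.array([2, -1, 4, -1, -1], dtype=np.int32),
        leaf_row=np.array([-1, 0, -1, 1, 2], dtype=np.int32),
        chf=np.zeros((3, 1)),
        inbag_counts=np.ones(3, dtype=np.int32),
    )
    X = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 3.0]])
    # sample 0: x0<=0.5 -> node 1; sample 1: right, x1<=2 -> node 3; sample 2: -> node 4
    np.testing.assert_array_equal(tree.apply(X), [1, 3, 4])


def test_terminal_ids_training_consistency(rng):
    X, t, e, _ = _two_group_data(rng, n=80)
    forest = fit_survival_forest(X, t, e, n_trees=8, min_node_size=5, seed=2)
    ids = terminal_node_ids(forest, X)
    assert ids.shape == (80, 8)
    np.testing.assert_array_equal(ids, forest.training_node_ids)
    # every id is a terminal node of its tree
    for j, tree in enumerate(forest.trees):
        assert np.all(tree.feature[ids[:, j]] == -1)


def test_variable_importance_counts(rng):
    X, t, e, _ = _two_group_data(rng)
    # shallow trees so outcome-driven splits dominate the counts
    forest = fit_survival_forest(X, t, e, n_trees=30, mtry=3, min_node_size=50, seed=3)
    ranking = variable_importance_frequency(forest)
    total_internal = sum(int((tree.feature >= 0).sum()) for tree in forest.trees)
    assert sum(c for _, c in ranking) == total_internal
    assert ranking[0][0] == "x0"  # informative feature ranked first
    # single-node forest: all counts zero
    stub = fit_survival_forest(X, t, e, n_trees=5, min_node_size=X.shape[0], seed=3)
    assert all(c == 0 for _, c in variable_importance_frequency(stub))


def test_risk_ordering_high_vs_low_hazard(rng):
    X, t, e, group = _two_group_data(rng)
    forest = fit_survival_forest(X, t, e, n_trees=40, min_node_size=5, seed=4)
    risk = predict_forest_risk(forest, X)
    assert risk[group == 1].mean() > risk[group == 0].mean()


def test_risk_invariant_to_monotone_feature_transform(rng):
    """Rank-based splitting: refit on exp-transformed data, same seed, same risks."""
    X, t, e, _ = _two_group_data(rng, n=100)
    f1 = fit_survival_forest(X, t, e, n_trees=15, min_node_size=5, seed=9)
    X2 = X.copy()
    X2[:, 0] = np.exp(X2[:, 0])
    f2 = fit_survival_forest(X2, t, e, n_trees=15, min_node_size=5, seed=9)
    np.testing.assert_allclose(
        predict_forest_risk(f1, X), predict_forest_risk(f2, X2), rtol=1e-12
    )


def test_bootstrap_unique_fraction_632(rng):
    X, t, e, _ = _two_group_data(rng, n=100)
    forest = fit_survival_forest(X, t, e, n_trees=300, min_node_size=100, seed=11)
    frac = np.mean([(tree.inbag_counts > 0).mean() for tree in forest.trees])
    assert abs(frac - (1 - np.exp(-1))) < 0.01


def test_best_split_matches_exhaustive_logrank_oracle(rng):
    """The chosen split maximizes the two-sample log-rank statistic over all
    admissible (feature, midpoint) candidates, verified against lifelines."""
    from proxsurv.forest import _best_split

    n, p, min_node = 40, 3, 3
    for trial in range(5):
        X = rng.normal(size=(n, p))
        t = rng.exponential(20, size=n)
        e = rng.integers(0, 2, size=n)
        if np.unique(t[e == 1]).size < 2:
            continue
        samples = np.arange(n)

        class AllFeatures:
            def choice(self, pp, size, replace):
                return np.arange(p)

        got = _best_split(X, t, e, samples, p, min_node, AllFeatures())

        best_chi, best = -1.0, None
        for f in range(p):
            xs = np.unique(X[:, f])
            for lo, hi in zip(xs[:-1], xs[1:]):
                thr = (lo + hi) / 2
                m = X[:, f] <= thr
                if m.sum() < min_node or (~m).sum() < min_node:
                    continue
                chi = ll_logrank(t[m], t[~m], e[m], e[~m]).test_statistic
                if chi > best_chi + 1e-9:
                    best_chi, best = chi, (f, thr)
        if best is None:
            assert got is None
        else:
            assert got is not None
            f_got, thr_got = got
            m = X[:, f_got] <= thr_got
            chi_got = ll_logrank(t[m], t[~m], e[m], e[~m]).test_statistic
            assert chi_got == pytest.approx(best_chi, abs=1e-8)


def test_never_splits_on_inbag_constant_feature(rng):
    X, t, e, _ = _two_group_data(rng, n=80)
    X = np.column_stack([X, np.full(80, 7.0)])
    forest = fit_survival_forest(X, t, e, n_trees=20, min_node_size=5, seed=6)
    for tree in forest.trees:
        assert not np.any(tree.feature == 3)


def test_json_roundtrip(rng):
    X, t, e, _ = _two_group_data(rng, n=60)
    forest = fit_survival_forest(X, t, e, n_trees=6, min_node_size=5, seed=7)
    back = forest_from_json(forest_to_json(forest))
    np.testing.assert_allclose(
        predict_forest_risk(forest, X), predict_forest_risk(back, X), rtol=0
    )
    np.testing.assert_array_equal(terminal_node_ids(forest, X), terminal_node_ids(back, X))


def test_mtry_too_large_raises(rng):
    X, t, e, _ = _two_group_data(rng, n=40)
    with pytest.raises(ValueError, match="mtry"):
        fit_survival_forest(X, t, e, n_trees=2, mtry=10, min_node_size=5, seed=0)
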