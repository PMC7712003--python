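"""Hard-tree stage: leaf estimators, split search, JSDT/JSDF construction."""

import json

import numpy as np
import pytest

from tntlearn import (
    DecisionTree,
    Forest,
    ForestConfig,
    TreeConfig,
    best_split,
    fit_cart,
    fit_forest,
    fit_jsdt,
    js_estimate,
    js_shrink_leaves,
    leaf_value_mle,
)
from tntlearn.trees import LeafStats, _find_best_split, _OtherLeaves


# ---------------------------------------------------------------------------
# Leaf estimators
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "targets, expected",
    [([1, 1, 1], 1.0), ([0, 2], 1.0), ([0.5, 1.5, 2.5, 3.5], 2.0)],
)
def test_leaf_value_is_arithmetic_mean(targets, expected):
    assert leaf_value_mle(targets) == pytest.approx(expected)


def test_leaf_value_rejects_empty_input():
    with pytest.raises(ValueError):
        leaf_value_mle([])


def test_js_estimate_hand_worked_case():
    # ||ybar||^2 = 6, factor = 1 - 1/6 = 5/6
    est = js_estimate([1.0, -1.0, 2.0, 0.0], np.zeros(4), 1.0, 4)
    assert est == pytest.approx([5 / 6, -5 / 6, 10 / 6, 0.0])


def test_js_estimate_degenerate_contracts():
    ybar = np.array([0.4, -0.2, 1.0, 0.3])
    # zero noise: no shrinkage, bit-identical
    assert np.array_equal(js_estimate(ybar, np.zeros(4), 0.0), ybar)
    # observed means equal the prior point: return the prior point
    nu = np.full(4, 2.0)
    assert np.array_equal(js_estimate(nu, nu, 1.0), nu)


def test_js_estimate_requires_four_dimensions():
    with pytest.raises(ValueError, match="m >= 4"):
        js_estimate([1.0, 2.0, 3.0], np.zeros(3), 1.0)


def test_js_estimate_positive_part_never_overshoots():
    # enormous noise: the factor clips at 0 and the estimate collapses to nu
    nu = np.array([1.0, 1.0, 1.0, 1.0])
    est = js_estimate([1.1, 0.9, 1.2, 0.8], nu, 1e6)
    assert est == pytest.approx(nu)


def test_js_shrink_hand_worked_case():
    means = np.array([0.0, 2.0, 4.0, 6.0])
    out = js_shrink_leaves((means, np.ones(4), np.ones(4)), 1.0)
    # GM = 3, gamma = 1/20, factor 0.95
    assert out == pytest.approx([0.15, 2.05, 3.95, 5.85])


def test_js_shrink_disabled_and_full_shrinkage_limits():
    means = np.array([0.0, 2.0, 4.0, 6.0])
    triple = (means, np.ones(4), np.ones(4))
    assert np.array_equal(js_shrink_leaves(triple, 0.0), means)
    # lambda*gamma >= 1 collapses every leaf to the global mean
    assert js_shrink_leaves(triple, 1e6) == pytest.approx(np.full(4, 3.0))


def test_js_shrink_equal_means_returned_unchanged():
    means = np.full(5, 1.25)
    out = js_shrink_leaves((means, np.full(5, 3.0), np.ones(5)), 25.0)
    assert np.array_equal(out, means)


def test_js_shrink_geometry_between_local_mean_and_global_mean(rng):
    """Every shrunk value lies on the segment [local mean, GM]."""
    for _ in range(50):
        m = int(rng.integers(4, 12))
        means = rng.normal(size=m)
        counts = rng.integers(1, 20, size=m).astype(float)
        variances = rng.uniform(0.01, 2.0, size=m)
        lam = float(rng.uniform(0.0, 50.0))
        out = js_shrink_leaves((means, counts, variances), lam)
        gm = means.mean()
        lo = np.minimum(means, gm) - 1e-12
        hi = np.maximum(means, gm) + 1e-12
        assert np.all(out >= lo) and np.all(out <= hi)


def test_js_shrink_accepts_leafstats_objects():
    leaves = [LeafStats(v, 1, 1.0, v) for v in (0.0, 2.0, 4.0, 6.0)]
    assert js_shrink_leaves(leaves, 1.0) == pytest.approx([0.15, 2.05, 3.95, 5.85])


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

def test_best_split_perfect_separation():
    sp = best_split(np.array([[1.0], [2.0], [3.0], [4.0]]), [0.0, 0.0, 1.0, 1.0])
    assert sp.feature_index == 0
    assert sp.threshold == pytest.approx(2.5)
    assert sp.loss == pytest.approx(0.0, abs=1e-12)


def test_best_split_constant_targets_returns_first_candidate():
    X = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]])
    sp = best_split(X, [2.0, 2.0, 2.0])
    assert sp.feature_index == 0
    assert sp.threshold == pytest.approx(1.5)
    assert sp.loss == pytest.approx(0.0, abs=1e-12)


def test_best_split_no_valid_split_on_constant_features():
    X = np.ones((6, 2))
    assert best_split(X, np.arange(6.0)) is None


def oracle_best_split(X, y, min_leaf=1):
    """Independent brute force over (feature, midpoint, missing-direction)."""
    n, d = X.shape
    best = None
    for a in range(d):
        col = X[:, a]
        miss = np.isnan(col)
        vals = np.unique(col[~miss])
        if vals.size < 2:
            continue
        for v in 0.5 * (vals[:-1] + vals[1:]):
            directions = [True, False] if miss.any() else [True]
            losses = []
            for mleft in directions:
                left = np.where(miss, mleft, col <= v)
                yl, yr = y[left], y[~left]
                if len(yl) < min_leaf or len(yr) < min_leaf:
                    losses.append(np.inf)
                    continue
                losses.append(
                    ((yl - yl.mean()) ** 2).sum() + ((yr - yr.mean()) ** 2).sum()
                )
            loss = min(losses)
            if best is None or loss < best[0] - 1e-9 * (1 + abs(best[0])):
                best = (loss, a, v)
    return best


@pytest.mark.parametrize("with_missing", [False, True])
def test_best_split_matches_bruteforce_enumeration(with_missing, rng):
    for _ in range(30):
        n = int(rng.integers(5, 51))
        d = int(rng.integers(1, 6))
        X = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        if with_missing:
            X = X.copy()
            X[rng.random((n, d)) < 0.2] = np.nan
        got = best_split(X, y)
        want = oracle_best_split(X, y)
        if want is None:
            assert got is None
            continue
        assert got.feature_index == want[1]
        assert got.threshold == pytest.approx(want[2], abs=1e-12)
        assert got.loss == pytest.approx(want[0], rel=1e-8, abs=1e-10)


# ---------------------------------------------------------------------------
# CART construction
# ---------------------------------------------------------------------------

def test_cart_single_sample_is_depth_zero():
    tree = fit_cart([[3.0]], [1.5])
    assert tree.n_leaves == 1 and tree.depth == 0
    assert tree.predict([[99.0]]) == pytest.approx([1.5])


def test_cart_zero_training_error_on_separable_data():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [3.0, 3.0]])
    y = np.array([1.0, 1.0, 2.0, 3.0])
    tree = fit_cart(X, y, TreeConfig(depth_limit=2))
    assert np.mean((tree.predict(X) - y) ** 2) == pytest.approx(0.0, abs=1e-20)


def test_cart_prediction_is_piecewise_constant(rng, clinical_small):
    depth = 3
    tree = fit_cart(clinical_small.X, clinical_small.y, TreeConfig(depth_limit=depth))
    assert np.unique(tree.predict(clinical_small.X)).size <= 2**depth


def test_cart_rejects_empty_dataset():
    with pytest.raises(ValueError):
        fit_cart(np.empty((0, 2)), [])


# ---------------------------------------------------------------------------
# JSDT
# ---------------------------------------------------------------------------

def test_jsdt_lambda_zero_serializes_identically_to_cart(rng):
    X = rng.normal(size=(80, 4))
    y = rng.normal(size=80)
    cart = fit_cart(X, y)
    jsdt = fit_jsdt(X, y, TreeConfig(shrink_lambda=0.0))
    assert json.dumps(cart.to_dict(), sort_keys=True) == json.dumps(
        jsdt.to_dict(), sort_keys=True
    )


def test_jsdt_two_leaf_tree_equals_cart_for_any_lambda(rng):
    X = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    cart = fit_cart(X, y, TreeConfig(depth_limit=1))
    jsdt = fit_jsdt(X, y, TreeConfig(depth_limit=1, shrink_lambda=25.0))
    assert np.array_equal(cart.predict(X), jsdt.predict(X))


def test_jsdt_leaf_values_pulled_toward_global_mean(rng):
    X = rng.normal(size=(150, 4))
    y = rng.normal(size=150)
    tree = fit_jsdt(X, y, TreeConfig(depth_limit=4, shrink_lambda=25.0))
    leaves = tree.leaves()
    means = np.array([l.local_mean for l in leaves])
    shrunk = np.array([l.shrunk_value for l in leaves])
    gm = means.mean()
    assert np.all(np.abs(shrunk - gm) <= np.abs(means - gm) + 1e-12)
    assert not np.allclose(shrunk, means)  # shrinkage actually engaged


def test_jsdt_shrunk_equals_mean_when_disabled(rng):
    X = rng.normal(size=(60, 3))
    y = rng.normal(size=60)
    for leaf in fit_cart(X, y).leaves():
        assert leaf.shrunk_value == leaf.local_mean


# ---------------------------------------------------------------------------
# Prediction and leaf indexing
# ---------------------------------------------------------------------------

def test_one_leaf_tree_predicts_global_mean(rng):
    y = rng.normal(size=20)
    tree = fit_cart(np.ones((20, 2)), y)  # constant features: no split
    assert tree.predict(rng.normal(size=(5, 2))) == pytest.approx(
        np.full(5, y.mean())
    )


def test_forest_prediction_is_simple_average_of_trees():
    # three single-leaf trees predicting 1, 2, 3
    trees = [fit_cart([[0.0]], [float(v)]) for v in (1, 2, 3)]
    forest = Forest(trees=trees, config=ForestConfig(n_trees=3), n_features=1)
    assert forest.predict([[0.0]]) == pytest.approx([2.0])


def test_forest_of_identical_trees_equals_single_tree(rng):
    X = rng.normal(size=(50, 3))
    y = rng.normal(size=50)
    tree = fit_jsdt(X, y)
    forest = Forest(trees=[tree, tree, tree], config=ForestConfig(), n_features=3)
    assert np.array_equal(forest.predict(X), tree.predict(X))


def test_apply_depth_zero_maps_all_to_leaf_zero(rng):
    tree = fit_cart([[1.0]], [2.0])
    assert np.array_equal(tree.apply(rng.normal(size=(7, 1))), np.zeros(7, dtype=int))


def test_apply_all_left_path_is_leaf_zero():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    tree = fit_cart(X, [0.0, 1.0, 2.0, 3.0], TreeConfig(depth_limit=2))
    assert tree.apply([[-100.0]])[0] == 0


def test_apply_partition_covers_all_samples(rng):
    X = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    tree = fit_cart(X, y, TreeConfig(depth_limit=2))
    idx = tree.apply(X)
    assert set(np.unique(idx)) <= set(range(tree.n_leaves))
    assert idx.shape == (40,)


def test_missing_values_always_reach_a_leaf(rng):
    X = rng.normal(size=(100, 4))
    y = rng.normal(size=100)
    X[rng.random((100, 4)) < 0.3] = np.nan
    tree = fit_jsdt(X, y, TreeConfig(shrink_lambda=25.0))
    all_nan = np.full((5, 4), np.nan)
    assert np.all(np.isfinite(tree.predict(all_nan)))
    assert np.all(np.isfinite(tree.predict(X)))


# ---------------------------------------------------------------------------
# Forest fitting
# ---------------------------------------------------------------------------

def test_forest_single_tree_without_bootstrap_equals_jsdt(rng):
    X = rng.normal(size=(60, 3))
    y = rng.normal(size=60)
    cfg = ForestConfig(n_trees=1, depth_limit=6, bootstrap=False, seed=3)
    forest = fit_forest(X, y, cfg)
    tree = fit_jsdt(X, y, TreeConfig(depth_limit=6, shrink_lambda=25.0))
    assert np.array_equal(forest.predict(X), tree.predict(X))


def test_forest_same_seed_gives_identical_leaf_indices(rng):
    X = rng.normal(size=(80, 4))
    y = rng.normal(size=80)
    cfg = ForestConfig(n_trees=6, depth_limit=4, seed=9)
    a = fit_forest(X, y, cfg).apply(X)
    b = fit_forest(X, y, cfg).apply(X)
    assert np.array_equal(a, b)


def test_forest_default_has_80_trees_capped_at_depth_9(clinical_small):
    forest = fit_forest(clinical_small.X, clinical_small.y, ForestConfig(seed=1))
    assert forest.n_trees == 80
    assert all(t.depth <= 9 for t in forest.trees)


def test_forest_rejects_zero_trees():
    with pytest.raises(ValueError):
        fit_forest(np.ones((5, 1)), np.ones(5), ForestConfig(n_trees=0))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_tree_json_round_trip_preserves_predictions(tmp_path, rng):
    X = rng.normal(size=(60, 3))
    y = rng.normal(size=60)
    tree = fit_jsdt(X, y)
    path = tmp_path / "tree.json"
    tree.to_json(path)
    clone = DecisionTree.from_json(path)
    assert np.array_equal(tree.predict(X), clone.predict(X))
    assert np.array_equal(tree.apply(X), clone.apply(X))


def test_forest_dict_round_trip(rng):
    X = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    forest = fit_forest(X, y, ForestConfig(n_trees=4, depth_limit=3, seed=2))
    clone = Forest.from_dict(json.loads(json.dumps(forest.to_dict())))
    assert np.array_equal(forest.predict(X), clone.predict(X))
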