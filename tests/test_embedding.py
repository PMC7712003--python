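"""Leaf embeddings: one-hot encoding, tree grouping, dense tables."""

import numpy as np
import pytest

from tntlearn import (
    EmbeddingTrainConfig,
    Forest,
    ForestConfig,
    TreeConfig,
    encode,
    fit_cart,
    fit_forest,
    fit_leaf_embedding,
    group_trees,
    leaf_onehot,
    leaf_targets,
    onehot_embedding,
)
from tntlearn.embedding import LeafEmbedding


@pytest.fixture(scope="module")
def small_forest():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(200, 4))
    y = rng.normal(size=200)
    forest = fit_forest(X, y, ForestConfig(n_trees=8, depth_limit=3, seed=4))
    return forest, X, y


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def test_single_leaf_tree_encodes_to_all_ones():
    tree = fit_cart([[1.0], [1.0]], [2.0, 2.0])  # constant: one leaf
    M = leaf_onehot(tree, [[0.0], [5.0], [9.0]])
    assert M.shape == (3, 1)
    assert np.all(M.toarray() == 1.0)


def test_onehot_row_sums_equal_tree_count(small_forest):
    forest, X, _ = small_forest
    M = leaf_onehot(forest, X)
    assert np.all(np.asarray(M.sum(axis=1)).ravel() == forest.n_trees)


def test_onehot_worked_two_tree_encoding():
    # two separable stumps on different features; a sample reaching leaves
    # (1, 0) encodes (0,1,1,0)
    X = np.array([[0.0, 3.0], [1.0, 6.0], [2.0, 4.0], [3.0, 7.0]])
    t1 = fit_cart(X, [0.0, 0.0, 1.0, 1.0], TreeConfig(depth_limit=1))
    t2 = fit_cart(X, [0.0, 1.0, 0.0, 1.0], TreeConfig(depth_limit=1))
    forest = Forest(trees=[t1, t2], config=ForestConfig(n_trees=2), n_features=2)
    probe = np.array([[2.5, 3.0]])  # right leaf of t1, left of t2
    assert t1.apply(probe)[0] == 1 and t2.apply(probe)[0] == 0
    assert leaf_onehot(forest, probe).toarray()[0].tolist() == [0, 1, 1, 0]


# ---------------------------------------------------------------------------
# Tree grouping
# ---------------------------------------------------------------------------

def test_group_trees_singletons_and_single_group():
    singles = group_trees(6, 6, seed=0)
    assert sorted(int(g[0]) for g in singles) == list(range(6))
    whole = group_trees(6, 1, seed=0)
    assert sorted(whole[0].tolist()) == list(range(6))


def test_group_trees_sizes_differ_by_at_most_one():
    groups = group_trees(80, 8, seed=1)
    sizes = [len(g) for g in groups]
    assert sizes == [10] * 8
    ragged = group_trees(10, 3, seed=1)
    assert max(len(g) for g in ragged) - min(len(g) for g in ragged) <= 1


def test_group_trees_deterministic_and_partitioning():
    a = group_trees(80, 8, seed=5)
    b = group_trees(80, 8, seed=5)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
    assert sorted(np.concatenate(a).tolist()) == list(range(80))


def test_group_trees_rejects_out_of_range_k():
    with pytest.raises(ValueError):
        group_trees(5, 0)
    with pytest.raises(ValueError):
        group_trees(5, 6)


# ---------------------------------------------------------------------------
# Dense embedding training
# ---------------------------------------------------------------------------

def test_dense_embedding_loss_decreases(small_forest):
    forest, X, _ = small_forest
    L = forest.apply(X)
    P = leaf_targets(forest, X)
    cfg = EmbeddingTrainConfig(embed_dim=3, n_groups=4, epochs=40, seed=0)
    emb = fit_leaf_embedding(L, P, [t.n_leaves for t in forest.trees], cfg)
    assert emb.loss_history[-1] < emb.loss_history[0]


def test_dense_embedding_constant_targets_reach_near_zero_loss(small_forest):
    forest, X, _ = small_forest
    L = forest.apply(X)
    P = np.full_like(L, 0.5, dtype=float)
    cfg = EmbeddingTrainConfig(embed_dim=2, n_groups=2, epochs=400, lr=0.05, seed=1)
    emb = fit_leaf_embedding(L, P, [t.n_leaves for t in forest.trees], cfg)
    assert emb.loss_history[-1] < 1e-2 * max(emb.loss_history[0], 1.0)


def test_grouped_targets_are_per_tree_sums():
    """On a worked 4-sample fixture the group target equals the sum of the
    two member trees' leaf predictions."""
    X = np.array([[0.0, 3.0], [1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
    y1 = np.array([0.0, 0.0, 1.0, 1.0])
    y2 = np.array([0.0, 1.0, 1.0, 1.0])
    t1 = fit_cart(X, y1, TreeConfig(depth_limit=1))
    t2 = fit_cart(X, y2, TreeConfig(depth_limit=1))
    forest = Forest(trees=[t1, t2], config=ForestConfig(n_trees=2), n_features=2)
    P = leaf_targets(forest, X)
    group_sum = P.sum(axis=1)
    assert group_sum == pytest.approx(t1.predict(X) + t2.predict(X))


def test_dense_targets_finite_check(small_forest):
    forest, X, _ = small_forest
    L = forest.apply(X)
    P = leaf_targets(forest, X)
    P[0, 0] = np.nan
    with pytest.raises(ValueError):
        fit_leaf_embedding(L, P, [t.n_leaves for t in forest.trees])


def test_leaf_shrinking_changes_targets_not_geometry(small_forest):
    forest, X, _ = small_forest
    raw = leaf_targets(forest, X, shrunk=False)
    shrunk = leaf_targets(forest, X, shrunk=True)
    assert raw.shape == shrunk.shape
    assert not np.allclose(raw, shrunk)
    # the leaf-index geometry is untouched by the target choice
    assert np.array_equal(forest.apply(X), forest.apply(X))


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def test_encode_onehot_mode_reduces_to_leaf_onehot(small_forest):
    forest, X, _ = small_forest
    emb = onehot_embedding(forest)
    assert np.array_equal(encode(emb, forest, X), leaf_onehot(forest, X).toarray())


def test_encode_dense_width_is_embed_dim_times_groups(small_forest):
    forest, X, _ = small_forest
    cfg = EmbeddingTrainConfig(embed_dim=4, n_groups=4, epochs=5, seed=2)
    emb = fit_leaf_embedding(
        forest.apply(X), leaf_targets(forest, X), [t.n_leaves for t in forest.trees], cfg
    )
    out = encode(emb, forest, X)
    assert out.shape == (X.shape[0], 4 * 4)
    assert emb.width == 16


def test_encode_identical_samples_identical_rows(small_forest):
    forest, X, _ = small_forest
    cfg = EmbeddingTrainConfig(embed_dim=3, n_groups=2, epochs=5, seed=3)
    emb = fit_leaf_embedding(
        forest.apply(X), leaf_targets(forest, X), [t.n_leaves for t in forest.trees], cfg
    )
    probe = np.vstack([X[0], X[0]])
    out = encode(emb, forest, probe)
    assert np.array_equal(out[0], out[1])


def test_encode_schema_mismatch_raises(small_forest):
    forest, X, _ = small_forest
    other = fit_forest(X[:, :3], np.arange(200.0), ForestConfig(n_trees=3, depth_limit=2, seed=0))
    emb = onehot_embedding(forest)
    with pytest.raises(ValueError):
        encode(emb, other, X[:, :3])


def test_embedding_serialization_round_trip(small_forest):
    forest, X, _ = small_forest
    cfg = EmbeddingTrainConfig(embed_dim=3, n_groups=2, epochs=5, seed=4)
    emb = fit_leaf_embedding(
        forest.apply(X), leaf_targets(forest, X), [t.n_leaves for t in forest.trees], cfg
    )
    clone = LeafEmbedding.from_dict(emb.to_dict())
    assert np.array_equal(encode(emb, forest, X), encode(clone, forest, X))
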