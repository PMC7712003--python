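"""Leaf embeddings: turning forest leaf indices into teacher inputs.

A fitted tree routes every sample to exactly one leaf, so a forest induces a
categorical code per (sample, tree).  Two encodings are provided:

* **one-hot** — one column block per tree, one hot entry per sample and tree;
  exact but wide (total width = total leaf count).  The default for single
  trees on small data.
* **dense** — trees are first partitioned into ``k`` equally sized random
  groups; each group holds a learnable lookup table mapping its leaves to
  ``embed_dim``-dimensional vectors, and a sample's group block is the sum of
  the embeddings of the leaves it reaches within the group.  The tables are
  trained with a linear head against the (group-summed) per-tree leaf
  predictions p_t(X) by mini-batch gradient descent.  Width = embed_dim * k,
  independent of the leaf count — the practical choice for forests.

An optional *leaf shrinking* mode uses the James-Stein-shrunk leaf values as
the regression targets instead of the raw leaf means; it changes only the
targets, never the leaf-index geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .trees import DecisionTree, Forest

__all__ = [
    "LeafEmbedding",
    "EmbeddingTrainConfig",
    "leaf_onehot",
    "group_trees",
    "leaf_targets",
    "fit_leaf_embedding",
    "encode",
]


def _tree_list(model: DecisionTree | Forest) -> list[DecisionTree]:
    return [model] if isinstance(model, DecisionTree) else model.trees


def leaf_onehot(model: DecisionTree | Forest, X) -> sparse.csr_matrix:
    """Sparse one-hot leaf encoding; column blocks ordered by tree index."""
    trees = _tree_list(model)
    leaf_idx = np.column_stack([t.apply(X) for t in trees])
    n = leaf_idx.shape[0]
    widths = [t.n_leaves for t in trees]
    offsets = np.concatenate([[0], np.cumsum(widths)])
    cols = (leaf_idx + offsets[:-1][None, :]).ravel()
    rows = np.repeat(np.arange(n), len(trees))
    data = np.ones(cols.size)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(n, int(offsets[-1]))
    )


def group_trees(n_trees: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Random partition of ``n_trees`` trees into ``k`` near-equal groups.

    Group sizes differ by at most one; deterministic given the seed.
    """
    if not 1 <= k <= n_trees:
        raise ValueError(f"k must lie in [1, n_trees={n_trees}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trees)
    return [np.sort(g) for g in np.array_split(perm, k)]


def leaf_targets(model: DecisionTree | Forest, X, shrunk: bool = True) -> np.ndarray:
    """Per-tree leaf predictions p_t(X), shape (n, n_trees).

    With ``shrunk`` the targets are the James-Stein-shrunk leaf values (the
    trees' actual predictions); otherwise the raw local leaf means.
    """
    trees = _tree_list(model)
    cols = []
    for t in trees:
        if shrunk:
            cols.append(t.predict(X))
        else:
            means = np.array([s.local_mean for s in t.leaves()])
            cols.append(means[t.apply(X)])
    return np.column_stack(cols)


@dataclass
class EmbeddingTrainConfig:
    embed_dim: int = 4
    n_groups: int = 8
    epochs: int = 200
    lr: float = 1e-2
    batch_size: int = 64
    seed: int = 0
    shrunk_targets: bool = True


@dataclass
class LeafEmbedding:
    """A fitted leaf-to-dense mapping (or the trivial one-hot mapping)."""

    mode: str                                  # "onehot" | "dense"
    n_trees: int
    leaf_counts: list[int]                     # leaves per tree
    groups: list[np.ndarray] = field(default_factory=list)
    tables: list[np.ndarray] = field(default_factory=list)   # per group
    head_w: list[np.ndarray] = field(default_factory=list)   # per group
    head_b: list[float] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)
    embed_dim: int = 0

    @property
    def width(self) -> int:
        if self.mode == "onehot":
            return int(sum(self.leaf_counts))
        return self.embed_dim * len(self.groups)

    def to_dict(self) -> dict:
        return {
            "kind": "embedding",
            "mode": self.mode,
            "n_trees": self.n_trees,
            "leaf_counts": list(self.leaf_counts),
            "embed_dim": self.embed_dim,
            "groups": [g.tolist() for g in self.groups],
            "tables": [t.tolist() for t in self.tables],
            "head_w": [w.tolist() for w in self.head_w],
            "head_b": list(self.head_b),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LeafEmbedding":
        return cls(
            mode=d["mode"],
            n_trees=int(d["n_trees"]),
            leaf_counts=[int(c) for c in d["leaf_counts"]],
            groups=[np.asarray(g, dtype=int) for g in d["groups"]],
            tables=[np.asarray(t, dtype=float) for t in d["tables"]],
            head_w=[np.asarray(w, dtype=float) for w in d["head_w"]],
            head_b=[float(b) for b in d["head_b"]],
            embed_dim=int(d["embed_dim"]),
        )


def onehot_embedding(model: DecisionTree | Forest) -> LeafEmbedding:
    """The trivial one-hot embedding for a fitted tree or forest."""
    trees = _tree_list(model)
    return LeafEmbedding(
        mode="onehot",
        n_trees=len(trees),
        leaf_counts=[t.n_leaves for t in trees],
    )


def fit_leaf_embedding(
    leaf_indices: np.ndarray,
    leaf_targets_matrix: np.ndarray,
    leaf_counts: list[int],
    config: EmbeddingTrainConfig | None = None,
) -> LeafEmbedding:
    """Learn dense per-group leaf embedding tables with a linear head.

    ``leaf_indices`` is the (n, n_trees) output of ``apply``;
    ``leaf_targets_matrix`` holds the per-tree leaf predictions p_t(X).  Trees
    are partitioned into ``config.n_groups`` random groups; within each group
    the model  sum_t table[leaf_t(x)] . w + b  is trained by mini-batch
    gradient descent against the group-summed targets (squared error).
    """
    cfg = config or EmbeddingTrainConfig()
    L = np.atleast_2d(np.asarray(leaf_indices, dtype=int))
    P = np.atleast_2d(np.asarray(leaf_targets_matrix, dtype=float))
    if not np.all(np.isfinite(P)):
        raise ValueError("leaf targets must be finite")
    if L.shape != P.shape:
        raise ValueError("leaf_indices and targets must have equal shapes")
    n, n_trees = L.shape
    if len(leaf_counts) != n_trees:
        raise ValueError("leaf_counts length must equal the number of trees")

    groups = group_trees(n_trees, cfg.n_groups, seed=cfg.seed)
    offsets = np.concatenate([[0], np.cumsum(leaf_counts)])
    rng = np.random.default_rng(cfg.seed + 1)

    emb = LeafEmbedding(
        mode="dense",
        n_trees=n_trees,
        leaf_counts=list(leaf_counts),
        groups=groups,
        embed_dim=cfg.embed_dim,
    )
    # per-group flattened leaf index (n,): position of each reached leaf in
    # the group's concatenated leaf table
    flat_by_group = []
    for g in groups:
        g_offsets = np.concatenate([[0], np.cumsum([leaf_counts[t] for t in g])])
        flat = L[:, g] + g_offsets[:-1][None, :]
        flat_by_group.append(flat)
        total_leaves = int(g_offsets[-1])
        emb.tables.append(rng.normal(0.0, 0.1, size=(total_leaves, cfg.embed_dim)))
        emb.head_w.append(rng.normal(0.0, 0.1, size=cfg.embed_dim))
        emb.head_b.append(0.0)

    targets = [P[:, g].sum(axis=1) for g in groups]
    batch = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            for gi in range(len(groups)):
                flat = flat_by_group[gi][idx]            # (b, |g|)
                table = emb.tables[gi]
                e = table[flat].sum(axis=1)              # (b, embed_dim)
                pred = e @ emb.head_w[gi] + emb.head_b[gi]
                err = pred - targets[gi][idx]
                epoch_loss += float(np.mean(err * err))
                ge = (2.0 * err / err.size)[:, None] * emb.head_w[gi][None, :]
                np.add.at(
                    table,
                    flat.ravel(),
                    np.repeat(ge, flat.shape[1], axis=0) * cfg.lr * -1.0,
                )
                emb.head_w[gi] -= cfg.lr * (e.T @ (2.0 * err / err.size))
                emb.head_b[gi] -= cfg.lr * float(np.sum(2.0 * err / err.size))
        emb.loss_history.append(epoch_loss)
    return emb


def encode(
    embedding: LeafEmbedding, model: DecisionTree | Forest, X
) -> np.ndarray:
    """Design matrix X_E for the teacher (dense array in either mode)."""
    trees = _tree_list(model)
    if len(trees) != embedding.n_trees or [
        t.n_leaves for t in trees
    ] != embedding.leaf_counts:
        raise ValueError(
            "embedding schema does not match the given model "
            "(tree count or leaf counts differ from fit time)"
        )
    if embedding.mode == "onehot":
        return np.asarray(leaf_onehot(model, X).todense())
    L = np.column_stack([t.apply(X) for t in trees])
    blocks = []
    for gi, g in enumerate(embedding.groups):
        g_offsets = np.concatenate(
            [[0], np.cumsum([embedding.leaf_counts[t] for t in g])]
        )
        flat = L[:, g] + g_offsets[:-1][None, :]
        blocks.append(embedding.tables[gi][flat].sum(axis=1))
    return np.concatenate(blocks, axis=1)
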