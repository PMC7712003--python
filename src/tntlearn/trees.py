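"""Hard regression trees with James-Stein leaf shrinkage.

This module implements three related estimators:

* a plain CART regression tree (squared-error splits, leaf means),
* the James-Stein Decision Tree (JSDT): identical greedy construction, but
  once the provisional tree has at least four leaves, split scoring and leaf
  prediction use positive-part James-Stein shrinkage of the leaf means toward
  the global leaf mean, and
* the James-Stein Decision Forest (JSDF): a bagged ensemble of JSDTs with
  optional per-split feature subsampling.

The James-Stein estimator of m >= 4 Gaussian group means dominates the
per-group average in total squared error; applied to tree leaves it borrows
strength across leaves and damps the over-fit local means of small leaves.
For unknown, unequal leaf variances the positive-part variant is used:

    mu_i = GM + (1 - lambda * gamma)_+ * (ybar_i - GM)

with GM the mean of leaf means, gamma = (m - 3) / sum_i (n_i / s2_i)
(ybar_i - GM)^2, and lambda a scale parameter (lambda = 0 disables shrinkage
and recovers CART exactly).

Missing feature values are handled natively: during split scoring the
missing-valued samples of a node are sent, as a block, to whichever child
yields the lower split loss; at prediction time a sample missing the split
feature follows the majority direction of the training samples at that node.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SplitSpec",
    "LeafStats",
    "TreeConfig",
    "ForestConfig",
    "DecisionTree",
    "Forest",
    "leaf_value_mle",
    "js_estimate",
    "js_shrink_leaves",
    "best_split",
    "fit_cart",
    "fit_jsdt",
    "fit_forest",
    "predict",
    "apply",
]

_VARIANCE_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """A candidate or chosen split: feature index, threshold, two-child loss."""

    feature_index: int
    threshold: float
    loss: float


@dataclass
class LeafStats:
    """Per-leaf statistics: local mean, member count, variance, shrunk value."""

    local_mean: float
    count: int
    variance: float
    shrunk_value: float


@dataclass
class TreeConfig:
    """Construction settings for a single tree.

    ``shrink_lambda = 0`` disables James-Stein shrinkage (plain CART);
    the paper-tuned default for single six-layer trees is 25.
    """

    depth_limit: int = 6
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    shrink_lambda: float = 0.0
    variance_floor: float = _VARIANCE_FLOOR


@dataclass
class ForestConfig:
    """Bagged-ensemble settings: 80 sub-trees of depth <= 9 by default."""

    n_trees: int = 80
    depth_limit: int = 9
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    shrink_lambda: float = 25.0
    variance_floor: float = _VARIANCE_FLOOR
    bootstrap: bool = True
    feature_subsample: float = 1.0
    seed: int = 0

    def tree_config(self) -> TreeConfig:
        return TreeConfig(
            depth_limit=self.depth_limit,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            shrink_lambda=self.shrink_lambda,
            variance_floor=self.variance_floor,
        )


class _Node:
    __slots__ = (
        "feature", "threshold", "loss", "missing_left", "left", "right",
        "stats", "leaf_index",
    )

    def __init__(self) -> None:
        self.feature: int | None = None
        self.threshold: float = 0.0
        self.loss: float = 0.0
        self.missing_left: bool = True
        self.left: "_Node | None" = None
        self.right: "_Node | None" = None
        self.stats: LeafStats | None = None
        self.leaf_index: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class DecisionTree:
    """A fitted binary regression tree (CART or JSDT)."""

    root: _Node
    config: TreeConfig
    n_features: int
    n_leaves: int
    depth: int

    # -- inference ----------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.n_features)
        out = np.empty(X.shape[0])
        _route(self.root, X, np.arange(X.shape[0]), out, value=True)
        return out

    def apply(self, X) -> np.ndarray:
        X = _as_matrix(X, self.n_features)
        out = np.empty(X.shape[0], dtype=np.int64)
        _route(self.root, X, np.arange(X.shape[0]), out, value=False)
        return out

    def leaves(self) -> list[LeafStats]:
        """Leaf statistics in depth-first, left-first order."""
        acc: list[LeafStats] = []
        _collect_leaves(self.root, acc)
        return acc

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "tree",
            "n_features": self.n_features,
            "n_leaves": self.n_leaves,
            "depth": self.depth,
            "config": {
                "depth_limit": self.config.depth_limit,
                "min_samples_split": self.config.min_samples_split,
                "min_samples_leaf": self.config.min_samples_leaf,
                "shrink_lambda": self.config.shrink_lambda,
                "variance_floor": self.config.variance_floor,
            },
            "root": _node_to_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        cfg = TreeConfig(**d["config"])
        root = _node_from_dict(d["root"])
        return cls(
            root=root,
            config=cfg,
            n_features=int(d["n_features"]),
            n_leaves=int(d["n_leaves"]),
            depth=int(d["depth"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "DecisionTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Forest:
    """An ordered bag of JSDTs; predictions are the simple tree average."""

    trees: list[DecisionTree]
    config: ForestConfig
    n_features: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.n_features)
        acc = np.zeros(X.shape[0])
        for t in self.trees:
            acc += t.predict(X)
        return acc / len(self.trees)

    def apply(self, X) -> np.ndarray:
        """Leaf-index matrix with one column per tree."""
        X = _as_matrix(X, self.n_features)
        return np.column_stack([t.apply(X) for t in self.trees])

    def to_dict(self) -> dict:
        return {
            "kind": "forest",
            "n_features": self.n_features,
            "config": {
                "n_trees": self.config.n_trees,
                "depth_limit": self.config.depth_limit,
                "min_samples_split": self.config.min_samples_split,
                "min_samples_leaf": self.config.min_samples_leaf,
                "shrink_lambda": self.config.shrink_lambda,
                "variance_floor": self.config.variance_floor,
                "bootstrap": self.config.bootstrap,
                "feature_subsample": self.config.feature_subsample,
                "seed": self.config.seed,
            },
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Forest":
        cfg = ForestConfig(**d["config"])
        trees = [DecisionTree.from_dict(td) for td in d["trees"]]
        return cls(trees=trees, config=cfg, n_features=int(d["n_features"]))


# ---------------------------------------------------------------------------
# Leaf estimators
# ---------------------------------------------------------------------------

def leaf_value_mle(targets: Sequence[float]) -> float:
    """Maximum-likelihood leaf value: the simple average of member targets."""
    t = np.asarray(targets, dtype=float)
    if t.size == 0:
        raise ValueError("cannot compute a leaf value from an empty target list")
    return float(t.mean())


def js_estimate(
    group_means,
    prior_point,
    noise_variance: float,
    m: int | None = None,
) -> np.ndarray:
    """Positive-part James-Stein estimate of ``m >= 4`` Gaussian means.

    Shrinks the observed means ``ybar`` toward the fixed prior point ``nu``:

        mu_hat = nu + max(0, 1 - (m - 3) * sigma^2 / ||ybar - nu||^2)
                 * (ybar - nu)

    Degenerate contracts: ``sigma^2 = 0`` returns ``ybar`` unchanged and
    ``ybar == nu`` returns ``nu``.
    """
    ybar = np.asarray(group_means, dtype=float)
    nu = np.asarray(prior_point, dtype=float)
    if nu.shape != ybar.shape:
        raise ValueError("group_means and prior_point must have equal shape")
    if m is None:
        m = ybar.shape[0]
    if m != ybar.shape[0]:
        raise ValueError(f"m={m} does not match vector length {ybar.shape[0]}")
    if m < 4:
        raise ValueError(
            f"the James-Stein estimator requires m >= 4 dimensions, got m={m}"
        )
    if noise_variance < 0:
        raise ValueError("noise_variance must be non-negative")
    diff = ybar - nu
    norm2 = float(diff @ diff)
    if norm2 == 0.0:
        return nu.copy()
    factor = 1.0 - (m - 3) * noise_variance / norm2
    if factor >= 1.0:
        return ybar.copy()
    if factor < 0.0:
        factor = 0.0
    return nu + factor * diff


def js_shrink_leaves(
    leaves: Iterable[LeafStats] | tuple,
    shrink_lambda: float,
    variance_floor: float = _VARIANCE_FLOOR,
) -> np.ndarray:
    """Positive-part JS shrinkage of leaf means toward the global leaf mean.

    Accepts a list of :class:`LeafStats` (or a ``(means, counts, variances)``
    array triple) of length m >= 4 and returns the shrunk leaf values

        GM + (1 - lambda * gamma)_+ * (ybar_i - GM),

    gamma = (m - 3) / sum_i (n_i / s2_i) (ybar_i - GM)^2.  Leaves with a
    single member have no sample variance; they receive the pooled variance of
    the remaining leaves, and every variance is floored at ``variance_floor``.
    When every local mean equals GM (gamma undefined) or the shrink factor is
    exactly 1 the local means are returned unchanged, bit for bit.
    """
    if isinstance(leaves, tuple) and len(leaves) == 3:
        means, counts, variances = (np.asarray(a, dtype=float) for a in leaves)
    else:
        ls = list(leaves)
        means = np.array([l.local_mean for l in ls], dtype=float)
        counts = np.array([l.count for l in ls], dtype=float)
        variances = np.array([l.variance for l in ls], dtype=float)
    m = means.shape[0]
    if m < 4:
        raise ValueError(f"James-Stein leaf shrinkage requires m >= 4 leaves, got {m}")
    if shrink_lambda == 0.0:
        return means.copy()
    var = _fill_pooled_variance(counts, variances, variance_floor)
    gm = means.mean()
    dev = means - gm
    denom = float(np.sum(counts / var * dev * dev))
    if denom == 0.0:
        return means.copy()
    gamma = (m - 3) / denom
    factor = 1.0 - shrink_lambda * gamma
    if factor >= 1.0:
        return means.copy()
    if factor < 0.0:
        factor = 0.0
    return gm + factor * dev


def _fill_pooled_variance(counts, variances, floor) -> np.ndarray:
    """Replace undefined variances by the pooled estimate of the other leaves.

    A variance is undefined when it is non-finite, or when a single-member
    leaf reports no sample variance (zero); a caller-supplied positive
    variance is honored even at count 1.  Every variance is floored.
    """
    var = np.array(variances, dtype=float)
    undefined = ~np.isfinite(var) | ((np.asarray(counts) < 2) & (var <= 0.0))
    defined = ~undefined & (np.asarray(counts) >= 2)
    den = float(np.sum(counts[defined] - 1.0))
    if den > 0:
        pooled = float(np.sum((counts[defined] - 1.0) * var[defined])) / den
    else:
        pooled = floor
    pooled = max(pooled, floor)
    var[undefined] = pooled
    return np.maximum(var, floor)


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

@dataclass
class _OtherLeaves:
    """Fixed statistics of the provisional tree's leaves other than the node
    being split (means, counts, raw variances with NaN where undefined)."""

    means: np.ndarray
    counts: np.ndarray
    variances: np.ndarray  # NaN where count < 2

    @classmethod
    def empty(cls) -> "_OtherLeaves":
        z = np.zeros(0)
        return cls(z, z, z)

    @property
    def m(self) -> int:
        return self.means.shape[0]


@dataclass
class _BestSplit:
    spec: SplitSpec
    missing_to_left: bool


def best_split(
    X,
    y,
    candidate_features: Sequence[int] | None = None,
    config: TreeConfig | None = None,
    m_temp: int = 1,
    other_leaves: _OtherLeaves | None = None,
) -> SplitSpec | None:
    """Exhaustive search for the squared-error-minimizing (feature, threshold).

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each feature.  Child representative values are simple averages
    when the provisional tree has ``m_temp <= 3`` leaves (or shrinkage is
    disabled) and JS-shrunk values over the hypothetical leaf set otherwise.
    Ties are broken toward the lowest feature index, then the lowest
    threshold.  Returns ``None`` when no feature admits a valid split.
    """
    found = _find_best_split(
        np.asarray(X, dtype=float).reshape(len(y), -1),
        np.asarray(y, dtype=float),
        candidate_features,
        config or TreeConfig(),
        m_temp,
        other_leaves or _OtherLeaves.empty(),
    )
    return found.spec if found is not None else None


def _find_best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidate_features: Sequence[int] | None,
    cfg: TreeConfig,
    m_temp: int,
    other: _OtherLeaves,
) -> _BestSplit | None:
    n, d = X.shape
    if n < 2:
        return None
    feats = range(d) if candidate_features is None else sorted(candidate_features)
    use_js = cfg.shrink_lambda > 0 and m_temp >= 4

    best: _BestSplit | None = None
    for a in feats:
        col = X[:, a]
        miss = np.isnan(col)
        xs = col[~miss]
        if xs.size < 2:
            continue
        order = np.argsort(xs, kind="stable")
        xs_sorted = xs[order]
        ys_sorted = y[~miss][order]
        # threshold between positions k-1 and k where the value changes
        change = np.nonzero(np.diff(xs_sorted) > 0)[0]
        if change.size == 0:
            continue
        kk = change + 1                       # left block sizes
        thresholds = 0.5 * (xs_sorted[change] + xs_sorted[kk])

        c1 = np.cumsum(ys_sorted)
        c2 = np.cumsum(ys_sorted * ys_sorted)
        tot1, tot2 = c1[-1], c2[-1]
        nL0 = kk.astype(float)
        sumL0 = c1[change]
        sqL0 = c2[change]
        nR0 = xs.size - nL0
        sumR0 = tot1 - sumL0
        sqR0 = tot2 - sqL0

        ym = y[miss]
        nm = float(ym.size)
        sm1 = float(ym.sum())
        sm2 = float((ym * ym).sum())

        variants = [(True, nm, sm1, sm2)] if nm > 0 else [(True, 0.0, 0.0, 0.0)]
        if nm > 0:
            variants.append((False, nm, sm1, sm2))

        loss_by_dir = []
        for to_left, vnm, vs1, vs2 in variants:
            if to_left:
                nL, sumL, sqL = nL0 + vnm, sumL0 + vs1, sqL0 + vs2
                nR, sumR, sqR = nR0, sumR0, sqR0
            else:
                nL, sumL, sqL = nL0, sumL0, sqL0
                nR, sumR, sqR = nR0 + vnm, sumR0 + vs1, sqR0 + vs2
            loss = _score_children(
                nL, sumL, sqL, nR, sumR, sqR, other, cfg, m_temp, use_js
            )
            bad = (nL < cfg.min_samples_leaf) | (nR < cfg.min_samples_leaf)
            loss = np.where(bad, np.inf, loss)
            loss_by_dir.append(loss)

        if len(loss_by_dir) == 2:
            to_left_arr = loss_by_dir[0] <= loss_by_dir[1]
            loss = np.where(to_left_arr, loss_by_dir[0], loss_by_dir[1])
        else:
            to_left_arr = np.ones(thresholds.shape, dtype=bool)
            loss = loss_by_dir[0]

        k = int(np.argmin(loss))
        if not np.isfinite(loss[k]):
            continue
        # tolerance-based tie-break: different (feature, threshold) pairs can
        # induce the same partition, whose losses agree only up to rounding;
        # prefer the lowest feature index, then the lowest threshold
        if best is None or loss[k] < best.spec.loss - _loss_tol(best.spec.loss):
            best = _BestSplit(
                SplitSpec(int(a), float(thresholds[k]), float(loss[k])),
                bool(to_left_arr[k]),
            )
    return best


def _loss_tol(loss: float) -> float:
    return 1e-9 * (1.0 + abs(loss))


def _score_children(nL, sumL, sqL, nR, sumR, sqR, other, cfg, m_temp, use_js):
    """Vectorized two-child loss over candidate thresholds.

    The loss is the sum of squared errors of both children around their
    representative values (plain means, or JS-shrunk means of the hypothetical
    leaf set when shrinkage is active).
    """
    meanL = sumL / nL
    meanR = sumR / nR
    if not use_js:
        cL, cR = meanL, meanR
    else:
        floor = cfg.variance_floor
        ssL = np.maximum(sqL - sumL * meanL, 0.0)
        ssR = np.maximum(sqR - sumR * meanR, 0.0)
        withL = nL >= 2
        withR = nR >= 2
        varL_raw = np.where(withL, ssL / np.maximum(nL - 1.0, 1.0), np.nan)
        varR_raw = np.where(withR, ssR / np.maximum(nR - 1.0, 1.0), np.nan)

        o_def = other.counts >= 2
        pooled_num = (
            float(np.sum((other.counts[o_def] - 1.0) * other.variances[o_def]))
            + np.where(withL, ssL, 0.0)
            + np.where(withR, ssR, 0.0)
        )
        pooled_den = (
            float(np.sum(other.counts[o_def] - 1.0))
            + np.where(withL, nL - 1.0, 0.0)
            + np.where(withR, nR - 1.0, 0.0)
        )
        pooled = np.where(pooled_den > 0, pooled_num / np.maximum(pooled_den, 1.0), floor)
        pooled = np.maximum(pooled, floor)

        varL = np.maximum(np.where(withL, varL_raw, pooled), floor)
        varR = np.maximum(np.where(withR, varR_raw, pooled), floor)

        m_new = other.m + 2
        gm = (other.means.sum() + meanL + meanR) / m_new
        devL = meanL - gm
        devR = meanR - gm
        denom = nL / varL * devL * devL + nR / varR * devR * devR
        if other.m:
            var_o = np.where(
                np.isnan(other.variances)[:, None],
                pooled[None, :],
                np.maximum(other.variances, floor)[:, None],
            )
            dev_o = other.means[:, None] - gm[None, :]
            denom = denom + np.sum(other.counts[:, None] / var_o * dev_o * dev_o, axis=0)
        with np.errstate(divide="ignore"):
            gamma = np.where(denom > 0, (m_new - 3) / np.maximum(denom, 1e-300), np.inf)
        factor = np.clip(1.0 - cfg.shrink_lambda * gamma, 0.0, 1.0)
        factor = np.where(denom > 0, factor, 1.0)
        cL = np.where(factor == 1.0, meanL, gm + factor * devL)
        cR = np.where(factor == 1.0, meanR, gm + factor * devR)
    lossL = sqL - 2.0 * cL * sumL + nL * cL * cL
    lossR = sqR - 2.0 * cR * sumR + nR * cR * cR
    return np.maximum(lossL + lossR, 0.0)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def fit_cart(X, y, config: TreeConfig | None = None) -> DecisionTree:
    """Greedy CART regression tree: squared-error splits, leaf means."""
    cfg = config or TreeConfig()
    cfg = TreeConfig(**{**cfg.__dict__, "shrink_lambda": 0.0})
    return _build_tree(X, y, cfg)


def fit_jsdt(X, y, config: TreeConfig | None = None) -> DecisionTree:
    """James-Stein Decision Tree.

    Identical to CART until the provisional tree has four leaves; from then
    on split scoring uses JS-shrunk child values over the full hypothetical
    leaf set, and the final leaf predictions are the JS-shrunk values of the
    completed tree.  ``shrink_lambda = 0`` reduces exactly to CART.
    """
    cfg = config or TreeConfig(shrink_lambda=25.0)
    return _build_tree(X, y, cfg)


def _build_tree(
    X,
    y,
    cfg: TreeConfig,
    rng: np.random.Generator | None = None,
    feature_fraction: float = 1.0,
) -> DecisionTree:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n == 0:
        raise ValueError("cannot fit a tree on an empty dataset")
    if y.shape[0] != n:
        raise ValueError("X and y have different lengths")

    root = _Node()
    root.stats = _node_stats(y)
    # registry of current leaves of the provisional tree: node -> stats
    registry: dict[_Node, LeafStats] = {root: root.stats}
    queue: deque[tuple[_Node, np.ndarray, int]] = deque([(root, np.arange(n), 0)])
    depth_seen = 0

    while queue:
        node, idx, depth = queue.popleft()
        depth_seen = max(depth_seen, depth)
        ynode = y[idx]
        if (
            depth >= cfg.depth_limit
            or idx.size < cfg.min_samples_split
            or np.ptp(ynode) == 0.0
        ):
            continue
        if feature_fraction < 1.0 and rng is not None:
            k = max(1, int(np.ceil(feature_fraction * d)))
            feats = np.sort(rng.choice(d, size=k, replace=False))
        else:
            feats = None
        other = _other_leaves(registry, node)
        found = _find_best_split(X[idx], ynode, feats, cfg, len(registry), other)
        if found is None:
            continue
        node.feature = found.spec.feature_index
        node.threshold = found.spec.threshold
        node.loss = found.spec.loss

        col = X[idx, node.feature]
        miss = np.isnan(col)
        go_left = col <= node.threshold
        go_left = np.where(miss, found.missing_to_left, go_left)
        li = idx[go_left]
        ri = idx[~go_left]
        node.missing_left = bool(li.size >= ri.size)  # majority direction
        node.stats = None

        left, right = _Node(), _Node()
        left.stats = _node_stats(y[li])
        right.stats = _node_stats(y[ri])
        node.left, node.right = left, right
        del registry[node]
        registry[left] = left.stats
        registry[right] = right.stats
        queue.append((left, li, depth + 1))
        queue.append((right, ri, depth + 1))

    leaves: list[LeafStats] = []
    _collect_leaves(root, leaves, assign_index=True)
    if cfg.shrink_lambda > 0 and len(leaves) >= 4:
        shrunk = js_shrink_leaves(leaves, cfg.shrink_lambda, cfg.variance_floor)
        for leaf, v in zip(leaves, shrunk):
            leaf.shrunk_value = float(v)
    return DecisionTree(
        root=root,
        config=cfg,
        n_features=d,
        n_leaves=len(leaves),
        depth=_tree_depth(root),
    )


def _node_stats(yv: np.ndarray) -> LeafStats:
    mean = float(yv.mean())
    var = float(yv.var(ddof=1)) if yv.size >= 2 else 0.0
    return LeafStats(
        local_mean=mean, count=int(yv.size), variance=var, shrunk_value=mean
    )


def _other_leaves(registry: dict, node: _Node) -> _OtherLeaves:
    others = [s for k, s in registry.items() if k is not node]
    if not others:
        return _OtherLeaves.empty()
    means = np.array([s.local_mean for s in others])
    counts = np.array([float(s.count) for s in others])
    variances = np.array(
        [s.variance if s.count >= 2 else np.nan for s in others]
    )
    return _OtherLeaves(means, counts, variances)


def _collect_leaves(node: _Node, acc: list, assign_index: bool = False) -> None:
    if node.is_leaf:
        if assign_index:
            node.leaf_index = len(acc)
        acc.append(node.stats)
        return
    _collect_leaves(node.left, acc, assign_index)
    _collect_leaves(node.right, acc, assign_index)


def _tree_depth(node: _Node) -> int:
    if node.is_leaf:
        return 0
    return 1 + max(_tree_depth(node.left), _tree_depth(node.right))


def _route(node: _Node, X, idx, out, value: bool) -> None:
    if node.is_leaf:
        out[idx] = node.stats.shrunk_value if value else node.leaf_index
        return
    col = X[idx, node.feature]
    miss = np.isnan(col)
    go_left = np.where(miss, node.missing_left, col <= node.threshold)
    _route(node.left, X, idx[go_left], out, value)
    _route(node.right, X, idx[~go_left], out, value)


# ---------------------------------------------------------------------------
# Forest
# ---------------------------------------------------------------------------

def fit_forest(X, y, config: ForestConfig | None = None) -> Forest:
    """James-Stein Decision Forest: bagged JSDTs, deterministic given a seed."""
    cfg = config or ForestConfig()
    if cfg.n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trees)
    trees = []
    tcfg = cfg.tree_config()
    for s in seeds:
        rng = np.random.default_rng(s)
        idx = rng.integers(0, n, size=n) if cfg.bootstrap else np.arange(n)
        trees.append(
            _build_tree(
                X[idx], y[idx], tcfg, rng=rng,
                feature_fraction=cfg.feature_subsample,
            )
        )
    return Forest(trees=trees, config=cfg, n_features=X.shape[1])


# ---------------------------------------------------------------------------
# Model-agnostic helpers
# ---------------------------------------------------------------------------

def predict(model: DecisionTree | Forest, X) -> np.ndarray:
    """Predict with a fitted tree or forest (forests average their trees)."""
    return model.predict(X)


def apply(model: DecisionTree | Forest, X) -> np.ndarray:
    """Leaf indices reached by each sample; forests give one column per tree.

    Leaves are numbered depth-first, left-child-first, starting at 0, so
    indices are stable across calls and serialization round-trips.
    """
    out = model.apply(X)
    if isinstance(model, DecisionTree):
        return out
    return out


def _as_matrix(X, n_features: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :] if X.shape[0] == n_features else X[:, None]
    if X.shape[1] != n_features:
        raise ValueError(
            f"expected {n_features} feature columns, got {X.shape[1]}"
        )
    return X


def _node_to_dict(node: _Node) -> dict:
    if node.is_leaf:
        s = node.stats
        return {
            "leaf": {
                "index": node.leaf_index,
                "local_mean": s.local_mean,
                "count": s.count,
                "variance": s.variance,
                "shrunk_value": s.shrunk_value,
            }
        }
    return {
        "split": {
            "feature_index": node.feature,
            "threshold": node.threshold,
            "loss": node.loss,
            "missing_left": node.missing_left,
        },
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> _Node:
    node = _Node()
    if "leaf" in d:
        leaf = d["leaf"]
        node.leaf_index = int(leaf["index"])
        node.stats = LeafStats(
            local_mean=float(leaf["local_mean"]),
            count=int(leaf["count"]),
            variance=float(leaf["variance"]),
            shrunk_value=float(leaf["shrunk_value"]),
        )
        return node
    sp = d["split"]
    node.feature = int(sp["feature_index"])
    node.threshold = float(sp["threshold"])
    node.loss = float(sp["loss"])
    node.missing_left = bool(sp["missing_left"])
    node.left = _node_from_dict(d["left"])
    node.right = _node_from_dict(d["right"])
    return node
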