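"""Differentiable complete-binary soft decision trees.

Every internal node ``i`` of a depth-``D`` complete binary tree carries a
linear sigmoid gate

    g_i(x) = sigmoid(beta * (w_i . x + b_i))

giving the probability of routing left; a sample therefore reaches leaf ``l``
with probability ``P_l(x)``, the product of the gate probabilities along the
root-to-leaf path (the ``P_l`` always sum to 1).  The tree output is the
path-probability-weighted sum of leaf values — a scalar for regression, or a
softmax leaf distribution for classification — which makes the whole model
differentiable in its gate weights and leaf parameters.

Nodes are stored in heap order: internal nodes are 0 .. 2^D - 2 with children
``2i + 1`` and ``2i + 2``; leaves occupy slots 2^D - 1 .. 2^(D+1) - 2, so leaf
``l`` (numbered left to right) is node ``2^D - 1 + l``.

Gradients are computed analytically with a two-sweep scheme: a top-down pass
accumulates the reach probabilities ``U`` of every node, a bottom-up pass
accumulates the soft subtree values ``S``; then d(out)/d(gate activation) =
U_i * (S_left - S_right) * g_i (1 - g_i) * beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoftTreeParams",
    "init_soft_tree",
    "gate",
    "path_probs",
    "sdt_forward",
    "sdt_forward_backward",
    "sdt_classification_forward",
    "sdt_distill_loss_classification",
    "sdt_classification_backward",
    "extract_path",
]


@dataclass
class SoftTreeParams:
    """Parameters of one complete-binary soft decision tree."""

    depth: int
    gate_weights: np.ndarray       # (n_internal, d)
    gate_bias: np.ndarray          # (n_internal,)
    leaf_values: np.ndarray        # (n_leaf,) regression, (n_leaf, K) logits
    inverse_temp: float = 1.0

    @property
    def n_internal(self) -> int:
        return 2**self.depth - 1

    @property
    def n_leaves(self) -> int:
        return 2**self.depth

    @property
    def n_features(self) -> int:
        return self.gate_weights.shape[1]

    def copy(self) -> "SoftTreeParams":
        return SoftTreeParams(
            depth=self.depth,
            gate_weights=self.gate_weights.copy(),
            gate_bias=self.gate_bias.copy(),
            leaf_values=self.leaf_values.copy(),
            inverse_temp=self.inverse_temp,
        )

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "gate_weights": self.gate_weights.tolist(),
            "gate_bias": self.gate_bias.tolist(),
            "leaf_values": self.leaf_values.tolist(),
            "inverse_temp": self.inverse_temp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SoftTreeParams":
        return cls(
            depth=int(d["depth"]),
            gate_weights=np.asarray(d["gate_weights"], dtype=float),
            gate_bias=np.asarray(d["gate_bias"], dtype=float),
            leaf_values=np.asarray(d["leaf_values"], dtype=float),
            inverse_temp=float(d["inverse_temp"]),
        )


def init_soft_tree(
    depth: int,
    n_features: int,
    seed: int = 0,
    leaf_init: float | np.ndarray = 0.0,
    n_classes: int | None = None,
    inverse_temp: float = 1.0,
    weight_scale: float = 0.01,
) -> SoftTreeParams:
    """Small-random gate weights, zero biases, leaf values at ``leaf_init``."""
    rng = np.random.default_rng(seed)
    n_internal = 2**depth - 1
    n_leaf = 2**depth
    W = rng.normal(0.0, weight_scale, size=(n_internal, n_features))
    b = np.zeros(n_internal)
    if n_classes is None:
        leaves = np.full(n_leaf, float(np.mean(leaf_init)))
    else:
        leaves = np.zeros((n_leaf, n_classes)) + np.asarray(leaf_init, dtype=float)
    return SoftTreeParams(depth, W, b, leaves, inverse_temp=inverse_temp)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _gates(params: SoftTreeParams, X: np.ndarray) -> np.ndarray:
    z = params.inverse_temp * (X @ params.gate_weights.T + params.gate_bias)
    return _sigmoid(z)


def gate(params: SoftTreeParams, x, node_id: int) -> float:
    """Left-routing probability ``P(L | x)`` of internal node ``node_id``."""
    if not 0 <= node_id < params.n_internal:
        raise ValueError(
            f"node {node_id} is not an internal node "
            f"(valid range 0..{params.n_internal - 1})"
        )
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return float(_gates(params, x)[0, node_id])


def _reach(params: SoftTreeParams, G: np.ndarray) -> np.ndarray:
    """Reach probabilities U for all 2^(D+1) - 1 nodes; U[:, 0] = 1."""
    n = G.shape[0]
    total = 2 ** (params.depth + 1) - 1
    U = np.ones((n, total))
    for i in range(params.n_internal):
        U[:, 2 * i + 1] = U[:, i] * G[:, i]
        U[:, 2 * i + 2] = U[:, i] * (1.0 - G[:, i])
    return U


def path_probs(params: SoftTreeParams, x) -> np.ndarray:
    """Leaf path-probability vector(s); rows sum to 1."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    G = _gates(params, X)
    P = _reach(params, G)[:, params.n_internal:]
    return P[0] if np.asarray(x).ndim == 1 else P


def _subtree_values(params: SoftTreeParams, G: np.ndarray, leaf_vals: np.ndarray):
    """Soft subtree values S for every node; S[:, 0] is the tree output.

    ``leaf_vals`` may be (n_leaf,) shared leaf scalars or (n, n_leaf)
    per-sample leaf quantities (used by the classification loss).
    """
    n = G.shape[0]
    total = 2 ** (params.depth + 1) - 1
    S = np.zeros((n, total))
    S[:, params.n_internal:] = leaf_vals
    for i in range(params.n_internal - 1, -1, -1):
        S[:, i] = G[:, i] * S[:, 2 * i + 1] + (1.0 - G[:, i]) * S[:, 2 * i + 2]
    return S


def sdt_forward(params: SoftTreeParams, x) -> np.ndarray | float:
    """Tree output: sum_l P_l(x) * leaf_value_l (regression leaves)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    G = _gates(params, X)
    S = _subtree_values(params, G, params.leaf_values[None, :])
    out = S[:, 0]
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def sdt_forward_backward(
    params: SoftTreeParams, X: np.ndarray, grad_out: np.ndarray
):
    """Forward pass plus gradients of ``sum_n grad_out[n] * out[n]``.

    Returns ``(out, dW, db, dleaf, dX)``; ``dX`` supports chaining the tree
    behind upstream differentiable stages.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = _gates(params, X)
    U = _reach(params, G)
    S = _subtree_values(params, G, params.leaf_values[None, :])
    out = S[:, 0]

    ni = params.n_internal
    # d out / d g_i = U_i * (S_left - S_right); chain through the sigmoid
    dS = S[:, 1 : 2 * ni : 2] - S[:, 2 : 2 * ni + 1 : 2]  # (n, ni)
    dz = grad_out[:, None] * U[:, :ni] * dS * G[:, :ni] * (1.0 - G[:, :ni])
    dz = dz * params.inverse_temp
    dW = dz.T @ X
    db = dz.sum(axis=0)
    dleaf = U[:, ni:].T @ grad_out
    dX = dz @ params.gate_weights
    return out, dW, db, dleaf, dX


# ---------------------------------------------------------------------------
# Classification head
# ---------------------------------------------------------------------------

def _leaf_distributions(params: SoftTreeParams) -> np.ndarray:
    z = params.leaf_values
    z = z - z.max(axis=1, keepdims=True)
    q = np.exp(z)
    return q / q.sum(axis=1, keepdims=True)


def sdt_classification_forward(params: SoftTreeParams, x) -> np.ndarray:
    """Class distribution: sum_l P_l(x) * Q^l."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    P = np.atleast_2d(path_probs(params, X))
    Q = _leaf_distributions(params)
    out = P @ Q
    return out[0] if np.asarray(x).ndim == 1 else out


def sdt_distill_loss_classification(
    params: SoftTreeParams, x, target_distribution
) -> float:
    """Leaf-weighted expected cross-entropy distillation objective.

    L(x) = -sum_l P_l(x) sum_k T_k log Q_k^l, averaged over the batch.  The
    target ``T`` (the teacher's softened distribution) must be a probability
    vector per sample.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    T = np.atleast_2d(np.asarray(target_distribution, dtype=float))
    if T.shape[0] == 1 and X.shape[0] > 1:
        T = np.repeat(T, X.shape[0], axis=0)
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("target_distribution rows must be probability vectors")
    G = _gates(params, X)
    P = _reach(params, G)[:, params.n_internal:]
    Q = np.clip(_leaf_distributions(params), 1e-12, None)
    # per-sample, per-leaf cross-entropy c_l = -sum_k T_k log Q^l_k
    C = -(T @ np.log(Q).T)
    return float(np.mean(np.sum(P * C, axis=1)))


def sdt_classification_backward(params: SoftTreeParams, X, T):
    """Gradients of the mean distillation cross-entropy w.r.t. all params."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    n = X.shape[0]
    G = _gates(params, X)
    U = _reach(params, G)
    Q = np.clip(_leaf_distributions(params), 1e-12, None)
    C = -(T @ np.log(Q).T)                     # (n, n_leaf)
    S = _subtree_values(params, G, C)          # soft values with leaf "values" C
    loss = float(np.mean(S[:, 0]))

    ni = params.n_internal
    g_up = np.full(n, 1.0 / n)
    dS = S[:, 1 : 2 * ni : 2] - S[:, 2 : 2 * ni + 1 : 2]
    dz = g_up[:, None] * U[:, :ni] * dS * G[:, :ni] * (1.0 - G[:, :ni])
    dz = dz * params.inverse_temp
    dW = dz.T @ X
    db = dz.sum(axis=0)
    # d loss / d leaf logit z^l_k = mean_n P_nl (Q_lk - T_nk)
    P = U[:, ni:]
    PT = P * g_up[:, None]
    dZ = (PT.sum(axis=0)[:, None] * Q) - (PT.T @ T)
    return loss, dW, db, dZ


# ---------------------------------------------------------------------------
# Interpretability surface
# ---------------------------------------------------------------------------

def extract_path(
    params: SoftTreeParams, x, top_features: int = 3
) -> dict:
    """Maximum-probability root-to-leaf decision path for one sample.

    Returns the reached leaf, its path probability (the max of the leaf
    path-probability vector), and per-gate records: the gate probability and
    the ``top_features`` input features with the largest absolute gate weight.
    """
    x = np.asarray(x, dtype=float).ravel()
    P = path_probs(params, x)
    leaf = int(np.argmax(P))
    node = params.n_internal + leaf
    # walk back up to the root to recover the path
    rev = []
    while node > 0:
        parent = (node - 1) // 2
        rev.append((parent, node == 2 * parent + 1))
        node = parent
    G = _gates(params, x[None, :])[0]
    steps = []
    for node_id, went_left in reversed(rev):
        w = params.gate_weights[node_id]
        top = np.argsort(-np.abs(w))[:top_features]
        steps.append(
            {
                "node": int(node_id),
                "direction": "left" if went_left else "right",
                "gate_probability": float(G[node_id] if went_left else 1 - G[node_id]),
                "top_features": [
                    {"feature": int(j), "weight": float(w[j])} for j in top
                ],
            }
        )
    return {
        "leaf": leaf,
        "path_probability": float(P[leaf]),
        "leaf_value": np.asarray(params.leaf_values[leaf]).tolist(),
        "steps": steps,
    }
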