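"""Soft decision tree: gating, path probabilities, outputs, gradients."""

import numpy as np
import pytest
from scipy.special import logit

from tntlearn import (
    extract_path,
    gate,
    init_soft_tree,
    path_probs,
    sdt_classification_backward,
    sdt_distill_loss_classification,
    sdt_forward,
    sdt_forward_backward,
)


def depth2_worked_tree():
    """Gates 0.8 / 0.6 / 0.3, scalar leaves (1, 2, 3, 4)."""
    p = init_soft_tree(2, 3, seed=0)
    p.gate_weights[:] = 0.0
    p.gate_bias[:] = logit([0.8, 0.6, 0.3])
    p.leaf_values = np.array([1.0, 2.0, 3.0, 4.0])
    return p


def central_difference_check(arrays_and_grads, f, tol):
    eps = 1e-6
    worst = 0.0
    for arr, grad in arrays_and_grads:
        it = np.nditer(np.asarray(arr), flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            fp = f()
            arr[i] = orig - eps
            fm = f()
            arr[i] = orig
            worst = max(worst, abs((fp - fm) / (2 * eps) - grad[i]))
    assert worst < tol, f"max gradient discrepancy {worst}"


# ---------------------------------------------------------------------------
# Gating and path probabilities
# ---------------------------------------------------------------------------

def test_gate_is_symmetric_at_zero_activation():
    p = init_soft_tree(2, 3, seed=0)
    p.gate_weights[:] = 0.0
    assert gate(p, np.ones(3), 0) == pytest.approx(0.5)


def test_gate_sharpens_toward_one_with_inverse_temperature():
    p = init_soft_tree(1, 1, seed=0)
    p.gate_weights[:] = 1.0
    p.inverse_temp = 1e4
    assert gate(p, np.array([1.0]), 0) == pytest.approx(1.0, abs=1e-12)


def test_gate_closed_form_value():
    p = init_soft_tree(1, 1, seed=0)
    p.gate_weights[0, 0] = float(np.log(3.0))
    assert gate(p, np.array([1.0]), 0) == pytest.approx(0.75)


def test_gate_rejects_leaf_node_ids():
    p = init_soft_tree(2, 3, seed=0)
    with pytest.raises(ValueError):
        gate(p, np.zeros(3), p.n_internal)


def test_path_probs_depth_one_symmetric():
    p = init_soft_tree(1, 2, seed=0)
    p.gate_weights[:] = 0.0
    assert path_probs(p, np.zeros(2)) == pytest.approx([0.5, 0.5])


def test_path_probs_hand_product():
    P = path_probs(depth2_worked_tree(), np.zeros(3))
    assert P == pytest.approx([0.48, 0.32, 0.06, 0.14])


def test_path_probs_normalize_over_random_instances(rng):
    for _ in range(1000):
        depth = int(rng.integers(1, 5))
        d = int(rng.integers(1, 6))
        p = init_soft_tree(depth, d, seed=int(rng.integers(1 << 30)), weight_scale=1.0)
        P = path_probs(p, rng.normal(size=d))
        assert P.min() >= 0.0
        assert abs(P.sum() - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def test_forward_constant_leaves_give_constant_output(rng):
    p = init_soft_tree(3, 4, seed=1, weight_scale=1.0)
    p.leaf_values[:] = 2.75
    assert sdt_forward(p, rng.normal(size=4)) == pytest.approx(2.75)


def test_forward_hand_weighted_sum():
    assert sdt_forward(depth2_worked_tree(), np.zeros(3)) == pytest.approx(1.86)


def test_forward_approaches_hard_tree_limit(rng):
    p = init_soft_tree(2, 3, seed=4, weight_scale=1.0)
    p.leaf_values = np.array([1.0, 2.0, 3.0, 4.0])
    x = rng.normal(size=3)
    # hard routing by thresholding each gate at 0.5
    node = 0
    for _ in range(p.depth):
        go_left = (x @ p.gate_weights[node] + p.gate_bias[node]) > 0
        node = 2 * node + 1 if go_left else 2 * node + 2
    hard_value = p.leaf_values[node - p.n_internal]
    p.inverse_temp = 1e4
    assert sdt_forward(p, x) == pytest.approx(hard_value, abs=1e-6)


def test_forward_gradients_match_central_differences(rng):
    p = init_soft_tree(3, 4, seed=2, weight_scale=0.5)
    p.leaf_values = rng.normal(size=8)
    X = rng.normal(size=(6, 4))
    g = rng.normal(size=6)
    _, dW, db, dleaf, _ = sdt_forward_backward(p, X, g)
    central_difference_check(
        [(p.gate_weights, dW), (p.gate_bias, db), (p.leaf_values, dleaf)],
        lambda: float(np.sum(g * sdt_forward(p, X))),
        tol=1e-5,
    )


# ---------------------------------------------------------------------------
# Classification distillation loss
# ---------------------------------------------------------------------------

def test_classification_loss_uniform_targets_equals_log_k():
    K = 3
    p = init_soft_tree(2, 2, seed=3, n_classes=K)
    T = np.full((2, K), 1.0 / K)
    assert sdt_distill_loss_classification(p, np.zeros((2, 2)), T) == pytest.approx(
        np.log(K)
    )


def test_classification_loss_minimized_at_perfect_agreement():
    K = 2
    p = init_soft_tree(2, 2, seed=3, n_classes=K)
    T = np.array([[1.0, 0.0]])
    x = np.zeros((1, 2))
    # every leaf concentrated on the target class (interior-clipped)
    p.leaf_values = np.tile([20.0, -20.0], (4, 1))
    best = sdt_distill_loss_classification(p, x, T)
    p.leaf_values = np.tile([-20.0, 20.0], (4, 1))
    worst = sdt_distill_loss_classification(p, x, T)
    assert best < 1e-6 < worst


def test_classification_loss_rejects_unnormalized_targets():
    p = init_soft_tree(2, 2, seed=0, n_classes=2)
    with pytest.raises(ValueError):
        sdt_distill_loss_classification(p, np.zeros((1, 2)), np.array([[0.7, 0.7]]))


def test_classification_gradients_match_central_differences(rng):
    K = 3
    p = init_soft_tree(2, 3, seed=5, n_classes=K, weight_scale=0.5)
    p.leaf_values = rng.normal(size=(4, K))
    X = rng.normal(size=(5, 3))
    T = rng.dirichlet(np.ones(K), size=5)
    loss, dW, db, dZ = sdt_classification_backward(p, X, T)
    assert loss == pytest.approx(sdt_distill_loss_classification(p, X, T))
    central_difference_check(
        [(p.gate_weights, dW), (p.gate_bias, db), (p.leaf_values, dZ)],
        lambda: sdt_distill_loss_classification(p, X, T),
        tol=1e-5,
    )


def test_classification_loss_decreases_under_gradient_descent(rng):
    p = init_soft_tree(2, 2, seed=6, n_classes=2, weight_scale=0.5)
    X = rng.normal(size=(16, 2))
    T = np.where(X[:, :1] > 0, [[0.9, 0.1]], [[0.2, 0.8]])
    first = sdt_distill_loss_classification(p, X, T)
    for _ in range(50):
        _, dW, db, dZ = sdt_classification_backward(p, X, T)
        p.gate_weights -= 0.5 * dW
        p.gate_bias -= 0.5 * db
        p.leaf_values -= 0.5 * dZ
    assert sdt_distill_loss_classification(p, X, T) < first


# ---------------------------------------------------------------------------
# Decision paths
# ---------------------------------------------------------------------------

def test_extract_path_all_left_when_gates_above_half():
    p = init_soft_tree(2, 2, seed=0)
    p.gate_weights[:] = 0.0
    p.gate_bias[:] = 2.0  # every gate > 0.5
    report = extract_path(p, np.zeros(2))
    assert report["leaf"] == 0
    assert [s["direction"] for s in report["steps"]] == ["left", "left"]


def test_extract_path_probability_is_max_of_path_probs(rng):
    p = init_soft_tree(3, 4, seed=7, weight_scale=1.0)
    x = rng.normal(size=4)
    report = extract_path(p, x)
    assert report["path_probability"] == pytest.approx(path_probs(p, x).max())


def test_extract_path_worked_case_reaches_leaf_zero():
    report = extract_path(depth2_worked_tree(), np.zeros(3))
    assert report["leaf"] == 0
    assert report["path_probability"] == pytest.approx(0.48)
    assert len(report["steps"]) == 2
    assert len(report["steps"][0]["top_features"]) == 3
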