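"""Distillable gradient-boosted soft decision trees (dGBDT).

An ensemble of ``M`` soft decision trees trained *simultaneously* on
mini-batches.  For each tree ``m`` the cumulative prediction of its
predecessors, ``s_{m-1} = sum_{j<m} o_j``, is evaluated, and the tree is fit
to the residual of the distillation loss

    dl(s, alpha, y, t) = alpha T^2 ||s - t||^2 + (1 - alpha) ||s - y||^2

where ``y`` is the ground truth and ``t`` the teacher's soft label.  The raw
residual is the negative gradient r = -d dl/ds = -[2 alpha T^2 (s - t) +
2 (1 - alpha) (s - y)].  Because dl is quadratic in ``s`` with curvature
2 (alpha T^2 + 1 - alpha), each tree's fitting target is the
curvature-normalized residual

    r / (2 (alpha T^2 + 1 - alpha)) = s* - s_{m-1},

i.e. a Newton step toward the per-sample loss minimizer
s* = [alpha T^2 t + (1 - alpha) y] / [alpha T^2 + 1 - alpha].  At alpha = 0
this is exactly the classical squared-loss boosting residual ``y - s``, and
the ensemble is the ground-truth-driven soft gradient boosting machine
(exposed as :func:`sgbm_baseline`).

All trees take one SGD step per mini-batch on the global loss
L = sum_m ||r_m - o_m||^2 with the residual targets held constant
(stop-gradient through earlier trees), which is the boosting semantics of the
simultaneous training scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .soft_tree import SoftTreeParams, init_soft_tree, sdt_forward, sdt_forward_backward

__all__ = [
    "DistillConfig",
    "BoostEnsemble",
    "distill_loss",
    "residual",
    "train_dgbdt",
    "dgbdt_predict",
    "sgbm_baseline",
]


@dataclass
class DistillConfig:
    """Distillation and optimization hyperparameters for dGBDT training.

    ``alpha`` trades the teacher-matching term against the ground-truth term
    (alpha = 0 ignores the teacher entirely); ``temperature`` scales the
    teacher term by T^2.  ``shrinkage`` multiplies the (Newton-normalized)
    residual targets, playing the role of the usual boosting learning rate on
    top of the per-step SGD learning rate ``lr``.
    """

    alpha: float = 0.9
    temperature: float = 1.0
    n_trees: int = 5
    depth: int = 4
    lr: float = 1e-2
    momentum: float = 0.9
    gate_decay: float = 0.0
    gate_l1: float = 0.0
    epochs: int = 100
    batch_size: int = 32
    shrinkage: float = 1.0
    inverse_temp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")


@dataclass
class BoostEnsemble:
    """M soft trees plus their training log and optimizer state."""

    members: list[SoftTreeParams]
    config: DistillConfig
    loss_history: list[dict] = field(default_factory=list)  # epoch, L, per-tree l_m
    fitted: bool = False
    _velocity: list | None = None

    @property
    def n_trees(self) -> int:
        return len(self.members)

    def predict(self, X) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("ensemble is not fitted; call train_dgbdt first")
        return dgbdt_predict(self, X, _check=False)

    def to_dict(self) -> dict:
        return {
            "kind": "dgbdt",
            "fitted": self.fitted,
            "config": {
                "alpha": self.config.alpha,
                "temperature": self.config.temperature,
                "n_trees": self.config.n_trees,
                "depth": self.config.depth,
                "lr": self.config.lr,
                "momentum": self.config.momentum,
                "gate_decay": self.config.gate_decay,
                "gate_l1": self.config.gate_l1,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "shrinkage": self.config.shrinkage,
                "inverse_temp": self.config.inverse_temp,
                "seed": self.config.seed,
            },
            "members": [m.to_dict() for m in self.members],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostEnsemble":
        cfg = DistillConfig(**d["config"])
        members = [SoftTreeParams.from_dict(md) for md in d["members"]]
        return cls(members=members, config=cfg, fitted=bool(d["fitted"]))

    def loss_curve_frame(self):
        """Training log as a DataFrame (epoch, L, l_1 .. l_M)."""
        import pandas as pd

        return pd.DataFrame(self.loss_history)


# ---------------------------------------------------------------------------
# Loss and residual
# ---------------------------------------------------------------------------

def distill_loss(s, y, t, alpha: float, T: float):
    """dl(s) = alpha T^2 (s - t)^2 + (1 - alpha) (s - y)^2, element-wise.

    Scalars in give a scalar out; arrays give the per-sample loss vector.
    """
    _check_alpha_T(alpha, T)
    s, y, t = (np.asarray(v, dtype=float) for v in (s, y, t))
    out = alpha * T * T * (s - t) ** 2 + (1.0 - alpha) * (s - y) ** 2
    return float(out) if out.ndim == 0 else out


def residual(s, y, t, alpha: float, T: float):
    """Negative gradient of the distillation loss with respect to ``s``:

    r = -[2 alpha T^2 (s - t) + 2 (1 - alpha) (s - y)].
    """
    _check_alpha_T(alpha, T)
    s, y, t = (np.asarray(v, dtype=float) for v in (s, y, t))
    out = -(2.0 * alpha * T * T * (s - t) + 2.0 * (1.0 - alpha) * (s - y))
    return float(out) if out.ndim == 0 else out


def _check_alpha_T(alpha: float, T: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")


def _newton_target(s, y, t, alpha: float, T: float) -> np.ndarray:
    """Curvature-normalized residual target s* - s (see module docstring)."""
    curv = alpha * T * T + (1.0 - alpha)
    return (alpha * T * T * (t - s) + (1.0 - alpha) * (y - s)) / curv


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def init_ensemble(n_features: int, config: DistillConfig, y_mean: float = 0.0) -> BoostEnsemble:
    """M soft trees; the first is seeded at y_mean so s_1 starts near the data."""
    members = []
    for m in range(config.n_trees):
        leaf_init = y_mean if m == 0 else 0.0
        members.append(
            init_soft_tree(
                config.depth,
                n_features,
                seed=config.seed + m,
                leaf_init=leaf_init,
                inverse_temp=config.inverse_temp,
            )
        )
    return BoostEnsemble(members=members, config=config)


def train_dgbdt(
    X,
    y,
    t,
    config: DistillConfig | None = None,
    ensemble: BoostEnsemble | None = None,
) -> BoostEnsemble:
    """Train a dGBDT on features ``X``, labels ``y`` and soft labels ``t``.

    Mini-batch loop of Algorithm style: per batch, evaluate every tree,
    form each tree's residual target from the cumulative output of its
    predecessors (held constant), and take one SGD step on the summed
    per-tree squared losses.  Deterministic given ``config.seed``.
    """
    cfg = config or DistillConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if not (len(y) == len(t) == X.shape[0]):
        raise ValueError("X, y and t must have equal lengths")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
        raise ValueError("train_dgbdt requires finite X, y and t")

    ens = ensemble or init_ensemble(X.shape[1], cfg, y_mean=float(y.mean()))
    if len(ens.members) != cfg.n_trees:
        raise ValueError("ensemble size does not match config.n_trees")
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    batch = min(cfg.batch_size, n)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_L = 0.0
        epoch_lm = np.zeros(cfg.n_trees)
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            Xb, yb, tb = X[idx], y[idx], t[idx]
            L, lm = _batch_step(ens, Xb, yb, tb, cfg)
            epoch_L += L
            epoch_lm += lm
            n_batches += 1
        rec = {"epoch": epoch, "L": epoch_L / n_batches}
        for m in range(cfg.n_trees):
            rec[f"l_{m + 1}"] = epoch_lm[m] / n_batches
        ens.loss_history.append(rec)
        if not np.isfinite(rec["L"]):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: L={rec['L']}"
            )
    ens.fitted = True
    return ens


def _batch_step(ens: BoostEnsemble, Xb, yb, tb, cfg: DistillConfig):
    """One simultaneous SGD step over all trees on one mini-batch."""
    b = Xb.shape[0]
    outputs = []
    grads = []
    s_prev = np.zeros(b)
    L = 0.0
    lm_record = np.zeros(len(ens.members))
    for m, tree in enumerate(ens.members):
        r_m = cfg.shrinkage * _newton_target(s_prev, yb, tb, cfg.alpha, cfg.temperature)
        # forward with gradient of l_m = mean((r_m - o_m)^2) w.r.t. tree m only
        o_m = sdt_forward(tree, Xb)
        g_out = 2.0 * (o_m - r_m) / b
        _, dW, db, dleaf, _ = sdt_forward_backward(tree, Xb, g_out)
        if cfg.gate_decay > 0:
            dW = dW + 2.0 * cfg.gate_decay * tree.gate_weights
        l_m = float(np.mean((r_m - o_m) ** 2))
        L += l_m
        lm_record[m] = l_m
        outputs.append(o_m)
        grads.append((dW, db, dleaf))
        s_prev = s_prev + o_m
    if ens._velocity is None:
        ens._velocity = [
            [np.zeros_like(g) for g in triple] for triple in grads
        ]
    for tree, (dW, db, dleaf), vel in zip(ens.members, grads, ens._velocity):
        for v, g in zip(vel, (dW, db, dleaf)):
            v *= cfg.momentum
            v += g
        tree.gate_weights -= cfg.lr * vel[0]
        tree.gate_bias -= cfg.lr * vel[1]
        tree.leaf_values -= cfg.lr * vel[2]
        if cfg.gate_l1 > 0:
            # proximal soft-threshold: exact zeros for uninformative gates
            w = tree.gate_weights
            np.copyto(w, np.sign(w) * np.maximum(np.abs(w) - cfg.lr * cfg.gate_l1, 0.0))
    return L, lm_record


def dgbdt_predict(ensemble: BoostEnsemble, X, _check: bool = True) -> np.ndarray:
    """Cumulative ensemble output sum_m o_m(x)."""
    if _check and not ensemble.fitted:
        raise RuntimeError("ensemble is not fitted; call train_dgbdt first")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.zeros(X.shape[0])
    for tree in ensemble.members:
        out += sdt_forward(tree, X)
    return out


def sgbm_baseline(
    X, y, config: DistillConfig | None = None, ensemble: BoostEnsemble | None = None
) -> BoostEnsemble:
    """Ground-truth-driven soft gradient boosting: dGBDT with alpha = 0.

    Identical code path to :func:`train_dgbdt`; exposed under its own name for
    ablations against the distilled student.
    """
    cfg = config or DistillConfig()
    cfg = DistillConfig(**{**cfg.__dict__, "alpha": 0.0})
    y = np.asarray(y, dtype=float).ravel()
    return train_dgbdt(X, y, np.zeros_like(y), cfg, ensemble=ensemble)
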