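"""The network stage: an MLP teacher trained on tree leaf embeddings.

The teacher is a plain fully connected network — ReLU hidden layers (default
widths 32-16-16-8-8) and a single linear output unit — trained by mini-batch
SGD on squared error.  The tasks handled here are regression or binary risk
probability regression on [0, 1], so no classification head is needed; when a
probability is required at metric time, callers may squash the output, but
the training target is the raw label.

After training the teacher provides:

* ``soft_labels`` — its predictions, cached as the distillation targets ``t``
  for the student stage, and
* ``feature_layer`` — the post-activation values of a chosen hidden layer,
  used as student input in the feature-distillation pipeline variant.

The implementation carries its own analytic backward pass, including the
gradient with respect to the input, so that it can sit in the middle of a
fully differentiable chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TeacherConfig", "TeacherModel", "train_teacher", "soft_labels", "feature_layer"]

_DEFAULT_HIDDEN = (32, 16, 16, 8, 8)


@dataclass
class TeacherConfig:
    """MLP teacher settings; ``weight_decay`` is the L2 penalty coefficient
    on the weights (not biases), the main guard against memorizing noisy
    labels on small tabular data."""

    hidden: tuple[int, ...] = _DEFAULT_HIDDEN
    epochs: int = 200
    lr: float = 1e-2
    batch_size: int = 32
    weight_decay: float = 0.015
    seed: int = 0


class MLP:
    """Fully connected ReLU network with one linear output unit.

    He-normal initialization; forward/backward passes are plain numpy.  The
    backward pass returns parameter gradients and the input gradient for a
    given upstream gradient on the (flattened) output.
    """

    def __init__(self, n_inputs: int, hidden: tuple[int, ...], seed: int = 0):
        sizes = [n_inputs, *hidden, 1]
        rng = np.random.default_rng(seed)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.sizes = sizes

    @property
    def n_hidden_layers(self) -> int:
        return len(self.W) - 1

    def forward(self, X: np.ndarray, keep: bool = False):
        """Output (n,); with ``keep`` also the per-layer activations."""
        A = [np.atleast_2d(np.asarray(X, dtype=float))]
        h = A[0]
        for i in range(len(self.W) - 1):
            h = np.maximum(h @ self.W[i] + self.b[i], 0.0)
            A.append(h)
        out = (h @ self.W[-1] + self.b[-1]).ravel()
        return (out, A) if keep else out

    def backward(self, A: list[np.ndarray], grad_out: np.ndarray):
        """Gradients of sum_n grad_out[n] * out[n] w.r.t. params and input."""
        g = np.asarray(grad_out, dtype=float)[:, None]
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        dW[-1] = A[-1].T @ g
        db[-1] = g.sum(axis=0)
        gh = g @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            gh = gh * (A[i + 1] > 0.0)
            dW[i] = A[i].T @ gh
            db[i] = gh.sum(axis=0)
            gh = gh @ self.W[i].T
        return dW, db, gh

    def sgd_step(self, dW, db, lr: float) -> None:
        for i in range(len(self.W)):
            self.W[i] -= lr * dW[i]
            self.b[i] -= lr * db[i]

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        sizes = list(d["sizes"])
        net = cls.__new__(cls)
        net.sizes = sizes
        net.W = [np.asarray(w, dtype=float) for w in d["W"]]
        net.b = [np.asarray(b, dtype=float) for b in d["b"]]
        return net


@dataclass
class TeacherModel:
    """A trained MLP teacher plus its training log."""

    net: MLP
    config: TeacherConfig
    loss_history: list[float] = field(default_factory=list)
    fitted: bool = False

    def predict(self, X) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("teacher is not fitted; call train_teacher first")
        return self.net.forward(X)

    def to_dict(self) -> dict:
        return {
            "kind": "teacher",
            "fitted": self.fitted,
            "config": {
                "hidden": list(self.config.hidden),
                "epochs": self.config.epochs,
                "lr": self.config.lr,
                "batch_size": self.config.batch_size,
                "weight_decay": self.config.weight_decay,
                "seed": self.config.seed,
            },
            "net": self.net.to_dict(),
            "loss_history": self.loss_history,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TeacherModel":
        cfg = d["config"]
        config = TeacherConfig(
            hidden=tuple(cfg["hidden"]),
            epochs=int(cfg["epochs"]),
            lr=float(cfg["lr"]),
            batch_size=int(cfg["batch_size"]),
            weight_decay=float(cfg.get("weight_decay", 0.015)),
            seed=int(cfg["seed"]),
        )
        return cls(
            net=MLP.from_dict(d["net"]),
            config=config,
            loss_history=list(d["loss_history"]),
            fitted=bool(d["fitted"]),
        )


def train_teacher(X_E, y, config: TeacherConfig | None = None) -> TeacherModel:
    """Train the MLP teacher on embedded inputs by mini-batch SGD on MSE.

    Deterministic given ``config.seed`` (initialization and batch order both
    derive from it).  Raises on non-finite inputs.
    """
    cfg = config or TeacherConfig()
    X = np.atleast_2d(np.asarray(X_E, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X_E and y have different lengths")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("train_teacher requires finite inputs and targets")

    net = MLP(X.shape[1], cfg.hidden, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    n = X.shape[0]
    batch = min(cfg.batch_size, n)
    model = TeacherModel(net=net, config=cfg)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            out, A = net.forward(X[idx], keep=True)
            err = out - y[idx]
            epoch_loss += float(np.mean(err * err))
            n_batches += 1
            dW, db, _ = net.backward(A, 2.0 * err / err.size)
            if cfg.weight_decay > 0:
                for i in range(len(net.W)):
                    dW[i] = dW[i] + 2.0 * cfg.weight_decay * net.W[i]
            net.sgd_step(dW, db, cfg.lr)
        model.loss_history.append(epoch_loss / n_batches)
    model.fitted = True
    return model


def soft_labels(teacher: TeacherModel, X) -> np.ndarray:
    """Teacher outputs on ``X`` — the distillation targets ``t``.

    A pure function of (teacher, X): repeated calls are bit-identical.
    """
    return teacher.predict(X)


def feature_layer(teacher: TeacherModel, X, layer_index: int) -> np.ndarray:
    """Post-activation values of hidden layer ``layer_index`` (0-based)."""
    if not teacher.fitted:
        raise RuntimeError("teacher is not fitted; call train_teacher first")
    n_hidden = teacher.net.n_hidden_layers
    if not 0 <= layer_index < n_hidden:
        raise ValueError(
            f"layer_index {layer_index} out of range for {n_hidden} hidden layers"
        )
    _, A = teacher.net.forward(X, keep=True)
    return A[layer_index + 1]
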