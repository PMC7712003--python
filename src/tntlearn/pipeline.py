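"""Tree-Network-Tree orchestration, evaluation, and the robustness protocol.

The default TNT pipeline runs three stages on a tabular dataset (X, y):

1. **T** — fit a hard tree model (CART / JSDT / JSDF forest) and encode every
   sample by the leaves it reaches (one-hot, or grouped dense embedding);
2. **N** — train an MLP teacher on the embedded inputs and generate soft
   labels t;
3. **T** — train a distillable gradient-boosted soft-tree student on
   {X, y, t} with the distillation loss; the student is the deployed,
   interpretable predictor.

Two variants are provided: *TNT-Fs* replaces the student's input X by a
selected hidden feature layer of the teacher, and *dTNT* replaces the hard
front tree by soft trees with linear connector layers between stages, making
the whole chain differentiable end to end (stage-wise warm start, then joint
fine-tuning of the distillation objective).

Missing feature cells (NaN) are routed natively by the hard trees; the
differentiable stages (teacher on raw features, student) receive
mean-imputed values, with the training-column means stored on the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .dgbdt import (
    BoostEnsemble,
    DistillConfig,
    dgbdt_predict,
    sgbm_baseline,
    train_dgbdt,
)
from .embedding import (
    EmbeddingTrainConfig,
    LeafEmbedding,
    encode,
    fit_leaf_embedding,
    leaf_targets,
    onehot_embedding,
)
from .soft_tree import SoftTreeParams, init_soft_tree, sdt_forward, sdt_forward_backward
from .synth import inject_missing, make_clinical_like
from .teacher import MLP, TeacherConfig, TeacherModel, feature_layer, soft_labels, train_teacher
from .trees import DecisionTree, Forest, ForestConfig, TreeConfig, fit_cart, fit_forest, fit_jsdt

__all__ = [
    "TNTConfig",
    "TNTModel",
    "run_tnt",
    "run_tnt_fs",
    "run_dtnt",
    "evaluate",
    "robustness_experiment",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TNTConfig:
    """Full pipeline configuration; every stage seed derives from ``seed``."""

    tree_kind: str = "jsdt"                      # cart | jsdt | jsdf
    shrink_lambda: float = 25.0
    tree_depth: int = 6
    forest: ForestConfig = field(default_factory=ForestConfig)
    embedding_mode: str = "onehot"               # onehot | dense
    embedding: EmbeddingTrainConfig = field(default_factory=EmbeddingTrainConfig)
    teacher: TeacherConfig = field(default_factory=TeacherConfig)
    student: DistillConfig = field(default_factory=DistillConfig)
    layer_index: int = 3                         # TNT-Fs feature layer
    dtnt_front_trees: int = 4
    dtnt_front_depth: int = 3
    joint_epochs: int = 30
    joint_lr: float = 1e-2
    seed: int = 0

    def resolve_seeds(self) -> "TNTConfig":
        """Copy with stage seeds derived deterministically from ``seed``."""
        cfg = TNTConfig(**{**self.__dict__})
        cfg.forest = ForestConfig(**{**self.forest.__dict__, "seed": self.seed + 1})
        cfg.embedding = EmbeddingTrainConfig(
            **{**self.embedding.__dict__, "seed": self.seed + 2}
        )
        cfg.teacher = TeacherConfig(**{**self.teacher.__dict__, "seed": self.seed + 3})
        cfg.student = DistillConfig(**{**self.student.__dict__, "seed": self.seed + 4})
        return cfg

    def to_dict(self) -> dict:
        return {
            "tree_kind": self.tree_kind,
            "shrink_lambda": self.shrink_lambda,
            "tree_depth": self.tree_depth,
            "forest": dict(self.forest.__dict__),
            "embedding_mode": self.embedding_mode,
            "embedding": dict(self.embedding.__dict__),
            "teacher": {**self.teacher.__dict__, "hidden": list(self.teacher.hidden)},
            "student": dict(self.student.__dict__),
            "layer_index": self.layer_index,
            "dtnt_front_trees": self.dtnt_front_trees,
            "dtnt_front_depth": self.dtnt_front_depth,
            "joint_epochs": self.joint_epochs,
            "joint_lr": self.joint_lr,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TNTConfig":
        d = dict(d)
        if "forest" in d:
            d["forest"] = ForestConfig(**d["forest"])
        if "embedding" in d:
            d["embedding"] = EmbeddingTrainConfig(**d["embedding"])
        if "teacher" in d:
            t = dict(d["teacher"])
            t["hidden"] = tuple(t.get("hidden", (32, 16, 16, 8, 8)))
            d["teacher"] = TeacherConfig(**t)
        if "student" in d:
            d["student"] = DistillConfig(**d["student"])
        return cls(**d)


# ---------------------------------------------------------------------------
# dTNT chain
# ---------------------------------------------------------------------------

@dataclass
class DTNTChain:
    """Soft-tree front end, linear connectors, and the MLP teacher.

    Produces the soft label t(x) = a * N(C(front(x))) + c where front(x) is
    the vector of front-tree outputs, C a square linear connector
    (identity-initialized), N the teacher network, and (a, c) a scalar affine
    connector toward the student.  Fully differentiable.
    """

    front: list[SoftTreeParams]
    conn_W: np.ndarray
    conn_b: np.ndarray
    net: MLP
    conn2_a: float = 1.0
    conn2_b: float = 0.0

    def front_out(self, X) -> np.ndarray:
        return np.column_stack([sdt_forward(t, X) for t in self.front])

    def soft_label(self, X) -> np.ndarray:
        H = self.front_out(X) @ self.conn_W + self.conn_b
        return self.conn2_a * self.net.forward(H) + self.conn2_b

    def to_dict(self) -> dict:
        return {
            "front": [t.to_dict() for t in self.front],
            "conn_W": self.conn_W.tolist(),
            "conn_b": self.conn_b.tolist(),
            "net": self.net.to_dict(),
            "conn2_a": self.conn2_a,
            "conn2_b": self.conn2_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DTNTChain":
        return cls(
            front=[SoftTreeParams.from_dict(t) for t in d["front"]],
            conn_W=np.asarray(d["conn_W"], dtype=float),
            conn_b=np.asarray(d["conn_b"], dtype=float),
            net=MLP.from_dict(d["net"]),
            conn2_a=float(d["conn2_a"]),
            conn2_b=float(d["conn2_b"]),
        )


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class TNTModel:
    """Assembled pipeline; ``predict`` always goes through the student."""

    variant: str                                 # tnt | tnt_fs | dtnt
    config: TNTConfig
    front: DecisionTree | Forest | None
    embedding: LeafEmbedding | None
    teacher: TeacherModel | None
    student: BoostEnsemble
    chain: DTNTChain | None = None               # dTNT only
    feature_fill: np.ndarray | None = None       # train-column means for NaN
    layer_index: int | None = None               # TNT-Fs only
    stage_logs: dict = field(default_factory=dict)

    def _fill(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_fill is None or not np.any(np.isnan(X)):
            return X
        X = X.copy()
        nan = np.isnan(X)
        X[nan] = np.broadcast_to(self.feature_fill, X.shape)[nan]
        return X

    def student_input(self, X) -> np.ndarray:
        if self.variant == "tnt_fs":
            X_E = encode(self.embedding, self.front, X)
            return feature_layer(self.teacher, X_E, self.layer_index)
        return self._fill(X)

    def predict(self, X) -> np.ndarray:
        return dgbdt_predict(self.student, self.student_input(X))


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _fit_front(X, y, cfg: TNTConfig):
    if cfg.tree_kind == "cart":
        return fit_cart(X, y, TreeConfig(depth_limit=cfg.tree_depth))
    if cfg.tree_kind == "jsdt":
        return fit_jsdt(
            X, y, TreeConfig(depth_limit=cfg.tree_depth, shrink_lambda=cfg.shrink_lambda)
        )
    if cfg.tree_kind == "jsdf":
        return fit_forest(X, y, cfg.forest)
    raise ValueError(f"unknown tree_kind {cfg.tree_kind!r}")


def _fit_embedding(front, X, cfg: TNTConfig) -> LeafEmbedding:
    if cfg.embedding_mode == "onehot":
        return onehot_embedding(front)
    if cfg.embedding_mode == "dense":
        L = front.apply(X) if isinstance(front, Forest) else front.apply(X)[:, None]
        P = leaf_targets(front, X, shrunk=cfg.embedding.shrunk_targets)
        counts = (
            [t.n_leaves for t in front.trees]
            if isinstance(front, Forest)
            else [front.n_leaves]
        )
        return fit_leaf_embedding(np.atleast_2d(L), P, counts, cfg.embedding)
    raise ValueError(f"unknown embedding_mode {cfg.embedding_mode!r}")


def run_tnt(X, y, config: TNTConfig | None = None) -> TNTModel:
    """Fit the default TNT pipeline: hard tree -> embedding -> teacher ->
    soft labels -> distilled soft-tree student on {X, y, t}."""
    cfg = (config or TNTConfig()).resolve_seeds()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()

    front = _fit_front(X, y, cfg)
    emb = _fit_embedding(front, X, cfg)
    X_E = encode(emb, front, X)
    teacher = train_teacher(X_E, y, cfg.teacher)
    t = soft_labels(teacher, X_E)

    fill = np.nanmean(X, axis=0)
    Xs = np.where(np.isnan(X), fill[None, :], X)
    student = train_dgbdt(Xs, y, t, cfg.student)
    return TNTModel(
        variant="tnt",
        config=cfg,
        front=front,
        embedding=emb,
        teacher=teacher,
        student=student,
        feature_fill=fill,
        stage_logs={
            "teacher_loss": teacher.loss_history,
            "student_loss": [r["L"] for r in student.loss_history],
        },
    )


def run_tnt_fs(X, y, config: TNTConfig | None = None) -> TNTModel:
    """TNT with feature-layer distillation: the student consumes a selected
    hidden layer of the teacher instead of the raw features.

    The decision paths of the student are then over learned features, which
    trades some direct interpretability for capacity.
    """
    cfg = (config or TNTConfig()).resolve_seeds()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()

    front = _fit_front(X, y, cfg)
    emb = _fit_embedding(front, X, cfg)
    X_E = encode(emb, front, X)
    teacher = train_teacher(X_E, y, cfg.teacher)
    t = soft_labels(teacher, X_E)
    F_S = feature_layer(teacher, X_E, cfg.layer_index)
    student = train_dgbdt(F_S, y, t, cfg.student)
    return TNTModel(
        variant="tnt_fs",
        config=cfg,
        front=front,
        embedding=emb,
        teacher=teacher,
        student=student,
        layer_index=cfg.layer_index,
        stage_logs={
            "teacher_loss": teacher.loss_history,
            "student_loss": [r["L"] for r in student.loss_history],
        },
    )


def run_dtnt(X, y, config: TNTConfig | None = None) -> TNTModel:
    """Fully differentiable TNT.

    The hard front tree is replaced by soft trees; linear connector layers
    join front -> teacher and teacher -> student.  Stage-wise warm start
    (front soft trees boosted on y, teacher trained on the connector output
    against y, student distilled from the warm teacher), then joint
    fine-tuning: mini-batch gradient descent on the distillation objective
    dl(s(x), alpha, y, t(x)) through every stage simultaneously.
    """
    cfg = (config or TNTConfig()).resolve_seeds()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    fill = np.nanmean(X, axis=0)
    Xs = np.where(np.isnan(X), fill[None, :], X)
    K = cfg.dtnt_front_trees

    # warm start: front soft trees boosted on the ground truth
    front_cfg = DistillConfig(
        alpha=0.0,
        n_trees=K,
        depth=cfg.dtnt_front_depth,
        lr=cfg.student.lr,
        epochs=cfg.student.epochs,
        batch_size=cfg.student.batch_size,
        seed=cfg.seed + 5,
    )
    front_ens = sgbm_baseline(Xs, y, front_cfg)
    chain = DTNTChain(
        front=front_ens.members,
        conn_W=np.eye(K),
        conn_b=np.zeros(K),
        net=MLP(K, cfg.teacher.hidden, seed=cfg.teacher.seed),
    )
    H = chain.front_out(Xs) @ chain.conn_W + chain.conn_b
    warm_teacher = train_teacher(H, y, cfg.teacher)
    chain.net = warm_teacher.net

    t = chain.soft_label(Xs)
    student = train_dgbdt(Xs, y, t, cfg.student)

    joint_log = _joint_finetune(chain, student, Xs, y, cfg)
    model = TNTModel(
        variant="dtnt",
        config=cfg,
        front=None,
        embedding=None,
        teacher=warm_teacher,
        student=student,
        chain=chain,
        feature_fill=fill,
        stage_logs={"joint_loss": joint_log},
    )
    return model


def dtnt_joint_loss(chain: DTNTChain, student: BoostEnsemble, X, y, alpha, T) -> float:
    """The joint distillation objective mean[dl(s(x), alpha, y, t(x))]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    t = chain.soft_label(X)
    s = dgbdt_predict(student, X, _check=False)
    dl = alpha * T * T * (s - t) ** 2 + (1.0 - alpha) * (s - y) ** 2
    return float(np.mean(dl))


def dtnt_joint_grads(chain: DTNTChain, student: BoostEnsemble, X, y, alpha, T):
    """Loss and analytic gradients of the joint objective for every stage."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]

    O = chain.front_out(X)                        # (n, K)
    H = O @ chain.conn_W + chain.conn_b
    u, A = chain.net.forward(H, keep=True)
    t = chain.conn2_a * u + chain.conn2_b
    s = dgbdt_predict(student, X, _check=False)

    dl = alpha * T * T * (s - t) ** 2 + (1.0 - alpha) * (s - y) ** 2
    loss = float(np.mean(dl))
    ds = (2.0 * alpha * T * T * (s - t) + 2.0 * (1.0 - alpha) * (s - y)) / n
    dt = (-2.0 * alpha * T * T * (s - t)) / n

    student_grads = [
        sdt_forward_backward(tree, X, ds)[1:4] for tree in student.members
    ]
    da = float(np.sum(dt * u))
    db2 = float(np.sum(dt))
    du = chain.conn2_a * dt
    dWnet, dbnet, gH = chain.net.backward(A, du)
    dconn_W = O.T @ gH
    dconn_b = gH.sum(axis=0)
    gO = gH @ chain.conn_W.T
    front_grads = [
        sdt_forward_backward(tree, X, gO[:, k])[1:4]
        for k, tree in enumerate(chain.front)
    ]
    return loss, {
        "student": student_grads,
        "front": front_grads,
        "conn_W": dconn_W,
        "conn_b": dconn_b,
        "net_W": dWnet,
        "net_b": dbnet,
        "conn2_a": da,
        "conn2_b": db2,
    }


def _joint_finetune(chain, student, X, y, cfg: TNTConfig) -> list[float]:
    rng = np.random.default_rng(cfg.seed + 6)
    n = X.shape[0]
    batch = min(cfg.student.batch_size, n)
    alpha, T = cfg.student.alpha, cfg.student.temperature
    lr = cfg.joint_lr
    log = []
    for _ in range(cfg.joint_epochs):
        order = rng.permutation(n)
        epoch = 0.0
        nb = 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            loss, g = dtnt_joint_grads(chain, student, X[idx], y[idx], alpha, T)
            epoch += loss
            nb += 1
            for tree, (dW, db, dleaf) in zip(student.members, g["student"]):
                tree.gate_weights -= lr * dW
                tree.gate_bias -= lr * db
                tree.leaf_values -= lr * dleaf
            for tree, (dW, db, dleaf) in zip(chain.front, g["front"]):
                tree.gate_weights -= lr * dW
                tree.gate_bias -= lr * db
                tree.leaf_values -= lr * dleaf
            chain.conn_W -= lr * g["conn_W"]
            chain.conn_b -= lr * g["conn_b"]
            chain.net.sgd_step(g["net_W"], g["net_b"], lr)
            chain.conn2_a -= lr * g["conn2_a"]
            chain.conn2_b -= lr * g["conn2_b"]
        log.append(epoch / nb)
    return log


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(model, X, y, metrics=("auroc", "auprc", "mse")) -> dict:
    """Score a fitted model (or a prediction vector / callable) on (X, y).

    AUROC is the rank statistic with tie averaging; AUPRC the step-wise
    average precision; MSE the plain mean squared error of the raw scores.
    """
    y = np.asarray(y, dtype=float).ravel()
    if hasattr(model, "predict"):
        scores = np.asarray(model.predict(X), dtype=float)
    elif callable(model):
        scores = np.asarray(model(X), dtype=float)
    else:
        scores = np.asarray(model, dtype=float)
    out = {}
    for m in metrics:
        if m in ("auroc", "auprc"):
            if np.unique(y).size < 2:
                raise ValueError(f"{m} is undefined for single-class labels")
            fn = roc_auc_score if m == "auroc" else average_precision_score
            out[m] = float(fn(y, scores))
        elif m == "mse":
            out[m] = float(np.mean((scores - y) ** 2))
        else:
            raise ValueError(f"unknown metric {m!r}")
    return out


# ---------------------------------------------------------------------------
# Robustness protocol
# ---------------------------------------------------------------------------

def _impute(Xtr, Xte):
    fill = np.nanmean(Xtr, axis=0)
    fill = np.where(np.isnan(fill), 0.0, fill)
    f = lambda A: np.where(np.isnan(A), fill[None, :], A)
    return f(Xtr), f(Xte)


def _fit_method(name: str, Xtr, ytr, seed: int, tnt_config: TNTConfig | None):
    """Fit one robustness-protocol method; returns a score function."""
    if name == "cart":
        model = fit_cart(Xtr, ytr, TreeConfig(depth_limit=6))
        return model.predict
    if name == "jsdt":
        model = fit_jsdt(Xtr, ytr, TreeConfig(depth_limit=6, shrink_lambda=25.0))
        return model.predict
    if name == "mlp":
        Xi, _ = _impute(Xtr, Xtr)
        fill = np.nanmean(Xtr, axis=0)
        teacher = train_teacher(Xi, ytr, TeacherConfig(seed=seed))
        return lambda Xte: teacher.predict(np.where(np.isnan(Xte), fill[None, :], Xte))
    if name == "tn":
        front = fit_jsdt(Xtr, ytr, TreeConfig(depth_limit=6, shrink_lambda=25.0))
        emb = onehot_embedding(front)
        teacher = train_teacher(encode(emb, front, Xtr), ytr, TeacherConfig(seed=seed))
        return lambda Xte: teacher.predict(encode(emb, front, Xte))
    if name == "nt":
        Xi, _ = _impute(Xtr, Xtr)
        fill = np.nanmean(Xtr, axis=0)
        teacher = train_teacher(Xi, ytr, TeacherConfig(seed=seed))
        t = soft_labels(teacher, Xi)
        student = train_dgbdt(Xi, ytr, t, DistillConfig(seed=seed))
        return lambda Xte: dgbdt_predict(
            student, np.where(np.isnan(Xte), fill[None, :], Xte)
        )
    if name == "tnt":
        cfg = tnt_config or TNTConfig()
        cfg = TNTConfig(**{**cfg.__dict__, "seed": seed})
        model = run_tnt(Xtr, ytr, cfg)
        return model.predict
    raise ValueError(f"unknown robustness method {name!r}")


def robustness_experiment(
    generator_config: dict | None = None,
    sparsity_levels=(0.0, 0.2, 0.4),
    methods=("cart", "jsdt", "mlp", "tn", "nt", "tnt"),
    n_seeds: int = 5,
    base_seed: int = 0,
    tnt_config: TNTConfig | None = None,
) -> dict:
    """Missing-value robustness protocol on clinical-style synthetic data.

    Per seed: generate a dataset, wipe each sparsity fraction of feature
    cells uniformly at random (train and test alike), fit every method, and
    score AUROC/AUPRC on the held-out quarter.  Returns the per-seed table,
    the seed-mean table, and per-method degradation (metric at sparsity 0
    minus metric at each level).
    """
    gen = {"n": 800, "d": 20, "informative": 6, "effect_size": 1.0, "noise_sd": 0.5}
    gen.update(generator_config or {})
    for level in sparsity_levels:
        if not 0.0 <= level < 1.0:
            raise ValueError(f"sparsity level {level} outside [0, 1)")

    rows = []
    for s in range(n_seeds):
        seed = base_seed + 1000 * s
        data = make_clinical_like(seed=seed, **gen)
        n = data.X.shape[0]
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(n)
        n_test = n // 4
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        for level in sparsity_levels:
            if level > 0:
                Xm, _ = inject_missing(data.X, level, seed=seed + 2)
            else:
                Xm = data.X
            Xtr, ytr = Xm[train_idx], data.y[train_idx]
            Xte, yte = Xm[test_idx], data.y[test_idx]
            for name in methods:
                try:
                    score_fn = _fit_method(name, Xtr, ytr, seed, tnt_config)
                    res = evaluate(score_fn, Xte, yte, metrics=("auroc", "auprc"))
                except Exception as exc:  # keep the table complete per cell
                    raise RuntimeError(
                        f"method {name!r} failed at sparsity {level}, seed {s}"
                    ) from exc
                rows.append(
                    {
                        "seed": s,
                        "method": name,
                        "sparsity": level,
                        "auroc": res["auroc"],
                        "auprc": res["auprc"],
                    }
                )
    per_seed = pd.DataFrame(rows)
    table = (
        per_seed.groupby(["method", "sparsity"])[["auroc", "auprc"]]
        .mean()
        .reset_index()
    )
    base = table[table["sparsity"] == min(sparsity_levels)].set_index("method")
    deg_rows = []
    for _, row in table.iterrows():
        deg_rows.append(
            {
                "method": row["method"],
                "sparsity": row["sparsity"],
                "auroc_degradation": base.loc[row["method"], "auroc"] - row["auroc"],
                "auprc_degradation": base.loc[row["method"], "auprc"] - row["auprc"],
            }
        )
    return {
        "per_seed": per_seed,
        "table": table,
        "degradation": pd.DataFrame(deg_rows),
    }


# ---------------------------------------------------------------------------
# Model bundle I/O
# ---------------------------------------------------------------------------

def save_model(model: TNTModel, out_dir) -> None:
    """Serialize a fitted pipeline as a directory of JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "variant": model.variant,
        "layer_index": model.layer_index,
        "feature_fill": None
        if model.feature_fill is None
        else model.feature_fill.tolist(),
    }
    _dump(out / "meta.json", meta)
    _dump(out / "config.json", model.config.to_dict())
    if model.front is not None:
        _dump(out / "front.json", model.front.to_dict())
    if model.embedding is not None:
        _dump(out / "embedding.json", model.embedding.to_dict())
    if model.teacher is not None:
        _dump(out / "teacher.json", model.teacher.to_dict())
    if model.chain is not None:
        _dump(out / "chain.json", model.chain.to_dict())
    _dump(out / "student.json", model.student.to_dict())


def load_model(model_dir) -> TNTModel:
    src = Path(model_dir)
    meta = _load(src / "meta.json")
    config = TNTConfig.from_dict(_load(src / "config.json"))
    front = None
    if (src / "front.json").exists():
        d = _load(src / "front.json")
        front = Forest.from_dict(d) if d["kind"] == "forest" else DecisionTree.from_dict(d)
    embedding = (
        LeafEmbedding.from_dict(_load(src / "embedding.json"))
        if (src / "embedding.json").exists()
        else None
    )
    teacher = (
        TeacherModel.from_dict(_load(src / "teacher.json"))
        if (src / "teacher.json").exists()
        else None
    )
    chain = (
        DTNTChain.from_dict(_load(src / "chain.json"))
        if (src / "chain.json").exists()
        else None
    )
    student = BoostEnsemble.from_dict(_load(src / "student.json"))
    fill = meta["feature_fill"]
    return TNTModel(
        variant=meta["variant"],
        config=config,
        front=front,
        embedding=embedding,
        teacher=teacher,
        student=student,
        chain=chain,
        feature_fill=None if fill is None else np.asarray(fill, dtype=float),
        layer_index=meta["layer_index"],
    )


def _dump(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True)


def _load(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
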