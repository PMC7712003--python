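"""Canned desk-scale experiments with frozen configurations.

Each function runs one self-contained study on synthetic data and returns its
headline numbers.  They are used both by the test suite and by the
reproduction script, so the configurations (sample sizes, optimizer
settings) live here in one place.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np

from .dgbdt import DistillConfig, dgbdt_predict, train_dgbdt
from .interpret import pdp_one_way
from .pipeline import TNTConfig, robustness_experiment, run_tnt
from .embedding import encode
from .synth import make_additive, make_clinical_like, make_gaussian_means
from .trees import TreeConfig, best_split, fit_cart, js_estimate

__all__ = [
    "js_dominance",
    "split_oracle_agreement",
    "teacher_recovery",
    "distillation_fidelity",
    "pdp_recovery",
    "robustness_summary",
    "convergence_gap",
]


def _r2(pred: np.ndarray, target: np.ndarray) -> float:
    ss_res = float(np.sum((pred - target) ** 2))
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def js_dominance(
    m: int = 10,
    n_per_group: int = 5,
    mu_spread: float = 1.0,
    sigma: float = 2.0,
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo risk comparison of the positive-part James-Stein estimator
    against the per-group average (shrinkage toward the origin).

    Returns the fraction of replicates where the shrunk estimate has strictly
    lower total squared error, plus the aggregate risk ratio.
    """
    wins = 0
    js_risk = 0.0
    mle_risk = 0.0
    for rep in range(n_replicates):
        data = make_gaussian_means(
            m, n_per_group, mu_spread, sigma, seed=seed * n_replicates + rep
        )
        ybar = data.group_means
        est = js_estimate(ybar, np.zeros(m), data.mean_variance, m)
        err_js = float(np.sum((est - data.true_means) ** 2))
        err_mle = float(np.sum((ybar - data.true_means) ** 2))
        js_risk += err_js
        mle_risk += err_mle
        wins += err_js < err_mle
    return {
        "win_rate": wins / n_replicates,
        "js_risk": js_risk / n_replicates,
        "mle_risk": mle_risk / n_replicates,
        "risk_ratio": js_risk / mle_risk,
        "n": n_replicates,
    }


def _bruteforce_split(X, y, min_leaf=1):
    """Reference exhaustive search over (feature, midpoint, missing side)."""
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


def split_oracle_agreement(
    n_instances: int = 100, missing_rate: float = 0.2, seed: int = 0
) -> dict:
    """Fraction of random instances where the vectorized split search returns
    the same (feature, threshold, loss) as brute-force enumeration; half the
    instances carry randomly wiped cells."""
    rng = np.random.default_rng(seed)
    agree = 0
    for trial in range(n_instances):
        n = int(rng.integers(5, 51))
        d = int(rng.integers(1, 6))
        X = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        if trial % 2 == 1:
            X = X.copy()
            X[rng.random((n, d)) < missing_rate] = np.nan
        got = best_split(X, y)
        want = _bruteforce_split(X, y)
        if want is None:
            agree += got is None
            continue
        agree += (
            got is not None
            and got.feature_index == want[1]
            and abs(got.threshold - want[2]) < 1e-12
            and abs(got.loss - want[0]) <= 1e-8 * (1 + abs(want[0]))
        )
    return {"agreement_rate": agree / n_instances, "n": n_instances}


def teacher_recovery(seed: int = 11) -> dict:
    """Distillation fidelity against a fixed depth-2 hard-tree teacher.

    The teacher labels a 4000-sample transfer set; the student (5 soft trees
    of depth 4) trains at alpha = 1 and is scored by R^2 against the teacher
    on 1000 held-out rows.
    """
    data = make_clinical_like(n=5000, seed=seed)
    n_train = 4000
    X, risk = data.X, data.risk
    teacher_tree = fit_cart(X[:n_train], risk[:n_train], TreeConfig(depth_limit=2))
    t = teacher_tree.predict(X[:n_train])
    cfg = DistillConfig(
        alpha=1.0, n_trees=5, depth=4, lr=0.1, epochs=300,
        batch_size=128, inverse_temp=4.0, seed=seed % (2**16),
    )
    student = train_dgbdt(X[:n_train], risk[:n_train], t, cfg)
    pred = dgbdt_predict(student, X[n_train:])
    target = teacher_tree.predict(X[n_train:])
    return {"r2": _r2(pred, target), "n": 1000}


def distillation_fidelity(seed: int = 9) -> dict:
    """Student/teacher agreement of the full pipeline at alpha = 0.9, T = 2
    on held-out clinical-style data."""
    data = make_clinical_like(n=5000, seed=seed)
    n_train = 4000
    X, y = data.X[:n_train], data.y[:n_train]
    X_test = data.X[n_train:]
    cfg = TNTConfig(
        seed=seed,
        tree_depth=3,
        student=DistillConfig(
            alpha=0.9, temperature=2.0, lr=0.1, epochs=300,
            batch_size=128, inverse_temp=4.0,
        ),
    )
    model = run_tnt(X, y, cfg)
    t_test = model.teacher.predict(encode(model.embedding, model.front, X_test))
    s_test = model.predict(X_test)
    return {"r2": _r2(s_test, t_test), "n": 1000}


def pdp_recovery(seed: int = 5) -> dict:
    """Partial-dependence recovery on additive ground truth y = 2 x1 - x2.

    Fits the pipeline (depth-3 front tree, student at alpha = 0.25 with an L1
    gate penalty) and reports the fitted PDP slope of the coefficient-2
    feature and the PDP range of an inert feature.
    """
    data = make_additive(
        n=2000, coefficients=[2.0, -1.0, 0.0, 0.0, 0.0], noise_sd=0.1, seed=seed
    )
    cfg = TNTConfig(
        seed=seed,
        tree_depth=3,
        student=DistillConfig(alpha=0.25, gate_l1=3e-3),
    )
    model = run_tnt(data.X, data.y, cfg)
    curve = pdp_one_way(model, data.X, feature=0)
    slope = float(np.polyfit(curve.grids[0], curve.values, 1)[0])
    inert = pdp_one_way(model, data.X, feature=3)
    return {
        "slope": slope,
        "inert_range": float(np.ptp(inert.values)),
        "n": data.X.shape[0],
    }


def robustness_summary(n_seeds: int = 5, base_seed: int = 0) -> dict:
    """Missing-value protocol; AUROC degradation (clean minus 40% sparse) of
    the full TNT pipeline and of the plain MLP."""
    res = robustness_experiment(
        sparsity_levels=(0.0, 0.2, 0.4),
        methods=("cart", "jsdt", "mlp", "tn", "nt", "tnt"),
        n_seeds=n_seeds,
        base_seed=base_seed,
    )
    deg = res["degradation"]
    at40 = deg[deg["sparsity"] == 0.4].set_index("method")["auroc_degradation"]
    return {
        "tnt_auroc_degradation": float(at40["tnt"]),
        "mlp_auroc_degradation": float(at40["mlp"]),
        "jsdt_auroc_degradation": float(at40["jsdt"]),
        "cart_auroc_degradation": float(at40["cart"]),
        "n": n_seeds,
        "tables": res,
    }


def convergence_gap(
    alphas=(0.25, 0.5, 0.9), temperatures=(1.0, 2.0), seed: int = 0
) -> dict:
    """Worst-case distance of a single-tree ensemble's one-sample output from
    the distillation-loss minimizer s* across (alpha, T) settings."""
    x = np.array([[0.5, -0.2]])
    y, t = np.array([0.3]), np.array([1.1])
    worst = 0.0
    for alpha in alphas:
        for T in temperatures:
            s_star = (alpha * T * T * t + (1 - alpha) * y) / (
                alpha * T * T + 1 - alpha
            )
            cfg = DistillConfig(
                alpha=alpha, temperature=T, n_trees=1, depth=2, lr=0.1,
                epochs=300, batch_size=1, seed=seed % (2**16),
            )
            ens = train_dgbdt(x, y, t, cfg)
            worst = max(worst, abs(dgbdt_predict(ens, x)[0] - s_star[0]))
    return {"max_error": worst, "n": len(alphas) * len(temperatures)}
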