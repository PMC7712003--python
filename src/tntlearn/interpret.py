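"""Post-hoc interpretability: partial dependence and per-case decision paths.

Partial dependence marginalizes the model's prediction over all features
except the one (or two) of interest: for a grid value v, the background rows
are copied with the feature forced to v and the predictions averaged.  For an
additive model the two-way surface equals the outer sum of the one-way curves
up to a constant, so curvature of the surface beyond that identity is
evidence of interaction.

Per-case explanations combine the student ensemble's prediction with the
maximum-probability decision path of every member soft tree: gate
probabilities along the path and the input features carrying the largest
absolute gate weight at each step.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .soft_tree import extract_path

__all__ = ["PDPResult", "pdp_one_way", "pdp_two_way", "explain_case", "leaf_responses"]


@dataclass
class PDPResult:
    """Grid and averaged predictions of a partial-dependence computation."""

    features: tuple[int, ...]
    grids: tuple[np.ndarray, ...]
    values: np.ndarray          # (len(grid),) one-way; (len(g1), len(g2)) two-way
    n_background: int

    def to_frame(self) -> pd.DataFrame:
        if len(self.features) == 1:
            return pd.DataFrame(
                {"grid": self.grids[0], "partial_dependence": self.values}
            )
        g1, g2 = np.meshgrid(self.grids[0], self.grids[1], indexing="ij")
        return pd.DataFrame(
            {
                "grid_1": g1.ravel(),
                "grid_2": g2.ravel(),
                "partial_dependence": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """Line plot (one-way) or filled contour (two-way); needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if len(self.features) == 1:
            ax.plot(self.grids[0], self.values)
            ax.set_xlabel(f"feature {self.features[0]}")
            ax.set_ylabel("partial dependence")
        else:
            cs = ax.contourf(self.grids[0], self.grids[1], self.values.T, levels=20)
            ax.figure.colorbar(cs, ax=ax)
            ax.set_xlabel(f"feature {self.features[0]}")
            ax.set_ylabel(f"feature {self.features[1]}")
        return ax


def _predict_fn(model):
    if hasattr(model, "predict"):
        return model.predict
    if callable(model):
        return model
    raise TypeError("model must expose .predict or be callable")


def _background(X, sample: int | None, seed: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    limit = min(500 if sample is None else sample, X.shape[0])
    if limit >= X.shape[0]:
        return X
    rng = np.random.default_rng(seed)
    return X[rng.choice(X.shape[0], size=limit, replace=False)]


def _grid(X, feature: int, grid, n_points: int) -> np.ndarray:
    # default grid: quantile points trimmed to the 5-95% range, so the plot
    # is not dominated by extreme order statistics
    if grid is not None:
        g = np.sort(np.asarray(grid, dtype=float))
    else:
        col = X[:, feature]
        col = col[~np.isnan(col)]
        g = np.unique(np.quantile(col, np.linspace(0.05, 0.95, n_points)))
    return g


def pdp_one_way(
    model,
    X_background,
    feature: int,
    grid=None,
    n_points: int = 20,
    sample: int | None = None,
    seed: int = 0,
) -> PDPResult:
    """One-way partial dependence of the model on one feature.

    By default the grid is 20 quantile points of the observed feature and the
    background is at most 500 rows sampled with a fixed seed.
    """
    f = _predict_fn(model)
    X = np.atleast_2d(np.asarray(X_background, dtype=float))
    if not 0 <= feature < X.shape[1]:
        raise ValueError(f"feature {feature} out of range for d={X.shape[1]}")
    bg = _background(X, sample, seed)
    g = _grid(X, feature, grid, n_points)
    values = np.empty(g.shape[0])
    for i, v in enumerate(g):
        Xv = bg.copy()
        Xv[:, feature] = v
        values[i] = float(np.mean(f(Xv)))
    return PDPResult(
        features=(feature,), grids=(g,), values=values, n_background=bg.shape[0]
    )


def pdp_two_way(
    model,
    X_background,
    feature_pair: tuple[int, int],
    grids=None,
    n_points: int = 20,
    sample: int | None = None,
    seed: int = 0,
) -> PDPResult:
    """Two-way partial dependence over a pair of distinct features."""
    f1, f2 = feature_pair
    if f1 == f2:
        raise ValueError("the two features of a two-way plot must differ")
    f = _predict_fn(model)
    X = np.atleast_2d(np.asarray(X_background, dtype=float))
    for feat in (f1, f2):
        if not 0 <= feat < X.shape[1]:
            raise ValueError(f"feature {feat} out of range for d={X.shape[1]}")
    bg = _background(X, sample, seed)
    g1 = _grid(X, f1, grids[0] if grids else None, n_points)
    g2 = _grid(X, f2, grids[1] if grids else None, n_points)
    values = np.empty((g1.shape[0], g2.shape[0]))
    for i, v1 in enumerate(g1):
        Xv = bg.copy()
        Xv[:, f1] = v1
        for j, v2 in enumerate(g2):
            Xv[:, f2] = v2
            values[i, j] = float(np.mean(f(Xv)))
    return PDPResult(
        features=(f1, f2), grids=(g1, g2), values=values, n_background=bg.shape[0]
    )


def explain_case(model, x, top_features: int = 3) -> dict:
    """Prediction plus per-student-tree decision paths for one sample.

    Read-only: the model is not modified.  The report is JSON-serializable:
    the ensemble prediction and, for each member soft tree, the
    maximum-probability root-to-leaf path with gate probabilities and the
    top-weighted gate features.
    """
    x = np.asarray(x, dtype=float).ravel()
    xs = model.student_input(x[None, :])[0]
    pred = float(model.predict(x[None, :])[0])
    paths = [
        extract_path(tree, xs, top_features=top_features)
        for tree in model.student.members
    ]
    return {"prediction": pred, "n_trees": len(paths), "paths": paths}


def leaf_responses(model, x) -> list[np.ndarray]:
    """Per-tree leaf path-probability vectors for one sample.

    A hook for aggregating per-leaf responses (e.g. saliency-style summaries);
    no aggregation is performed here.
    """
    from .soft_tree import path_probs

    x = np.asarray(x, dtype=float).ravel()
    xs = model.student_input(x[None, :])[0]
    return [path_probs(tree, xs) for tree in model.student.members]


def case_report_json(model, x, path, top_features: int = 3) -> None:
    """Write an explain_case report to a JSON file."""
    with open(path, "w") as fh:
        json.dump(explain_case(model, x, top_features=top_features), fh, sort_keys=True)
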