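"""Synthetic data generators with known ground truth.

Four scenarios cover the stages of the tree-network-tree pipeline:

A. Gaussian group means — the shrinkage-estimation setting: ``m`` groups with
   unknown true means observed through i.i.d. Gaussian noise.  Used to measure
   the risk of the James-Stein estimator against the per-group average.
B. Clinical-style tabular data — ~30 numeric covariates, a sparse logistic
   risk model with pairwise interactions, binary outcome (0 = benign,
   1 = malignant style risk label) plus the latent risk itself.
C. The missing-value robustness protocol: scenario-B data with a uniformly
   random fraction of feature cells wiped to NaN.
D. Additive/interaction regression ground truth for partial-dependence
   recovery checks.

All generators are pure functions of their arguments; randomness comes from
``numpy.random.default_rng`` (PCG64), which is reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianMeansData",
    "ClinicalData",
    "AdditiveData",
    "make_gaussian_means",
    "make_clinical_like",
    "inject_missing",
    "make_additive",
]


@dataclass
class GaussianMeansData:
    """Group-structured Gaussian draws for shrinkage-risk simulations."""

    true_means: np.ndarray        # (m,)
    observations: np.ndarray      # (m, n_per_group)
    group_means: np.ndarray       # (m,) per-group averages
    sigma: float                  # observation noise sd
    n_per_group: int

    @property
    def mean_variance(self) -> float:
        """Sampling variance of each group mean, sigma^2 / n."""
        return self.sigma**2 / self.n_per_group


def make_gaussian_means(
    m: int,
    n_per_group: int,
    mu_spread: float = 1.0,
    sigma: float = 2.0,
    seed: int | None = 0,
) -> GaussianMeansData:
    """Draw ``m`` true group means and noisy observations of each.

    True means are uniform on ``[-mu_spread, +mu_spread]`` (``mu_spread`` is a
    half-width, so the mean sd is ``mu_spread / sqrt(3)``); each group then
    receives ``n_per_group`` observations with independent ``N(0, sigma^2)``
    noise.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(seed)
    mu = rng.uniform(-mu_spread, mu_spread, size=m)
    obs = mu[:, None] + rng.normal(0.0, sigma, size=(m, n_per_group))
    return GaussianMeansData(
        true_means=mu,
        observations=obs,
        group_means=obs.mean(axis=1),
        sigma=float(sigma),
        n_per_group=int(n_per_group),
    )


@dataclass
class ClinicalData:
    """Tabular binary-risk dataset with known generative coefficients."""

    X: np.ndarray                 # (n, d)
    y: np.ndarray                 # (n,) labels in {0, 1}
    risk: np.ndarray              # (n,) latent Bernoulli probability
    coef: np.ndarray              # (d,) linear coefficients (zeros = inert)
    interactions: list[tuple[int, int, float]] = field(default_factory=list)


def make_clinical_like(
    n: int,
    d: int = 30,
    informative: int = 8,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    seed: int | None = 0,
) -> ClinicalData:
    """Generate a clinical-style risk dataset.

    Features are standard normal.  The latent score is a sparse linear
    combination of the first ``informative`` features (alternating-sign
    coefficients scaled by ``effect_size``) plus two pairwise interactions
    among them, corrupted by ``N(0, noise_sd^2)`` noise; the risk is the
    logistic of the score and labels are Bernoulli draws of the risk.
    """
    if informative > d:
        raise ValueError(f"informative={informative} exceeds d={d}")
    if informative < 1:
        raise ValueError("need at least one informative feature")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    coef = np.zeros(d)
    signs = np.where(np.arange(informative) % 2 == 0, 1.0, -1.0)
    magnitudes = 1.0 - 0.5 * np.arange(informative) / max(informative, 1)
    coef[:informative] = effect_size * signs * magnitudes
    score = X @ coef
    interactions: list[tuple[int, int, float]] = []
    if informative >= 2:
        interactions.append((0, 1, 0.5 * effect_size))
    if informative >= 4:
        interactions.append((2, 3, -0.5 * effect_size))
    for i, j, c in interactions:
        score = score + c * X[:, i] * X[:, j]
    if noise_sd > 0:
        score = score + rng.normal(0.0, noise_sd, size=n)
    risk = 1.0 / (1.0 + np.exp(-score))
    y = (rng.random(n) < risk).astype(float)
    return ClinicalData(X=X, y=y, risk=risk, coef=coef, interactions=interactions)


def inject_missing(
    X: np.ndarray, rate: float, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Wipe a uniformly random fraction ``rate`` of cells to NaN.

    Returns ``(X_missing, mask)`` where ``mask`` is the boolean wiped-cell
    indicator.  The input array is left unmodified.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    mask = rng.random(X.shape) < rate
    Xm = np.array(X, dtype=float, copy=True)
    Xm[mask] = np.nan
    return Xm, mask


@dataclass
class AdditiveData:
    """Regression dataset with exactly known additive + interaction truth."""

    X: np.ndarray
    y: np.ndarray
    coef: np.ndarray
    interactions: list[tuple[int, int, float]]
    noise_sd: float


def make_additive(
    n: int,
    coefficients,
    interaction_pairs: list[tuple[int, int, float]] | None = None,
    noise_sd: float = 0.1,
    seed: int | None = 0,
) -> AdditiveData:
    """Generate ``y = X @ beta + sum(c * x_i * x_j) + N(0, noise_sd^2)``."""
    coef = np.asarray(coefficients, dtype=float)
    d = coef.shape[0]
    interaction_pairs = list(interaction_pairs or [])
    for i, j, _ in interaction_pairs:
        if not (0 <= i < d and 0 <= j < d):
            raise ValueError(f"interaction pair ({i}, {j}) out of range for d={d}")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = X @ coef
    for i, j, c in interaction_pairs:
        y = y + c * X[:, i] * X[:, j]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return AdditiveData(
        X=X, y=y, coef=coef, interactions=interaction_pairs, noise_sd=float(noise_sd)
    )
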