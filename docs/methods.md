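# Methods

This note records the models implemented in `tntlearn`, their assumptions,
the numerical choices that a re-implementation would need to match, and what
the synthetic benchmarks do and do not demonstrate.

## Hard trees with James–Stein leaf shrinkage

The front stage is a greedy binary regression tree. Split candidates are
midpoints between consecutive distinct sorted values of each feature; the
chosen split minimizes the summed squared error of the two children around
their representative values. Construction proceeds breadth-first and stops
at the depth limit (default 6 for single trees, 9 for forest members), when
a node falls below the minimum split size (default 2, minimum 1 per leaf),
when no feature has two distinct values, or when the node's targets are all
identical (a purity stop: splitting a pure node is loss-0 busywork and would
pollute the shrinkage pool with duplicate means).

Leaf values are leaf means under CART. The JSDT applies positive-part
James–Stein shrinkage toward the global mean of leaf means,
μ̂ᵢ = GM + (1 − λγ)₊(ȳᵢ − GM) with
γ = (m − 3) / Σᵢ (nᵢ/δᵢ²)(ȳᵢ − GM)². Conventions that the formula leaves
open and that this package fixes:

* **γ uses the per-leaf count nᵢ** (the unequal-variance group-means form).
  The computation is isolated in `js_shrink_leaves`, so the pooled-n
  alternative is a one-line change.
* **Variance floor.** A single-member leaf has no sample variance; it
  receives the pooled variance of the remaining leaves, and every variance
  is floored at 1e-8 so γ stays finite. A caller-supplied positive variance
  for a count-1 group is honored.
* **Shrinkage during split scoring** engages once the provisional tree has
  m ≥ 4 leaves: the hypothetical leaf set (current leaves minus the node
  being split, plus both candidate children) is shrunk and the split is
  scored by the children's squared error around their *shrunk* values; with
  fewer leaves the plain means are used. Only the two children enter the
  split loss; the other leaves enter through GM and γ.
* **Exact CART reduction.** When the shrink factor is exactly 1 (λ = 0, or
  γ non-positive/undefined) the leaf means are returned bit-identically
  rather than via GM + 1·(ȳ − GM); `fit_jsdt(λ=0)` therefore serializes
  identically to `fit_cart`, a property the tests assert as a byte-level
  identity.
* **Tie-breaking** prefers the lowest feature index, then the lowest
  threshold, with a relative 1e-9 tolerance on loss comparisons: distinct
  (feature, threshold) pairs can induce the same partition, whose losses
  agree only up to rounding.

**Missing values.** During split scoring, the missing-valued samples of a
node are assigned as a block to the child that yields the lower split loss
(left on ties); at prediction a sample missing the split feature follows the
stored majority-training direction. Block assignment avoids the circularity
of per-sample assignment (assignments change child means). Every sample —
even an all-NaN row — reaches exactly one leaf.

The JSDF bags JSDTs over bootstrap resamples (default 80 trees, depth ≤ 9,
optional per-split feature subsampling); per-tree randomness comes from
spawned `SeedSequence` children, so forests are reproducible across
platforms.

## Leaf embeddings and the teacher

One-hot encoding gives one column block per tree with exactly one hot entry
per (sample, tree); leaves are numbered depth-first left-first, so encodings
are stable across serialization. For forests, trees are partitioned into k
random near-equal groups; each group learns a lookup table mapping its
leaves to `embed_dim`-vectors and a linear head trained by mini-batch
gradient descent (default 200 epochs, lr 1e-2) against the group-summed
per-tree leaf predictions p_t(X); the abstract fitting loss is realized as
mean squared error. An optional *leaf shrinking* mode uses the shrunk leaf
values as regression targets; it never changes the leaf-index geometry.
One-hot is the default for single trees on small data; the dense grouped
embedding is for forests, whose total leaf count grows linearly with
ensemble size.

The teacher is a fully connected ReLU network (hidden widths 32-16-16-8-8,
single linear output) trained by mini-batch SGD on squared error, with L2
weight decay (default 0.015) on the weight matrices. The decay matters: on
noisy Bernoulli risk labels an unregularized network of this size memorizes
the training set (train AUROC 1.0, held-out barely above chance), which
would make every teacher-dependent stage an amplifier of noise. The decay
default was selected on held-out AUROC of the teacher alone on clean
clinical-style data and is applied identically wherever the network appears
(standalone baseline, T-N, N-T, full pipeline). Binary tasks are treated as
risk-probability regression on [0, 1]; no sigmoid is applied during
training, and rank metrics consume the raw scores.

## Distillable gradient-boosted soft trees

A soft decision tree of depth D is a complete binary tree whose internal
nodes carry linear sigmoid gates g(x) = σ(β(w·x + b)); a sample reaches leaf
ℓ with the product of gate probabilities along the path, and the output is
the path-probability-weighted sum of leaf values. β (the gate inverse
temperature) controls sharpness; as β → ∞ the soft output approaches the
hard routing value. Gradients are computed analytically by a two-sweep
scheme (top-down reach probabilities, bottom-up subtree values) and are
checked against central differences at 1e-5 in the tests, as are the MLP's
and the full dTNT chain's.

The student ensemble trains M trees (default 5, depth 4) *simultaneously*:
per mini-batch, tree m's target is the residual of the distillation loss
dl(s, α, y, t) = αT²‖s − t‖² + (1 − α)‖s − y‖² evaluated at the cumulative
output s of its predecessors, and one SGD step (momentum 0.9) is taken on
the summed per-tree squared losses, with the residual targets held constant
(stop-gradient through earlier trees).

**Residual normalization.** The raw negative gradient of dl is
−[2αT²(s − t) + 2(1 − α)(s − y)]; used directly as a fitting target it makes
the unit boosting step overshoot or diverge whenever the loss curvature
2(αT² + 1 − α) differs from 1/2 (already at α = 0: the raw gradient is
2(y − s) where classical boosting fits y − s). The trees therefore fit the
curvature-normalized residual r/(2(αT² + 1 − α)) = s* − s, a Newton step
toward the per-sample minimizer s* = [αT²t + (1 − α)y]/[αT² + 1 − α]. This
reduces exactly to the classical squared-loss residual at α = 0 and makes a
single tree on a single sample converge to s*, which the tests verify at
1e-2 across an (α, T) grid. The `residual` function itself still returns the
raw negative gradient (that is the quantity checked against central
differences); the normalization lives in the trainer. A further global
`shrinkage` multiplier on the target is exposed as the usual boosting
learning-rate knob (default 1).

Optimizer knobs beyond the spec's plain-SGD sketch — momentum (0.9), the
gate inverse temperature, optional L2 (`gate_decay`) and L1 (`gate_l1`,
proximal soft-thresholding, producing exact zeros) penalties on gate
weights — exist because plain SGD at small learning rates cannot sharpen
sigmoid gates enough to mimic even a depth-2 hard tree within desk-scale
budgets. All are serialized with the model. For classification-style
distillation a leaf-softmax head with the leaf-weighted expected
cross-entropy objective L(x) = −Σ_ℓ P_ℓ(x) Σ_k T_k log Q_k^ℓ is provided
(the conventional soft-tree form; probabilities are clipped at 1e-12 inside
the log). No leaf-balance regularizer is used.

**sGBM baseline.** `sgbm_baseline` is literally `train_dgbdt` at α = 0 with
zero soft labels — the only difference between the distilled student and
ground-truth soft boosting is the loss, and the tests assert the reduction
as exact prediction equality.

## Pipeline variants

* **TNT** (default): hard tree → leaf embedding → teacher → soft labels →
  student trained on {X, y, t}. The student consumes raw features, so its
  decision paths are in the original feature space. NaN cells are routed
  natively by the hard tree; the differentiable stages receive mean-imputed
  values with the training-column means stored on the model.
* **TNT-Fs**: identical through the teacher; the student consumes a chosen
  hidden layer of the teacher instead of raw X (features-only, no mixing of
  raw inputs). Decision paths are then over learned features — more
  capacity, less direct interpretability.
* **dTNT**: the hard front end is replaced by K soft trees (default 4,
  depth 3); a square identity-initialized linear connector joins front and
  teacher and a scalar affine connector joins teacher and student, making
  the soft label t(x) differentiable in every upstream parameter. Training
  is stage-wise warm start (front boosted on y; teacher on the connector
  output against y; student distilled from the warm chain) followed by joint
  mini-batch fine-tuning of mean dl(s(x), α, y, t(x)) through all stages.
  After a full warm start the joint objective is typically already near a
  stationary point, so the fine-tuning mainly co-adapts t and s; the
  joint-loss-decrease test therefore starts from a deliberately cold warm
  start.
* A hard-tree *predicted-target* data flow (training the teacher on tree
  predictions instead of y) is deliberately not implemented: a low-capacity
  hard tree's predictions are a noisier target than the labels themselves.

Every stage seed is derived deterministically from the single pipeline seed;
refitting with an equal config yields byte-identical serialized bundles
(directories of JSON files written with sorted keys).

## Metrics and interpretability

AUROC is the rank statistic with tie averaging and AUPRC the step-wise
average precision (scikit-learn's `roc_auc_score` / `average_precision_score`);
MSE is the plain mean squared error of raw scores. Partial dependence forces
a feature (or pair) to each grid value over a background sample (default at
most 500 rows, fixed seed) and averages predictions; the default grid is 20
quantile points trimmed to the 5–95% range so curves are not dominated by
extreme order statistics, where the sigmoid gates saturate. Per-case reports
combine the student prediction with each member tree's maximum-probability
root-to-leaf path (the arg-max of the path-probability vector, not greedy
per-gate routing), the gate probabilities along it, and the largest-|w|
input features at each gate.

## Synthetic benchmarks

* **Scenario A (group means).** m true means drawn uniformly on
  [−spread, +spread], n observations each at noise σ. The bounded uniform
  reading makes the mean sd (spread/√3 ≈ 0.58 at the defaults) comparable to
  the sampling noise σ/√n ≈ 0.89 — the regime where shrinkage is materially
  beneficial and the dominance simulation is informative rather than
  vacuous. At the defaults (m = 10, n = 5, spread 1, σ = 2) the positive-part
  estimator wins ~96–98% of replicates with an aggregate risk ratio ~0.43.
* **Scenario B (clinical-style risk).** Standard-normal features, a sparse
  alternating-sign linear score over the first `informative` features plus
  two pairwise interactions, logistic link, Bernoulli labels; the latent
  risk is returned alongside. Default d = 30 numeric features; prevalence
  ≈ 0.5.
* **Scenario C (robustness protocol).** Scenario-B data with a uniformly
  random fraction of feature cells (20%/40%) wiped to NaN — missing
  completely at random, matching uniform wiping; informative missingness is
  out of scope. Protocol: per seed, a 75/25 split, all methods fit on the
  wiped training portion and scored on the wiped test portion; degradation
  is the clean-data metric minus the sparse-data metric. Experiment scale:
  n = 800, d = 20, 6 informative, 5 seeds.
* **Scenario D (additive truth).** y = Xβ + interactions + ε with known β,
  for PDP recovery. The PDP experiment uses β = (2, −1, 0, 0, 0), n = 2000,
  a depth-3 front tree and a student at α = 0.25 with `gate_l1` = 3e-3: the
  shallow front keeps the teacher from inheriting noise-feature splits
  (a deeper front demonstrably leaks inert-feature dependence into the
  soft labels), the lower α lets the ground truth set the slope, and the L1
  penalty zeroes inert gate weights.

All generators are pure functions of their arguments on top of numpy's
PCG64, so datasets are bit-reproducible across platforms.

**What the benchmarks do not show.** The generators are Gaussian,
homoscedastic, and MCAR; real clinical tables have mixed types, skewed and
censored measurements, correlated blocks, and informative missingness. The
distillation-fidelity and robustness results on these fixtures demonstrate
that the machinery behaves as designed (reductions exact, gradients correct,
shrinkage dominant, tree front ends no more sparsity-sensitive than the
plain network), not that the pipeline outperforms alternatives on any
particular real dataset.

## Experiment configurations

Frozen in `tntlearn.experiments` (shared by tests and the reproduction
script): teacher-recovery uses a 4000-sample transfer set, student
lr 0.1 / 300 epochs / batch 128 / β = 4 — distillation can query the teacher
on arbitrarily many unlabeled draws, and the boundary regions of a
piecewise-constant teacher are only learnable when they are well sampled;
pipeline fidelity adds T = 2 so the teacher term dominates the Eq. blend;
the convergence study uses 300 single-sample epochs at lr 0.1. Problem sizes
throughout are chosen so each experiment runs in seconds to a few minutes on
one CPU.

## Known limitations

* Split search is axis-aligned and exhaustive over midpoints; no histogram
  binning, so very large n per node is slow.
* The dGBDT is regression/risk-probability only; the classification
  soft-tree head is provided as a building block but no classification-mode
  boosting loop is wired.
* No pruning, honest splitting, or oblique hard trees; no leaf-balance
  penalty for soft trees.
* Mean imputation for the differentiable stages is deliberately simple; the
  hard trees are the component that handles missingness natively.
* The dTNT joint objective fine-tunes all stages against y through the
  distillation blend; it does not re-run the embedding stage, which is
  specific to hard trees.
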