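# Methods

`convbag` implements a hybrid classifier for imbalanced clinical tabular
data: a small convolutional network trained from its explicit
forward/backward algebra, whose softmax output layer is replaced at
classification time by a bagging ensemble voting on the network's
penultimate-layer activations.  This note records the model, the tunable
parameters, the synthetic-data generator, and the design choices that were
genuinely open.

## The model

**Grid encoding.** After preprocessing, exactly 36 feature columns survive.
Each is z-scored with training-set statistics (stored and reused verbatim at
prediction time; zero-variance columns encode to zeros) and laid out
row-major by descending importance on a 6×6 single-channel grid: cell
(r, c) holds the feature at importance rank 6r + c.  The mapping is an
arbitrary fixed bijection — any fixed layout is valid — chosen to be
documented and exactly invertible.

**Network.** The architecture is fixed:

    6×6×1 → conv 3×3×32 (same, stride 1, ReLU) → maxpool 2×2 (stride 1)
          → conv 3×3×64 (same, stride 1, ReLU) → maxpool 2×2 (stride 1)
          → flatten 1024 → dense 128 (ReLU) → dense 128 (ReLU) → softmax 2

Convolutions use the cross-correlation convention with one bias per output
channel.  Pooling is *overlapping* (stride 1), so each spatial dimension
shrinks by one per pool layer; backward routing sends each error term only
to its recorded argmax (ties: first position in row-major scan) and
accumulates additively across overlapping windows, conserving error mass.

**Training.** Softmax cross-entropy, so the output-layer error is
`δ_L = a_L − y`; hidden dense layers propagate `δ = (Wᵀ δ_next) ⊙ relu′(z)`;
convolution layers propagate error by full correlation with the
180°-rotated kernels (implemented through the im2col transpose).  Updates
are plain gradient descent on the **batch-summed** per-sample gradients —
no momentum, no weight decay, no dropout.  One iteration processes one
batch of `min(n, batch_size)` rows (a fresh uniform subsample when
n > batch_size); the loop stops when the Frobenius norm of the concatenated
parameter change falls below `tolerance` (default 1e−6) or after
`max_iterations` (default 1000), whichever comes first.  Initialisation is
He-uniform scaled by fan-in with zero biases, seeded.

Because updates sum rather than average per-sample gradients, the stable
learning-rate scale is roughly 1/batch smaller than mean-gradient
conventions: the default is `learning_rate = 1e−4` at `batch_size = 256`,
which reaches 100 % training accuracy on the noise-free fixture within a
few hundred iterations, while 1e−3 diverges into a dead-ReLU network.
All arithmetic is float64, which lets every analytic gradient be verified
against central finite differences (step 1e−5) to ~1e−9 relative error on a
miniature spec.

**Ensemble head.** The trained network's last dense layer provides a
128-dimensional representation.  A bagging ensemble of `T = 21` (odd — no
ties at the default) depth-limited CART trees (Gini midpoint splits,
max_depth 8, min_leaf 5) is trained on bootstrap resamples of those
features with labels in {−1, +1}, and predicts by the sign of the vote sum.
A zero sum (possible only for even T) breaks to +1 — in the clinical
framing the positive class is the event of interest, so ties resolve
conservatively for recall — and is counted in a reported tie statistic.

## Preprocessing

Stage order is fixed: clean → balance → rank/select → outlier-screen →
encode.

* **Cleaning** drops rows with a missing label or with more than 50 % of
  feature cells missing, then imputes remaining holes by class-conditional
  median (global median as fallback).  The global per-column medians are
  stored; prediction-time imputation uses them because the class of an
  incoming row is unknown.
* **Balancing** oversamples the minority class to exact parity: either
  replicated rows (`random_oversample`, the default) or SMOTE interpolation
  `x_i + λ(x_nn − x_i)`, λ ~ U[0,1], over the k = 5 nearest minority
  neighbours.  Original rows are never deleted.  Balancing is applied to
  training data only; balancing evaluation data would corrupt the reported
  metrics.
* **Importance ranking** is permutation importance on a bagged-tree model:
  each bootstrap tree's out-of-bag accuracy drop under per-feature
  permutation, averaged over trees and clipped at zero.  The trees restrict
  each split search to `ceil(sqrt(p)/2)` random candidate features.  This
  decorrelation is essential, not cosmetic: with full-feature trees, strong
  features mask weak-but-informative ones, whose estimated importance then
  becomes indistinguishable from noise (measured on the noise-free fixture:
  the ranking invariant fails in ~70–80 % of seeds without subsampling and
  in 0/50 seeds with it).  Expert knowledge enters as an optional keep-list
  merged with the top-k.
* **Outlier screening** is an isolation forest built from scratch: 100
  trees, subsample ψ = 256 (clamped to n), height limit ⌈log₂ ψ⌉, score
  `s(x) = 2^(−E[h(x)]/c(ψ))` with the path length extended below external
  nodes by `c(size)`, where `c(m) = 2H(m−1) − 2(m−1)/m` and
  `H(i) = ln i + γ` (so c(2) ≈ 0.1544).  The top 5 % (`contamination`) of
  rows by score are removed from training data only.

## Synthetic cohorts

The generator emulates a readmission-style cohort: 49 numeric columns of
which 36 are informative, a rare binary outcome, missing cells, and
corrupted records.  Labels follow a latent logistic model
`y = 1{β·x + ε > t}`, ε ~ Logistic(0, noise_sd), with t set (via an
auxiliary simulation) so the marginal positive rate equals
`imbalance_ratio`; with noise_sd = 0 the classes are exactly linearly
separable.  A documented subset of *non-informative* columns is discretised
into 0–4 integer codes to emulate categorical clinical fields — only
non-informative ones, so the generating signal stays continuous and
recoverable by construction.

Two corruption mechanisms are injected with per-row truth flags:

* **Missing cells**: completely-at-random masking at `missing_rate`
  (outlier rows exempt, so every injected anomaly stays observable).
* **Corrupted records**: `outlier_rate` of rows get a block of 6–12
  features displaced to 8–12 class-conditional SDs from the class mean
  (≥ 6 SD guaranteed) — the signature of a row-shift or unit-system error
  hitting a panel of fields.  The block size matters: a single displaced
  cell among 49 dimensions is *intrinsically* invisible to isolation
  forests (the reference scikit-learn implementation recovers only ~59 % of
  such outliers under the same budget, versus ~100 % for 6–12-cell blocks),
  because a random axis-aligned cut rarely selects the one corrupted
  coordinate.  The generator therefore models the multi-field corruption
  that isolation screening is actually suited to detect.

Fixture catalogue (all seed-fixed): `separable_small` (n = 400, 6 strong
informative features, noise-free, balanced), `imbalanced_benchmark`
(n = 4000, 36 informative, 20 % positives, noise_sd = 3 — a deliberately
weak, readmission-like signal — 3 % missing, 2 % outliers),
`outlier_screen` (n = 2000, 5 % outliers, nothing else), and
`noisy_benchmark` (n = 2000, balanced, heavy label noise).
`separable_small` uses 6 informative features with |β| ∈ [1.2, 2.0]: at
n = 400 the margin between the weakest informative and the luckiest noise
column must be well clear of estimator noise for ranking properties to be
meaningful by construction; with 8+ weaker coefficients the true
importances genuinely interleave.

What the generator does **not** emulate: real code tables and marginal
distributions of clinical attributes, informative missingness (missingness
is MCAR here), correlated features, or concept drift.  Passing tests
demonstrate the pipeline's mechanics and its behaviour under known ground
truth — not performance on any real cohort.

## Evaluation protocol

Metrics come from the confusion counts: accuracy (TP+TN)/(P+N), recall
TP/P with P the *actual* positives, precision TP/(TP+FP), F-measure
2TP/(2TP+FP+FN); a zero denominator reports 0 with a warning.  The
benchmark harness repeats stratified 80/20 splits, optionally balances the
training split inside each model's own flow, and reports per-model mean and
variance across repetitions.  Comparators: the hybrid model, the identical
network with its original softmax head, and scikit-learn's decision tree,
random forest and Gaussian naive Bayes behind a thin table adapter.

## Known limitations

* **Small-sample generalisation of the fixed architecture.**  The stride-1
  max-pool layers destroy most linearly-decodable signal at random
  initialisation (a ridge probe on the untrained stack recovers 0.95
  holdout accuracy after the first convolution but only ~0.66 after the
  second pool on the n = 400 fixture).  With few hundred training rows the
  network interpolates the training set before its filters adapt, so
  holdout accuracy on `separable_small` stays near chance even though a
  plain logistic fit on the same 36 encoded features reaches 0.95.  With
  thousands of rows the filters do adapt and the network becomes
  competitive.  Training-set claims ("the network fits the training data")
  are therefore meaningful at n = 400, but generalisation claims are tested
  on larger cohorts.
* **Balancing and accuracy.**  Oversampling only the training split shifts
  the decision threshold toward the minority class; on an *imbalanced* test
  set this reliably raises recall but tends to lower raw accuracy relative
  to unbalanced training — the opposite ordering can only be expected when
  the evaluation set is itself balanced.  The benchmark reports both
  conditions rather than asserting one ordering.
* The training-loop stopping rule reads the iteration threshold as a
  *parameter*-change norm; reading it as an activation-change norm is
  equally consistent with the training equations and is not implemented.
* No GPU path, no optimisers beyond plain gradient descent, two output
  classes only, and the layer grammar covers exactly the shapes the fixed
  architecture needs.
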