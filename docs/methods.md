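# Methods

## Problem setting

Micro-expression corpora are small (a few hundred samples each) and were
collected with different cameras, lighting, and participant pools. When
several of them are pooled into one composite training set, two things go
wrong: the feature distributions of the sources disagree (models learn
"which dataset is this from" as a shortcut), and the per-dataset and
per-category sample counts are badly imbalanced, so the model over-serves
the largest sources. This package implements a training-time regularizer
against the first problem, a rebalancing planner against the second, and a
leave-one-dataset-out (LODO) protocol that measures generalization to a
truly unseen source.

All emotion labels use the 3-class scheme standard for composite
micro-expression work: Positive, Negative, Surprise. Raw labels are mapped
with a configurable table (happiness→Positive; disgust, repression, anger,
fear, sadness, contempt, tense→Negative; surprise→Surprise); unmapped raw
labels are excluded with a logged count rather than guessed, since the
authoritative per-dataset mapping is not published.

## Batch Regularization Learning

Within each mini-batch, a sigmoid head scores every sample's penultimate
feature vector, a_ij = σ(Wᵀx_ij + b); per-source means m_i are averaged over
the samples of each source dataset present in the batch, and the loss is the
range L_BRL = max m_i − min m_i. The composite objective is
L_total = (1 − λ)L_CE + λL_BRL with λ ∈ [0, 1).

Design choices that the formulation leaves open:

- **Loss-only attention.** The attention weights feed only L_BRL; they do
  not rescale features, logits, or per-sample CE terms. This is the reading
  consistent with the module being a detachable loss component.
- **Feature gradients.** L_BRL back-propagates into the backbone features,
  not just the head — without this the regularizer could not shape the
  representation at all; the head alone can always trivially balance itself
  (a constant head gives L_BRL = 0, which is also why head-only gradient
  descent drives the loss to ~0 on fixed features, a property the tests
  exercise).
- **Partial batches.** The range is computed over the sources present; a
  batch with fewer than two sources contributes L_BRL = 0 (counted and
  logged). The bundled stratified sampler splits every source's shuffled
  indices into near-equal chunks across the batches of an epoch, so each
  batch contains every source whenever the source has at least one sample
  per batch.
- **Ties and initialization.** max/min use standard subgradients (first
  arg-max/arg-min on ties); the head starts from a zero-mean Gaussian
  (sd 0.01) with zero bias, seeded from the run seed.
- Generalization from four fixed sources to any number of source groups is
  immediate, since the range is defined over the groups present.

Because sigmoid outputs lie in (0, 1), 0 ≤ L_BRL < 1 always, and
L_BRL = 0 exactly when all source means coincide.

## AU clustering and augmentation planning

Per category, the 17 OpenFace intensity regressors (AU01_r … AU45_r, 0–5
scale, clipped on ingestion with a logged warning) form the AU set; K-means
(Euclidean, raw intensities — all dimensions share one scale) with k = 3 by
default clusters the set, and the centroid of the largest cluster is the
category prototype. Ties on membership break toward the cluster with the
smaller within-cluster sum of squares, then the lower index. k is
configurable and reported alongside every centroid, since small per-category
sample sizes make the choice material. To make the result independent of
manifest order, vectors are put in lexicographic order before clustering, so
k-means++ initialization (10 restarts, tol 1e-6, ≤300 iterations) depends
only on the seed and the multiset of vectors.

The planner takes the dataset with the largest total as the reference
(arg-max of row totals, not a hard-coded name) and fills every other
dataset's shortfall with ⌊shortfall/C⌋ per category plus one extra for each
of the (shortfall mod C) rarest categories, ascending original count, ties
by category order. This "even split, remainders to the rarest" rule is the
unique simple rule reproducing all published per-category augmentation rows
(23/23/24, 51/50/50, 35/35/35, 38/37/38) from the count matrix, and it is
idempotent: planning on the post-augmentation table returns all zeros.
Generated samples are train-split only and flagged synthetic; they never
enter a test set.

## Metrics

Acc = ΣTP_c/N, UAR = (1/C)ΣTP_c/N_c, UF1 = (1/C)Σ2TP_c/(2TP_c+FP_c+FN_c).
A class never predicted but present in the truth gets F1 = 0 (positive
denominator); a class absent from the ground truth makes UAR/UF1 undefined
and raises a degenerate-ground-truth error instead of silently scoring.
Reports carry the confusion matrix and percentages rounded to 2 decimals.

## Trainer

The default backbone is the small CNN: conv 5×5 → 2×2 max-pool → conv 3×3 →
2×2 max-pool → flatten → linear classifier. Channel widths are 32 and 64 (the
published description fixes only kernel and pool sizes). It is implemented
in NumPy — im2col convolutions with explicit backward passes — because the
desk-scale problem sizes make a deep-learning framework unnecessary; the
backward pass is verified against central finite differences in the test
suite. Deeper standard architectures plug in through the same
forward/backward protocol and are deliberately not re-implemented here.

Optimization uses an Adam-style optimizer (β = 0.9/0.999, ε = 1e-8) with
decoupled weight decay on weight matrices, at the published operating point:
learning rate 2e-4, weight decay 5e-4, λ = 0.5, 100 epochs with the
regularizer activated after epoch 50 (λ is treated as 0 through
`brl_start_epoch` and effective from the following epoch). Batch size
defaults to 32 (not specified in the published schedule). The held-out
dataset is evaluated every epoch after activation and the best UAR is
recorded; UAR is the selection metric because it is the class-balance-robust
headline metric of the protocol. Note this "best after activation"
convention inspects the test set during training — it mirrors the published
protocol but is not blind, and the package keeps the full evaluation log so
stricter selections can be applied downstream.

## Synthetic benchmark

The generator emulates exactly the two structural phenomena the method
targets, and nothing else:

- **AU-driven classes.** Each class has a FACS-informed prototype
  (Positive: AU6 3.5, AU12 4.0; Negative: AU4 3.5, AU7 2.5, AU9 2.0,
  AU15 3.0; Surprise: AU1 3.5, AU2 3.5, AU5 3.0, AU25 3.0, AU26 2.5; all
  other AUs 0.3), with isotropic Gaussian spread 0.3 and clipping to [0, 5].
  Faces are parametric (oval, brows, eyes, mouth as control-point curves);
  control points move linearly with AU intensity, and the analytic
  neutral→apex pixel displacement field stands in for onset–apex optical
  flow. Images are RGB in [0, 1], origin top-left; flow is (dy, dx) pixels.
- **Domain biases.** Five bundled sites differ in brightness (−0.12…+0.10),
  contrast gain (0.8…1.25), RGB tint, effective resolution (box down/up
  sampling at factors 1, 0.66, 0.5, 0.33), and sensor noise (sd
  0.01…0.03). These produce a pixel-space domain silhouette > 0.9 on the
  bundled presets — a much cleaner shift than real corpora exhibit.

Presets: `desk` (5 sites × 20 per category; the scale of the package's own
experiments), `table1` (5 sites with the published count matrix of the five
real benchmarks, grand total 731), `toy2` (two small sites, one mildly
imbalanced, for smoke tests). All randomness derives from one master seed
via per-sample seed sequences, so outputs are byte-identical per seed and
subsets are reproducible.

What passing tests on this benchmark show — and what they do not: classes
are linearly separable in AU space by construction and domain biases are
strong, low-dimensional and appearance-only, so results here demonstrate the
*mechanics* of the method (the regularizer balances source attention; the
planner restores count balance; the pipeline is deterministic), not
recognition performance on real faces, where expression signal is far
subtler than the domain shift and label noise exists.

## Desk-scale BRL mechanism experiment

`trainer.desk_brl_comparison` trains the CNN on four sites of the `desk`
preset (64×64, 240 training samples), holding the fifth out, for 12 epochs
with the regularizer active from epoch 5, at λ = 0 and λ = 0.5 with three
seeds each. Twelve epochs is a deliberate scale reduction of the published
100-epoch schedule chosen so the full contrast runs in minutes on one CPU;
the warm-up fraction (one third) is kept similar. The readouts are the
final-epoch attention range H − L (median over seeds) and the best held-out
UAR. Under λ = 0 the head is frozen at its initialization (attention feeds
only the inactive loss), so the range drifts up as features grow during CE
training; under λ = 0.5 the regularizer holds it down — measured medians are
about 0.034 vs 0.018, with the reduction appearing in every seed, at equal
held-out UAR.

A caveat found and kept honest: the 2D-PCA silhouette of penultimate
features by source domain is *saturated* (≈0.9) in both arms at this scale —
the planted appearance biases dominate the feature variance after this few
epochs, so the silhouette does not discriminate λ = 0 from λ = 0.5 (medians
0.904 vs 0.918). The attention range is the sensitive mechanism readout;
the comparison reports silhouettes but no directional claim is made for
them.

## Numerical and degenerate-input conventions

- AU vectors: exactly 17 finite values; out-of-range values clip to [0, 5]
  with a logged warning (or raise, on request).
- An AU set whose vectors are all identical returns that vector as centroid
  (with a logged note) instead of running k > 1 clustering on zero variance.
- Identical features in diagnostics yield an all-zero projection and a null
  silhouette rather than 0/0.
- Losses accumulate in float64; network parameters and activations are
  float32.
- Rendering requires size ≥ 32 so the face template resolves; 64 is the
  test/deck default and 224 matches the published preprocessing size.

## Known limitations

- The NumPy backbone is CPU-bound and desk-scale; it is not meant for
  224×224 × 100-epoch runs.
- The synthetic benchmark cannot validate recognition accuracy claims on
  real micro-expression data; the real corpora are license-restricted and
  deliberately out of scope.
- Published-architecture backbones (ResNet-18, PoolFormer-S12) and GAN-based
  sample synthesis are consumed through plugin interfaces only.
- The authors' exact raw-label mapping and K-means k are not published; the
  defaults here are declared and configurable rather than certain.
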