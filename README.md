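# crossmex

A toolkit for **cross-dataset facial micro-expression recognition**: training
on a composite of several micro-expression datasets and evaluating on a
completely unseen one (leave-one-dataset-out, LODO). The package is aimed at
affective-computing researchers who need the two ingredients that make this
protocol workable — a regularizer against source-dataset bias and a
principled rebalancing of the composite training set — plus a fully synthetic
multi-domain benchmark, because the underlying corpora (SMIC, CASME,
CASME II, SAMM, MMEW) are license-restricted and cannot be redistributed.

## What it implements

**Batch Regularization Learning (BRL).** Samples in a mini-batch are scored
by a sigmoid attention head, a_ij = σ(Wᵀx_ij + b), where x_ij is the feature
vector of sample j from source dataset i. Per-source mean attention
m_i = (1/n_i) Σ_j a_ij measures how much the model attends to each source;
the loss penalizes the *range*

    L_BRL = max_i m_i − min_i m_i,

and the training objective is

    L_total = (1 − λ)·L_CE + λ·L_BRL,   λ ∈ [0, 1),

so cross-entropy never vanishes. Gradients of L_BRL flow through the head
*and* into the backbone features, pushing the representation toward
domain-invariance. λ = 0.5 with activation after the warm-up phase is the
standard operating point.

**AU-guided augmentation planning.** For each emotion category the
17-dimensional OpenFace Action-Unit intensity vectors (AU1, 2, 4, 5, 6, 7,
9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45 on a 0–5 scale) are clustered with
K-means; the centroid of the dominant (largest) cluster is the category's
prototypical AU pattern and conditions sample generation. The planner tops
every dataset up to the largest dataset's total, splitting each shortfall
evenly over the three categories (Positive / Negative / Surprise) and giving
remainder units to the rarest categories first.

**Evaluation.** Accuracy, unweighted average recall (UAR = mean per-class
recall) and unweighted F1 (UF1 = mean per-class F1) from the 3-class
confusion matrix.

**Synthetic benchmark.** A parametric face renderer whose control points are
displaced linearly by AU intensities (AU12 raises mouth corners, AU4 lowers
brows, AU25/26 open the mouth, ...), with per-site appearance biases
(brightness, contrast, tint, resolution, noise) that reproduce the domain
shift of real composite benchmarks, plus analytic displacement fields as an
optical-flow surrogate. The default CNN backbone (5×5 and 3×3 convolutions,
each with 2×2 pooling, then a linear classifier) and its training loop are
implemented in NumPy with explicit backpropagation, so the whole protocol
runs on one CPU.

## Worked example

```python
from crossmex import BENCHMARK_COUNTS, plan_augmentation, composite_training_size

plan = plan_augmentation(BENCHMARK_COUNTS)
print(plan.reference_dataset, plan.reference_total)
for d in plan.datasets:
    print(d, [plan[d, c] for c in plan.categories])
print(composite_training_size(BENCHMARK_COUNTS, "SMIC"),
      composite_training_size(BENCHMARK_COUNTS, "SMIC", with_augmentation=True))
```

prints

```
MMEW 234
SMIC [23, 23, 24]
CASME [51, 50, 50]
CASME II [35, 35, 35]
SAMM [38, 37, 38]
MMEW [0, 0, 0]
567 936
```

i.e. MMEW (234 samples) is the reference; SMIC needs 70 synthetic samples,
one extra going to Surprise, its rarest category; holding SMIC out leaves
567 real training samples, or 936 once every training dataset is topped up
to 234. The same numbers are available from the command line
(`crossmex plan --out plan.csv`).

A full synthetic run:

```sh
crossmex synth --preset desk --seed 1 --size 64 --out bench/
crossmex lodo-run --manifest bench/manifest.csv --held-out siteE --out run/
```

trains the CNN on four synthetic sites and reports Acc/UAR/UF1 on the
held-out fifth, writing per-epoch loss logs (including the attention range
H − L per source) and a metrics JSON per split.

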