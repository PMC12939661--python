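"""Batch Regularization Learning (BRL): attention-balance loss across sources.

When a classifier is trained on a composite of several source datasets it
tends to allocate its capacity unevenly across them. BRL makes that
allocation observable and penalizes the imbalance:

1. a sigmoid attention head scores every sample's feature vector,
   ``a_ij = sigmoid(W . x_ij + b)``, read as the sample's relative
   contribution to learning;
2. attention weights are averaged per source dataset within the batch,
   ``m_i = mean_j a_ij``;
3. the loss is the *range* of those group means, ``L_BRL = max_i m_i -
   min_i m_i``, zero iff the model attends to all sources equally;
4. the training objective is ``L_total = (1 - lambda) * L_CE + lambda *
   L_BRL`` with lambda in [0, 1) so the cross-entropy term never vanishes.

The attention weights feed only this loss — they do not rescale features or
logits. Gradients of L_BRL flow both into the head and back into the
features, which is what pushes the backbone toward domain-invariant
representations.

Everything here is plain NumPy and backbone-agnostic; the trainer wires the
gradients into its own backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass
class AttentionHead:
    """Affine + sigmoid scoring head: a = sigmoid(weight . x + bias)."""

    weight: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float).ravel()
        if not np.all(np.isfinite(self.weight)) or not np.isfinite(self.bias):
            raise ValueError("attention head parameters must be finite")

    @property
    def dim(self) -> int:
        return self.weight.size


def init_head(dim: int, seed: int = 0, scale: float = 0.01) -> AttentionHead:
    """Gaussian-initialized head (sd ``scale``), zero bias."""
    rng = np.random.default_rng(seed)
    return AttentionHead(weight=rng.normal(0.0, scale, size=dim), bias=0.0)


@dataclass
class LossBreakdown:
    """Per-batch (or per-epoch) decomposition of the composite objective."""

    l_ce: float
    l_brl: float
    lambda_weight: float
    group_means: dict[str, float] = field(default_factory=dict)

    @property
    def l_total(self) -> float:
        return (1.0 - self.lambda_weight) * self.l_ce + self.lambda_weight * self.l_brl


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def attention_weights(features: np.ndarray, head: AttentionHead) -> np.ndarray:
    """Per-sample attention a_ij = sigmoid(W . x_ij + b), strictly in (0, 1)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != head.dim:
        raise ValueError(
            f"feature dim {features.shape[1]} does not match head dim {head.dim}"
        )
    return _sigmoid(features @ head.weight + head.bias)


def group_mean_attention(weights: Sequence[float],
                         groups: Sequence[str]) -> dict[str, float]:
    """Mean attention weight per source dataset present in the batch."""
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("empty batch")
    if len(groups) != weights.size:
        raise ValueError("one group label required per weight")
    means: dict[str, float] = {}
    groups_arr = np.asarray(groups)
    for g in dict.fromkeys(groups):          # preserve first-appearance order
        means[g] = float(weights[groups_arr == g].mean())
    return means


def brl_loss(group_means: Mapping[str, float]) -> float:
    """Range (max - min) of the per-source mean attention weights.

    Zero when all groups receive equal mean attention, and zero for a
    single-source batch (max == min).
    """
    if not group_means:
        raise ValueError("brl_loss requires at least one group mean")
    vals = np.fromiter(group_means.values(), dtype=float)
    return float(vals.max() - vals.min())


def total_loss(l_ce: float, l_brl: float, lambda_weight: float) -> float:
    """Composite objective (1 - lambda) * L_CE + lambda * L_BRL."""
    if not (0.0 <= lambda_weight < 1.0):
        raise ValueError(f"lambda must be in [0, 1), got {lambda_weight}")
    return (1.0 - lambda_weight) * l_ce + lambda_weight * l_brl


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

def brl_loss_grad_wrt_weights(weights: np.ndarray,
                              groups: Sequence[str]) -> tuple[float, np.ndarray]:
    """L_BRL and its (sub)gradient with respect to the attention weights.

    d(max_i m_i - min_i m_i)/da_j is 1/n_H for samples in the arg-max group
    and -1/n_L for samples in the arg-min group (first group on ties, the
    standard max/min subgradient). A single-group batch gives loss 0 with a
    zero gradient.
    """
    weights = np.asarray(weights, dtype=float)
    means = group_mean_attention(weights, groups)
    loss = brl_loss(means)
    grad = np.zeros_like(weights)
    if len(means) < 2:
        return 0.0, grad
    names = list(means)
    vals = np.array([means[g] for g in names])
    g_hi = names[int(np.argmax(vals))]
    g_lo = names[int(np.argmin(vals))]
    if g_hi == g_lo:
        return loss, grad
    groups_arr = np.asarray(groups)
    hi_mask = groups_arr == g_hi
    lo_mask = groups_arr == g_lo
    grad[hi_mask] = 1.0 / hi_mask.sum()
    grad[lo_mask] = -1.0 / lo_mask.sum()
    return loss, grad


def brl_backward(features: np.ndarray, head: AttentionHead,
                 groups: Sequence[str]) -> dict:
    """Full backward pass of L_BRL through the sigmoid head.

    Returns the loss, per-sample attention, group means, and gradients with
    respect to the head weight, head bias, and the input features (the
    feature gradient is what regularizes the backbone).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    a = attention_weights(features, head)
    loss, da = brl_loss_grad_wrt_weights(a, groups)
    dz = da * a * (1.0 - a)                  # sigmoid derivative
    return {
        "loss": loss,
        "attention": a,
        "group_means": group_mean_attention(a, groups),
        "d_weight": features.T @ dz,
        "d_bias": float(dz.sum()),
        "d_features": np.outer(dz, head.weight),
    }


def descend_head(features: np.ndarray, groups: Sequence[str],
                 head: AttentionHead, lr: float = 1.0,
                 steps: int = 500) -> tuple[AttentionHead, list[float]]:
    """Plain gradient descent on L_BRL over the head parameters only.

    With features fixed, a constant head already achieves L_BRL = 0, so
    descent drives the loss toward zero; used as a sanity probe of the
    gradient path.
    """
    w = head.weight.copy()
    b = head.bias
    trace: list[float] = []
    for _ in range(steps):
        out = brl_backward(features, AttentionHead(w, b), groups)
        trace.append(out["loss"])
        w -= lr * out["d_weight"]
        b -= lr * out["d_bias"]
    return AttentionHead(w, b), trace


# ---------------------------------------------------------------------------
# Stratified batch sampler
# ---------------------------------------------------------------------------

def stratified_batches(groups: Sequence[str], batch_size: int,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """Index batches with every source dataset represented in every batch.

    Each source's indices are shuffled and split into ``n_batches`` nearly
    equal chunks (n_batches = ceil(N / batch_size)); batch b concatenates
    chunk b of every source. Every batch therefore holds at least one sample
    per source, provided each source has at least n_batches samples; smaller
    sources simply go missing from some batches (the range loss then runs
    over the groups present).
    """
    groups_arr = np.asarray(groups)
    n = groups_arr.size
    if n == 0:
        raise ValueError("empty index set")
    n_batches = max(1, int(np.ceil(n / batch_size)))
    per_source: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(groups):
        idx = np.flatnonzero(groups_arr == g)
        rng.shuffle(idx)
        per_source[g] = idx
    batches: list[list[int]] = [[] for _ in range(n_batches)]
    for idx in per_source.values():
        for b, chunk in enumerate(np.array_split(idx, n_batches)):
            batches[b].extend(chunk.tolist())
    out = []
    for b in batches:
        arr = np.array(b, dtype=int)
        rng.shuffle(arr)
        out.append(arr)
    return [b for b in out if b.size]
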