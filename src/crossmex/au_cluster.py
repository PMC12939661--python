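"""Prototypical AU patterns per emotion category via dominant-cluster K-means.

For each emotion category of the composite training set, the 17-dimensional
AU intensity vectors of all samples in that category are clustered with
K-means (Euclidean, raw 0-5 intensities — all dimensions share one scale).
The *dominant* cluster is the one with the largest membership; its centroid
(the arithmetic mean of the member vectors) is the category's prototypical
AU activation pattern and conditions synthetic-sample generation.

k is configurable (default 3: per-category sample counts are small). Ties
on membership break toward the cluster with the smaller within-cluster sum
of squares, then the lower cluster index. To make the result invariant to
the order of the input list, the vectors are put in a canonical
(lexicographic) order before clustering, so initialization depends only on
the seed and the multiset of vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .manifests import AU_COLUMNS, SampleRecord, as_au_vector

logger = logging.getLogger("crossmex")


@dataclass
class AUCentroid:
    """Dominant-cluster AU centroid for one emotion category."""

    category: str
    centroid: np.ndarray          # 17-dim, values in [0, 5]
    cluster_size: int
    total_samples: int            # M, size of the category's AU set
    k_used: int

    def __post_init__(self) -> None:
        self.centroid = as_au_vector(self.centroid)
        if self.cluster_size > self.total_samples:
            raise ValueError("cluster_size cannot exceed total_samples")


def collect_au_set(records: Sequence[SampleRecord], category: str) -> list[np.ndarray]:
    """The complete AU intensity set for one category, in manifest order."""
    au_set = [r.au for r in records if r.label == category and r.au is not None]
    if not au_set:
        raise ValueError(f"no AU-bearing record with category {category!r}")
    return au_set


def dominant_centroid(au_set: Sequence[np.ndarray], k: int, seed: int = 0,
                      category: str = "?") -> AUCentroid:
    """Centroid of the largest K-means cluster of an AU intensity set.

    Deterministic given the seed and invariant to input order. k-means++
    initialization with 10 restarts, tolerance 1e-6, at most 300 iterations.
    """
    X = np.stack([as_au_vector(v) for v in au_set])
    m = X.shape[0]
    if k < 1 or m < k:
        raise ValueError(f"need M >= k >= 1, got M={m}, k={k}")

    # canonical row order -> permutation-invariant initialization
    order = np.lexsort(X.T[::-1])
    Xs = X[order]

    if np.allclose(Xs, Xs[0]) and k > 1:
        logger.info("AU set for %s is degenerate (all vectors identical); "
                    "returning that vector as the centroid", category)
        return AUCentroid(category=category, centroid=Xs[0].copy(),
                          cluster_size=m, total_samples=m, k_used=k)

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-6,
                max_iter=300, random_state=seed % (2**32))
    assign = km.fit_predict(Xs)

    sizes = np.bincount(assign, minlength=k)
    wcss = np.array([
        float(((Xs[assign == c] - Xs[assign == c].mean(axis=0)) ** 2).sum())
        if sizes[c] else np.inf
        for c in range(k)
    ])
    best = max(range(k), key=lambda c: (sizes[c], -wcss[c], -c))
    members = Xs[assign == best]
    return AUCentroid(
        category=category,
        centroid=members.mean(axis=0),
        cluster_size=int(sizes[best]),
        total_samples=m,
        k_used=k,
    )


def category_centroids(records: Sequence[SampleRecord], categories: Sequence[str],
                       k: int, seed: int = 0) -> dict[str, AUCentroid]:
    """Dominant centroid per category, pooling the composite training set."""
    return {
        c: dominant_centroid(collect_au_set(records, c), k=k, seed=seed, category=c)
        for c in categories
    }


def write_centroid_report(centroids: dict[str, AUCentroid], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for c in centroids.values():
        rows.append({
            "category": c.category, "k_used": c.k_used,
            "cluster_size": c.cluster_size, "M": c.total_samples,
            **dict(zip(AU_COLUMNS, c.centroid)),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
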