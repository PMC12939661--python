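"""Augmentation planner: rebalance every dataset to the reference total.

The largest dataset in the count table is the *reference*; every other
dataset is topped up with synthetic samples until its total matches the
reference total. Within a dataset the shortfall is split as evenly as
possible across the emotion categories: every category gets
``floor(shortfall / C)``, and the ``shortfall mod C`` leftover units go one
each to the categories with the smallest original counts (ascending count,
ties broken by category order). The reference dataset receives nothing.

Generation itself is pluggable (`GeneratorInterface`); the bundled backend
lives in :mod:`crossmex.synthetic`. Generated samples are train-split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .au_cluster import AUCentroid
from .manifests import CountTable, SampleRecord


@dataclass
class AugmentationPlan:
    """Number of synthetic samples to add per (dataset, category) cell."""

    datasets: list[str]
    categories: list[str]
    reference_dataset: str
    reference_total: int
    additions: np.ndarray            # [dataset x category], non-negative ints
    original_totals: np.ndarray

    def __post_init__(self) -> None:
        self.additions = np.asarray(self.additions, dtype=int)
        if (self.additions < 0).any():
            raise ValueError("additions must be non-negative")

    def __getitem__(self, key: tuple[str, str]) -> int:
        d, c = key
        return int(self.additions[self.datasets.index(d), self.categories.index(c)])

    @property
    def per_dataset_totals(self) -> np.ndarray:
        return self.additions.sum(axis=1)

    @property
    def total_additions(self) -> int:
        return int(self.additions.sum())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [
            {"dataset": d, "category": c, "additions": int(self.additions[i, j])}
            for i, d in enumerate(self.datasets)
            for j, c in enumerate(self.categories)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def summary(self) -> dict:
        return {
            "reference_dataset": self.reference_dataset,
            "reference_total": self.reference_total,
            "per_dataset_additions": {
                d: int(t) for d, t in zip(self.datasets, self.per_dataset_totals)
            },
            "total_additions": self.total_additions,
        }

    def summary_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.summary(), indent=2))
        return path


def plan_augmentation(counts: CountTable) -> AugmentationPlan:
    """Even-split-with-rarest-remainder allocation toward the reference total.

    The reference dataset is the arg-max of the per-dataset totals (first on
    ties). An already balanced table yields the all-zero plan, which also
    makes the operation idempotent: planning on the post-augmentation table
    returns all zeros.
    """
    if not counts.datasets or not counts.categories:
        raise ValueError("count table must have at least one dataset and category")
    totals = counts.row_totals()
    ref_idx = int(np.argmax(totals))
    reference_total = int(totals[ref_idx])
    C = len(counts.categories)
    additions = np.zeros_like(counts.counts)
    for i, total in enumerate(totals):
        shortfall = reference_total - int(total)
        if shortfall <= 0:
            continue
        additions[i, :] = shortfall // C
        remainder = shortfall % C
        # leftover units to the rarest categories of this dataset
        order = np.lexsort((np.arange(C), counts.counts[i]))
        for j in order[:remainder]:
            additions[i, j] += 1
    return AugmentationPlan(
        datasets=list(counts.datasets),
        categories=list(counts.categories),
        reference_dataset=counts.datasets[ref_idx],
        reference_total=reference_total,
        additions=additions,
        original_totals=totals,
    )


def composite_training_size(counts: CountTable, held_out: str,
                            with_augmentation: bool = False) -> int:
    """Size of the leave-one-dataset-out composite training set.

    Without augmentation: the summed totals of all datasets but the held-out
    one. With augmentation every training dataset is topped up to the
    reference total, so the size is (n_datasets - 1) * reference_total.
    """
    if held_out not in counts.datasets:
        raise ValueError(f"unknown dataset {held_out!r}; have {counts.datasets}")
    totals = counts.row_totals()
    if with_augmentation:
        return (len(counts.datasets) - 1) * int(totals.max())
    keep = [i for i, d in enumerate(counts.datasets) if d != held_out]
    return int(totals[keep].sum())


class GeneratorInterface(Protocol):
    """Contract for synthetic-sample backends conditioned on an AU centroid."""

    def generate(self, dataset: str, category: str, centroid: AUCentroid,
                 count: int, seed: int) -> list[SampleRecord]:
        """Return ``count`` new train-split records flagged synthetic."""
        ...


def fulfill_plan(plan: AugmentationPlan, centroids: Mapping[str, AUCentroid],
                 generator: GeneratorInterface, seed: int = 0) -> list[SampleRecord]:
    """Drive the generator cell by cell; deterministic per seed.

    Raises if a category with positive additions lacks a centroid; a backend
    failure is re-raised with the (dataset, category) cell named.
    """
    out: list[SampleRecord] = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = iter(ss.generate_state(plan.additions.size) % (2**31))
    for i, d in enumerate(plan.datasets):
        for j, c in enumerate(plan.categories):
            count = int(plan.additions[i, j])
            cell_seed = int(next(cell_seeds))
            if count == 0:
                continue
            if c not in centroids:
                raise ValueError(f"no AU centroid for category {c!r} "
                                 f"(needed for dataset {d!r})")
            try:
                recs = generator.generate(d, c, centroids[c], count, cell_seed)
            except Exception as exc:
                raise RuntimeError(
                    f"generator failed for cell ({d!r}, {c!r}): {exc}") from exc
            if len(recs) != count:
                raise RuntimeError(
                    f"generator returned {len(recs)} records for cell "
                    f"({d!r}, {c!r}), expected {count}")
            bad = [r for r in recs if not r.synthetic or r.split != "train"]
            if bad:
                raise RuntimeError(
                    f"generator records for cell ({d!r}, {c!r}) must be "
                    "synthetic and train-split")
            out.extend(recs)
    return out
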