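"""Evaluation metrics for 3-class recognition: Acc, UAR, and UF1.

Accuracy is the overall fraction correct; unweighted average recall (UAR)
and unweighted F1 (UF1) average per-class recall / per-class F1 with equal
class weight, which makes them robust to the strong class imbalance of
composite micro-expression benchmarks:

    Acc = sum_c TP_c / N
    UAR = (1/C) * sum_c TP_c / N_c
    UF1 = (1/C) * sum_c 2*TP_c / (2*TP_c + FP_c + FN_c)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


class DegenerateGroundTruthError(ValueError):
    """A declared class has no ground-truth samples; UAR/UF1 undefined."""


@dataclass
class MetricsReport:
    """Confusion matrix (rows = true, columns = predicted) plus Acc/UAR/UF1."""

    classes: list[str]
    confusion: np.ndarray
    acc: float
    uar: float
    uf1: float
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def as_percent(self) -> dict[str, float]:
        """Acc/UAR/UF1 on the 0-100 scale, rounded to 2 decimals."""
        return {
            "acc": round(100 * self.acc, 2),
            "uar": round(100 * self.uar, 2),
            "uf1": round(100 * self.uf1, 2),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "acc": self.acc,
            "uar": self.uar,
            "uf1": self.uf1,
            "confusion": self.confusion.tolist(),
            "classes": self.classes,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def compute_metrics(true_labels: Sequence, pred_labels: Sequence,
                    classes: Sequence) -> MetricsReport:
    """Compute the confusion matrix and Acc/UAR/UF1.

    Every entry of ``classes`` must occur in ``true_labels``: a class with no
    ground-truth sample makes its recall 0/0 and is rejected rather than
    silently scored.

    A class that is merely never *predicted* is fine — its F1 is 0 when it has
    false negatives (denominator ``2*TP + FP + FN`` stays positive).
    """
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(pred_labels)} predicted"
        )
    if not true_labels:
        raise ValueError("cannot compute metrics on zero samples")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    for lab in true_labels:
        if lab not in index:
            raise ValueError(f"true label {lab!r} not in classes {classes}")
    missing = set(classes) - set(true_labels)
    if missing:
        raise DegenerateGroundTruthError(
            f"class(es) {sorted(map(str, missing))} absent from ground truth; "
            "UAR/UF1 would be undefined"
        )

    C = len(classes)
    confusion = np.zeros((C, C), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in classes {classes}")
        confusion[index[t], index[p]] += 1

    n = confusion.sum()
    tp = np.diag(confusion).astype(float)
    fn = confusion.sum(axis=1) - tp          # per true class
    fp = confusion.sum(axis=0) - tp          # per predicted class
    n_c = confusion.sum(axis=1).astype(float)

    recall = tp / n_c
    f1 = 2 * tp / (2 * tp + fp + fn)         # denominator > 0: every class has N_c >= 1

    return MetricsReport(
        classes=classes,
        confusion=confusion,
        acc=float(tp.sum() / n),
        uar=float(recall.mean()),
        uf1=float(f1.mean()),
        per_class_recall=recall,
        per_class_f1=f1,
    )
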