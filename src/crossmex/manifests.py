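"""Sample manifests, AU intensity tables, count tables, and run configuration.

This module holds the shared data model for the toolkit: one
:class:`SampleRecord` per micro-expression sample, a :class:`CountTable` of
per-dataset x per-category sample counts, 17-dimensional facial Action Unit
(AU) intensity vectors in the OpenFace ``AU*_r`` column layout, and the
:class:`RunConfig` that parameterizes training runs.

Emotion labels use the three-category convention common in composite
micro-expression benchmarks: ``Positive``, ``Negative``, ``Surprise``.
Raw dataset labels (happiness, disgust, repression, ...) must be mapped to
these three categories before a manifest validates; see
:data:`DEFAULT_LABEL_MAP` and :func:`map_raw_labels`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("crossmex")

#: The three emotion categories, in canonical order.
LABELS: tuple[str, ...] = ("Positive", "Negative", "Surprise")

#: AU identifiers reported as intensity regressors by OpenFace, in fixed order.
AU_IDS: tuple[int, ...] = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45)

#: Column names of the OpenFace intensity table dialect.
AU_COLUMNS: tuple[str, ...] = tuple(f"AU{k:02d}_r" for k in AU_IDS)

#: Intensity range of the OpenFace AU regressors.
AU_RANGE: tuple[float, float] = (0.0, 5.0)

MANIFEST_COLUMNS = ("sample_id", "dataset", "label", "image_path", "flow_path", "split")

#: Default raw-label -> 3-class mapping. Raw labels not present here are
#: excluded from the manifest (with a logged count) rather than guessed.
DEFAULT_LABEL_MAP: dict[str, str] = {
    "happiness": "Positive",
    "happy": "Positive",
    "positive": "Positive",
    "disgust": "Negative",
    "repression": "Negative",
    "anger": "Negative",
    "fear": "Negative",
    "sadness": "Negative",
    "contempt": "Negative",
    "tense": "Negative",
    "negative": "Negative",
    "surprise": "Surprise",
}


class ManifestFormatError(ValueError):
    """A manifest or AU table is structurally malformed (missing columns...)."""


class ManifestValidationError(ValueError):
    """A manifest parses but violates a record invariant."""


# ---------------------------------------------------------------------------
# AU vectors
# ---------------------------------------------------------------------------

def as_au_vector(values: Sequence[float] | np.ndarray, *, clip: bool = True) -> np.ndarray:
    """Validate (and optionally clip) a 17-dim AU intensity vector.

    Values are on the OpenFace 0-5 intensity scale, ordered as :data:`AU_IDS`.
    Out-of-range values are clipped to [0, 5] with a logged warning; pass
    ``clip=False`` to raise instead.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(AU_IDS),):
        raise ManifestValidationError(
            f"AU vector must have {len(AU_IDS)} entries, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ManifestValidationError("AU vector contains non-finite values")
    lo, hi = AU_RANGE
    if arr.min() < lo or arr.max() > hi:
        if not clip:
            raise ManifestValidationError("AU intensities outside [0, 5]")
        logger.warning(
            "AU intensities outside [0, 5] clipped (min=%.3f max=%.3f)",
            arr.min(), arr.max(),
        )
        arr = np.clip(arr, lo, hi)
    return arr


# ---------------------------------------------------------------------------
# Sample records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """One micro-expression sample of a (possibly composite) training set.

    At least one of ``image_ref`` / ``flow_ref`` / ``au`` must be present:
    a record with no usable input modality is rejected.
    """

    sample_id: str
    source_dataset: str
    label: str
    image_ref: str | None = None
    flow_ref: str | None = None
    au: np.ndarray | None = None
    split: str = "train"
    synthetic: bool = False

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ManifestValidationError(
                f"record {self.sample_id!r}: unknown label {self.label!r} "
                f"(raw labels must be mapped to {LABELS} first)"
            )
        if self.split not in ("train", "test"):
            raise ManifestValidationError(
                f"record {self.sample_id!r}: split must be train/test, got {self.split!r}"
            )
        if self.image_ref is None and self.flow_ref is None and self.au is None:
            raise ManifestValidationError(
                f"record {self.sample_id!r}: needs at least one of image/flow/AU"
            )
        if self.au is not None:
            object.__setattr__(self, "au", as_au_vector(self.au))

    def with_au(self, au: Sequence[float]) -> "SampleRecord":
        return replace(self, au=np.asarray(au, dtype=float))


def map_raw_labels(raw_labels: Iterable[str],
                   mapping: Mapping[str, str] | None = None) -> tuple[list[str | None], int]:
    """Map raw emotion labels to the 3-class scheme.

    Returns the mapped labels (``None`` where a raw label is not covered by
    the mapping) and the count of excluded labels, which is also logged.
    """
    mapping = DEFAULT_LABEL_MAP if mapping is None else mapping
    out: list[str | None] = []
    excluded = 0
    for raw in raw_labels:
        mapped = mapping.get(str(raw).strip().lower())
        if mapped is None and str(raw) in LABELS:
            mapped = str(raw)  # already 3-class
        if mapped is None:
            excluded += 1
        out.append(mapped)
    if excluded:
        logger.info("label mapping excluded %d record(s) with unmapped raw labels", excluded)
    return out, excluded


# ---------------------------------------------------------------------------
# Manifest I/O (CSV, UTF-8, comma separated, one header row)
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path, resolve_paths: bool = True) -> list[SampleRecord]:
    """Read a sample manifest CSV into validated :class:`SampleRecord` s.

    Image/flow paths stored relative in the file are resolved against the
    manifest's directory unless ``resolve_paths=False``.
    """
    base = Path(path).parent

    def _resolve(p: str) -> str | None:
        if not p:
            return None
        if resolve_paths and not Path(p).is_absolute():
            return str(base / p)
        return p

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"manifest {path}: missing column(s) {missing}")
    ids = df["sample_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
    if dupes:
        raise ManifestValidationError(f"manifest {path}: duplicate sample_id(s) {dupes[:5]}")
    records = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(SampleRecord(
                sample_id=row.sample_id,
                source_dataset=row.dataset,
                label=row.label,
                image_ref=_resolve(row.image_path),
                flow_ref=_resolve(row.flow_path),
                split=row.split or "train",
                synthetic=str(getattr(row, "synthetic", "")).strip() in ("1", "True", "true"),
            ))
        except ManifestValidationError as exc:
            raise ManifestValidationError(f"manifest {path}, row {rownum}: {exc}") from exc
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> Path:
    """Write a manifest CSV; paths under the manifest's directory are stored
    relative to it, so a benchmark directory is relocatable."""
    path = Path(path)
    base = path.parent.resolve()

    def _relativize(p: str | None) -> str:
        if not p:
            return ""
        try:
            return str(Path(p).resolve().relative_to(base))
        except ValueError:
            return p

    df = pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "dataset": [r.source_dataset for r in records],
        "label": [r.label for r in records],
        "image_path": [_relativize(r.image_ref) for r in records],
        "flow_path": [_relativize(r.flow_ref) for r in records],
        "split": [r.split for r in records],
        "synthetic": [int(r.synthetic) for r in records],
    })
    df.to_csv(path, index=False)
    return path


def read_au_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read an OpenFace-dialect AU intensity table keyed by sample_id.

    The table must carry all 17 ``AU*_r`` intensity columns; values are
    clipped to [0, 5] with a logged warning when out of range.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ManifestFormatError(f"AU table {path}: missing sample_id column")
    missing = [c for c in AU_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"AU table {path}: missing AU column(s) {missing}")
    block = df[list(AU_COLUMNS)]
    try:
        values = block.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ManifestFormatError(f"AU table {path}: non-numeric AU cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise ManifestFormatError(f"AU table {path}: non-finite AU cell")
    return {
        str(sid): as_au_vector(row)
        for sid, row in zip(df["sample_id"].astype(str), values)
    }


def write_au_table(au_map: Mapping[str, np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    rows = {sid: as_au_vector(v) for sid, v in au_map.items()}
    df = pd.DataFrame([{"sample_id": sid, **dict(zip(AU_COLUMNS, v))} for sid, v in rows.items()])
    df.to_csv(path, index=False)
    return path


def attach_au(records: Sequence[SampleRecord], au_map: Mapping[str, np.ndarray]) -> list[SampleRecord]:
    """Join AU vectors onto records by sample_id; records without AU stay as-is."""
    return [r.with_au(au_map[r.sample_id]) if r.sample_id in au_map else r for r in records]


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Per-dataset x per-category sample counts."""

    datasets: list[str]
    categories: list[str] = field(default_factory=lambda: list(LABELS))
    counts: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.datasets), len(self.categories)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.datasets)} datasets x {len(self.categories)} categories"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, key: tuple[str, str]) -> int:
        d, c = key
        return int(self.counts[self.datasets.index(d), self.categories.index(c)])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.counts, index=self.datasets, columns=self.categories)\
            .rename_axis("dataset").to_csv(path)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, index_col=0)
        return cls(datasets=list(df.index), categories=list(df.columns),
                   counts=df.to_numpy(dtype=int))


def count_table_from_manifest(records: Sequence[SampleRecord],
                              datasets: Sequence[str] | None = None,
                              categories: Sequence[str] = LABELS) -> CountTable:
    """Tally records into a dataset x category count table.

    Dataset order defaults to first appearance in the manifest; an empty
    manifest yields an empty (or all-zero, if datasets given) table.
    """
    if datasets is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.source_dataset, None)
        datasets = list(seen)
    counts = np.zeros((len(datasets), len(categories)), dtype=int)
    d_idx = {d: i for i, d in enumerate(datasets)}
    c_idx = {c: i for i, c in enumerate(categories)}
    for r in records:
        counts[d_idx[r.source_dataset], c_idx[r.label]] += 1
    return CountTable(datasets=list(datasets), categories=list(categories), counts=counts)


#: Published per-category sample counts of the five spontaneous
#: micro-expression benchmarks (Positive, Negative, Surprise).
BENCHMARK_COUNTS = CountTable(
    datasets=["SMIC", "CASME", "CASME II", "SAMM", "MMEW"],
    counts=np.array([
        [51, 70, 43],    # SMIC    -> 164
        [9, 53, 21],     # CASME   -> 83
        [32, 72, 25],    # CASME II-> 129
        [26, 80, 15],    # SAMM    -> 121
        [36, 109, 89],   # MMEW    -> 234
    ]),
)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Training-run configuration.

    Defaults follow the published operating point: composite loss weight
    lambda=0.5, 100 epochs with the balance regularizer activated after
    epoch 50, Adam-style optimizer at lr 2e-4 with weight decay 5e-4,
    faces cropped to 224x224. Desk-scale experiments override epochs and
    image_size explicitly.
    """

    lambda_weight: float = 0.5
    epochs: int = 100
    brl_start_epoch: int = 50
    learning_rate: float = 2e-4
    weight_decay: float = 5e-4
    batch_size: int = 32
    seed: int = 0
    kmeans_k: int = 3
    image_size: int = 224

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_weight < 1.0):
            raise ValueError(
                f"lambda_weight must be in [0, 1) so cross-entropy keeps non-zero "
                f"weight; got {self.lambda_weight}"
            )
        if self.brl_start_epoch > self.epochs:
            raise ValueError("brl_start_epoch must be <= epochs")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))
        return path
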