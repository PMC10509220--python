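"""Dataset representation, validation/training split, and labeled/unlabeled pools.

The active-learning emulation works with *pseudo-unlabeled* data: every sample
carries a true class, but that class is concealed from the learner and is only
revealed through the auto-labeling oracle when a sample is queried.  Concealment
is enforced by interface discipline — iterating a :class:`Dataset` or a pool
yields images and metadata but never a class label; the only routes to a label
are :meth:`Dataset.oracle_label` (the oracle / evaluation side) and
:func:`oracle_reveal` (the query path, which also moves the sample between
pools and counts the query).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image


class Label(str, Enum):
    """The two classes: slices crossing the left pulmonary artery orthogonally
    through its widest point (*included*) versus all others (*excluded*)."""

    INCLUDED = "included"
    EXCLUDED = "excluded"

    @classmethod
    def coerce(cls, value: "Label | str") -> "Label":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().lower())


# class index convention used by the classifier head: 0 = excluded, 1 = included
LABEL_TO_INDEX = {Label.EXCLUDED: 0, Label.INCLUDED: 1}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}


@dataclass(frozen=True)
class Sample:
    """One scan slice: an image plus its raw acquisition-metadata vector.

    Deliberately label-free; the class lives behind the dataset's oracle.
    """

    sample_id: str
    image: np.ndarray
    metadata_raw: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.image).ndim not in (2, 3):
            raise ValueError("sample image must be a 2-D (or multi-channel 3-D) array")


class Dataset:
    """A two-class collection of :class:`Sample` with oracle-gated labels."""

    def __init__(self, samples: Sequence[Sample], labels: Mapping[str, Label | str]):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique within a dataset")
        coerced = {sid: Label.coerce(lab) for sid, lab in labels.items()}
        missing = set(ids) - set(coerced)
        if missing:
            raise ValueError(f"samples without a class label: {sorted(missing)[:5]}")
        self._samples = {s.sample_id: s for s in samples}
        self._labels = {sid: coerced[sid] for sid in ids}

    def __len__(self) -> int:
        return len(self._samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self._samples.values())

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._samples

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self._samples)

    def get(self, sample_id: str) -> Sample:
        return self._samples[sample_id]

    def oracle_label(self, sample_id: str) -> Label:
        """Reveal the true class of one sample.

        This is the auto-labeling oracle's door: the query path and the
        evaluation of the (label-known) validation holdout go through here;
        ordinary data iteration never does.
        """
        if sample_id not in self._labels:
            raise KeyError(f"unknown sample_id {sample_id!r}")
        return self._labels[sample_id]

    def ids_with_label(self, label: Label | str) -> list[str]:
        """Oracle-side listing of one class, used by the stratified splitter."""
        label = Label.coerce(label)
        return sorted(sid for sid, lab in self._labels.items() if lab == label)

    def class_counts(self) -> dict[Label, int]:
        counts = {Label.INCLUDED: 0, Label.EXCLUDED: 0}
        for lab in self._labels.values():
            counts[lab] += 1
        return counts


@dataclass(frozen=True)
class SplitResult:
    """Partition of a dataset into a class-balanced validation holdout and a
    training pool (everything else)."""

    validation: frozenset[str]
    training_pool: frozenset[str]

    def __post_init__(self) -> None:
        if self.validation & self.training_pool:
            raise ValueError("validation and training pool overlap")

    def to_json(self) -> str:
        return json.dumps(
            {"validation": sorted(self.validation), "training_pool": sorted(self.training_pool)}
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitResult":
        obj = json.loads(text)
        return cls(frozenset(obj["validation"]), frozenset(obj["training_pool"]))


@dataclass(frozen=True)
class PoolState:
    """The evolving labeled/unlabeled partition of the training pool.

    ``query_count`` counts oracle reveals after initialization, so it always
    equals ``len(labeled) - initial_size``.
    """

    labeled: frozenset[str]
    unlabeled: frozenset[str]
    revealed_labels: Mapping[str, Label]
    query_count: int
    initial_size: int
    _oracle: Callable[[str], Label] = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.labeled & self.unlabeled:
            raise ValueError("labeled and unlabeled pools overlap")
        if set(self.revealed_labels) != set(self.labeled):
            raise ValueError("revealed_labels must cover exactly the labeled pool")
        if self.query_count != len(self.labeled) - self.initial_size:
            raise ValueError("query_count inconsistent with pool sizes")

    def to_json(self) -> str:
        return json.dumps(
            {
                "labeled": sorted(self.labeled),
                "unlabeled": sorted(self.unlabeled),
                "revealed_labels": {k: v.value for k, v in sorted(self.revealed_labels.items())},
                "query_count": self.query_count,
                "initial_size": self.initial_size,
            }
        )

    @classmethod
    def from_json(cls, text: str, oracle: Callable[[str], Label]) -> "PoolState":
        obj = json.loads(text)
        return cls(
            labeled=frozenset(obj["labeled"]),
            unlabeled=frozenset(obj["unlabeled"]),
            revealed_labels={k: Label(v) for k, v in obj["revealed_labels"].items()},
            query_count=obj["query_count"],
            initial_size=obj["initial_size"],
            _oracle=oracle,
        )


def split_dataset(dataset: Dataset, per_class_cap: int, seed: int) -> SplitResult:
    """Withhold a class-balanced validation set; the rest is the training pool.

    The per-class validation count is ``min(per_class_cap, floor(min(|E|,|I|)/2))``:
    half of the smaller class, capped (e.g. at 50 scans per class), so the
    holdout is balanced without starving the queryable pool.  Selection is
    uniform without replacement under ``seed``.
    """
    if per_class_cap < 1:
        raise ValueError("per_class_cap must be >= 1")
    included = dataset.ids_with_label(Label.INCLUDED)
    excluded = dataset.ids_with_label(Label.EXCLUDED)
    if not included or not excluded:
        raise ValueError("split undefined: both classes must be non-empty")
    k = min(per_class_cap, min(len(included), len(excluded)) // 2)
    if k < 1:
        raise ValueError("split undefined: smaller class too small to hold out half a sample")
    rng = np.random.default_rng(seed)
    val_inc = rng.choice(included, size=k, replace=False)
    val_exc = rng.choice(excluded, size=k, replace=False)
    validation = frozenset(val_inc) | frozenset(val_exc)
    training = frozenset(dataset.sample_ids) - validation
    return SplitResult(validation=validation, training_pool=training)


def initialize_labeled(dataset: Dataset, split: SplitResult, n: int, seed: int) -> PoolState:
    """Seed the labeled pool with ``n`` uniformly chosen training samples.

    ``n = 1`` is the active-learning start; ``n = |training pool|`` is the
    fully-supervised configuration (nothing left to query).
    """
    pool_ids = sorted(split.training_pool)
    if not 1 <= n <= len(pool_ids):
        raise ValueError(f"n must be in [1, {len(pool_ids)}], got {n}")
    rng = np.random.default_rng(seed)
    chosen = frozenset(rng.choice(pool_ids, size=n, replace=False))
    revealed = {sid: dataset.oracle_label(sid) for sid in chosen}
    return PoolState(
        labeled=chosen,
        unlabeled=frozenset(pool_ids) - chosen,
        revealed_labels=revealed,
        query_count=0,
        initial_size=n,
        _oracle=dataset.oracle_label,
    )


def oracle_reveal(pool: PoolState, sample_id: str) -> PoolState:
    """Query one unlabeled sample: reveal its class and move it to the labeled
    pool, incrementing the query count.  Returns a new :class:`PoolState`."""
    if sample_id not in pool.unlabeled:
        raise KeyError(f"sample {sample_id!r} is not in the unlabeled pool")
    revealed = dict(pool.revealed_labels)
    revealed[sample_id] = pool._oracle(sample_id)
    return replace(
        pool,
        labeled=pool.labeled | {sample_id},
        unlabeled=pool.unlabeled - {sample_id},
        revealed_labels=revealed,
        query_count=pool.query_count + 1,
    )


# ---------------------------------------------------------------------------
# dataset manifest I/O


def write_manifest(dataset: Dataset, out_dir: str | Path, image_format: str = "npy") -> Path:
    """Write ``manifest.csv`` plus one image file per sample.

    ``image_format='npy'`` is lossless; ``'png'`` rescales each image to 8-bit
    grayscale (adequate for display-range data).
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in dataset:
        rel = f"images/{sample.sample_id}.{image_format}"
        img = np.asarray(sample.image)
        if image_format == "npy":
            np.save(out_dir / rel, img)
        elif image_format == "png":
            lo, hi = float(img.min()), float(img.max())
            scaled = np.zeros_like(img, dtype=float) if hi == lo else (img - lo) / (hi - lo)
            Image.fromarray((scaled * 255).astype(np.uint8)).save(out_dir / rel)
        else:
            raise ValueError(f"unsupported image_format {image_format!r}")
        row = {
            "sample_id": sample.sample_id,
            "image_path": rel,
            "label": dataset.oracle_label(sample.sample_id).value,
        }
        for j, value in enumerate(np.asarray(sample.metadata_raw, dtype=float)):
            row[f"m_{j}"] = value
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest_path: str | Path) -> Dataset:
    """Load a dataset written by :func:`write_manifest` (or hand-built in the
    same CSV layout: sample_id, image_path, label, m_0..m_{M-1})."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype={"sample_id": str})
    meta_cols = sorted(
        (c for c in df.columns if c.startswith("m_")), key=lambda c: int(c.split("_")[1])
    )
    samples, labels = [], {}
    for row in df.itertuples(index=False):
        path = base / getattr(row, "image_path")
        if path.suffix == ".npy":
            img = np.load(path)
        else:
            img = np.asarray(Image.open(path), dtype=float)
        meta = np.array([getattr(row, c) for c in meta_cols], dtype=float)
        samples.append(Sample(sample_id=row.sample_id, image=img, metadata_raw=meta))
        labels[row.sample_id] = Label.coerce(row.label)
    return Dataset(samples, labels)
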