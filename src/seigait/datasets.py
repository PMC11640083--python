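"""Labeled SEI dataset assembly: 8:1:1 splits, oversampling, per-class partitions.

The severity classes are heavily imbalanced (healthy subjects dominate and
the mild class is the smallest), so two dataset variants exist alongside
the raw one: a balanced variant in which randomly chosen minority-class
images are duplicated until every class matches the majority count, and a
reduced key-frame variant produced upstream.  Splitting is an 8:1:1
train/validation/test partition by seeded random sampling at the level of
individual SEIs.

Oversampling BEFORE splitting (the order used for the balanced-dataset
replication experiment) lets duplicates of one image land on both sides of
the train/test boundary and therefore inflates test accuracy; the default
for new work is to balance the training subset only, after splitting.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from seigait.pose import CLASSES

__all__ = [
    "SEIRecord",
    "DatasetSplit",
    "split_dataset",
    "oversample_balance",
    "balance_training_split",
    "per_class_partitions",
    "records_from_seis",
    "write_dataset_index",
]


@dataclass(frozen=True)
class SEIRecord:
    """One labeled SEI with provenance; ``duplicate_of`` marks oversampled copies."""

    record_id: str
    label: str
    image: object = None  # ndarray, SkeletonEnergyImage, or a path reference
    video_id: str = ""
    segment_id: str = ""
    subject_id: str = ""
    start_index: int = 0
    variant: str = "normal"
    duplicate_of: str | None = None

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"label {self.label!r} not one of {CLASSES}")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test record lists plus the split's provenance."""

    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)
    ratios: tuple[int, int, int] = (8, 1, 1)
    seed: int = 0

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def split_dataset(
    records: Sequence,
    ratios: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded uniform 8:1:1 partition of records into train/validation/test.

    Validation and test each receive ``floor(N / 10)`` records (for the
    default ratios); when N is not divisible by 10 the remainder bumps
    validation first, then test, by at most one each, and the rest stays in
    train.  The same seed reproduces the identical assignment.
    """
    n = len(records)
    total = sum(ratios)
    if n < total:
        raise ValueError(f"need at least {total} records to split, got {n}")
    unit = n // total
    n_val = unit * ratios[1]
    n_test = unit * ratios[2]
    remainder = n - unit * total
    if remainder >= 1:
        n_val += 1
    if remainder >= 2:
        n_test += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx = set(perm[:n_val].tolist())
    test_idx = set(perm[n_val : n_val + n_test].tolist())
    split = DatasetSplit(ratios=tuple(ratios), seed=seed)
    for i, rec in enumerate(records):
        if i in val_idx:
            split.validation.append(rec)
        elif i in test_idx:
            split.test.append(rec)
        else:
            split.train.append(rec)
    return split


def oversample_balance(records: Sequence[SEIRecord], seed: int = 0) -> list[SEIRecord]:
    """Duplicate random minority-class records until all classes match the max.

    Originals are all retained; each added record is a copy of a uniformly
    chosen (with replacement) record of its class, with ``duplicate_of`` set
    to the source's id.
    """
    by_class: dict[str, list[SEIRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    for label, recs in by_class.items():
        if not recs:
            raise ValueError(f"class {label!r} has no records to oversample from")
    if not by_class:
        raise ValueError("no records to balance")
    target = max(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    out = list(records)
    for label in sorted(by_class):
        recs = by_class[label]
        deficit = target - len(recs)
        for j, pick in enumerate(rng.integers(0, len(recs), size=deficit)):
            src = recs[int(pick)]
            out.append(
                replace(
                    src,
                    record_id=f"{src.record_id}#dup{j}",
                    duplicate_of=src.record_id,
                )
            )
    return out


def balance_training_split(split: DatasetSplit, seed: int = 0) -> DatasetSplit:
    """Oversample the training subset only, leaving validation/test untouched."""
    return DatasetSplit(
        train=oversample_balance(split.train, seed=seed),
        validation=list(split.validation),
        test=list(split.test),
        ratios=split.ratios,
        seed=split.seed,
    )


def per_class_partitions(
    records: Sequence,
) -> tuple[dict[str, list], dict[str, float]]:
    """Split a test set class by class, with size-proportional weights.

    The weights turn per-class accuracies into the pooled accuracy:
    ``sum_c w_c * acc_c == pooled accuracy`` exactly, for any predictions.
    """
    if not records:
        raise ValueError("test set is empty")
    partitions: dict[str, list] = {}
    for rec in records:
        partitions.setdefault(rec.label, []).append(rec)
    total = len(records)
    weights = {label: len(recs) / total for label, recs in partitions.items()}
    return partitions, weights


def records_from_seis(seis: Sequence, video_id: str = "") -> list[SEIRecord]:
    """Wrap SkeletonEnergyImage objects as dataset records."""
    out = []
    for i, sei in enumerate(seis):
        out.append(
            SEIRecord(
                record_id=f"{sei.segment_id}:{sei.variant}:{sei.start_index}",
                label=sei.label,
                image=sei.pixels,
                video_id=video_id,
                segment_id=sei.segment_id,
                start_index=sei.start_index,
                variant=sei.variant,
            )
        )
    return out


def write_dataset_index(split: DatasetSplit, path, image_paths=None) -> None:
    """CSV index (record_id, path, label, split, duplicate_of) of a split."""
    image_paths = image_paths or {}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "path", "label", "split", "duplicate_of"])
        for name, recs in (
            ("train", split.train),
            ("val", split.validation),
            ("test", split.test),
        ):
            for rec in recs:
                writer.writerow(
                    [
                        rec.record_id,
                        image_paths.get(rec.record_id, ""),
                        rec.label,
                        name,
                        rec.duplicate_of or "",
                    ]
                )


def class_counts(records: Sequence) -> Counter:
    """Convenience tally of labels (used by reports and tests)."""
    return Counter(rec.label for rec in records)
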