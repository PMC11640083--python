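"""Split arithmetic, oversampling, and per-class partition identities."""

import numpy as np
import pytest

from seigait.datasets import (
    SEIRecord,
    balance_training_split,
    class_counts,
    oversample_balance,
    per_class_partitions,
    split_dataset,
)
from seigait.pose import CLASSES


def _records(counts: dict[str, int]) -> list[SEIRecord]:
    out = []
    for label, n in counts.items():
        out.extend(
            SEIRecord(record_id=f"{label}{i}", label=label) for i in range(n)
        )
    return out


class TestSplitDataset:
    def test_balanced_dataset_row_arithmetic(self):
        records = list(range(23_580))
        split = split_dataset(records, seed=0)
        assert split.sizes == (18_864, 2_358, 2_358)

    def test_ten_records_split_8_1_1(self):
        assert split_dataset(list(range(10)), seed=1).sizes == (8, 1, 1)

    def test_partition_is_disjoint_and_complete(self):
        records = list(range(103))
        split = split_dataset(records, seed=3)
        pooled = split.train + split.validation + split.test
        assert sorted(pooled) == records
        assert sum(split.sizes) == 103

    def test_remainder_bumps_validation_then_test(self):
        # N = 101: floor gives 10/10, remainder 1 goes to validation
        assert split_dataset(list(range(101)), seed=0).sizes == (80, 11, 10)
        assert split_dataset(list(range(102)), seed=0).sizes == (80, 11, 11)

    def test_same_seed_reproduces_different_seed_reassigns(self):
        records = list(range(200))
        a = split_dataset(records, seed=5)
        b = split_dataset(records, seed=5)
        c = split_dataset(records, seed=6)
        assert a.test == b.test and a.train == b.train
        assert a.test != c.test
        assert a.sizes == c.sizes

    def test_fewer_than_ten_records_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(9)))


class TestOversampleBalance:
    def test_counts_equalized_to_maximum(self):
        records = _records({"normal": 10, "mild": 4, "moderate": 6, "severe": 8})
        balanced = oversample_balance(records, seed=0)
        counts = class_counts(balanced)
        assert all(counts[c] == 10 for c in CLASSES)
        assert len(balanced) == 40

    def test_duplicates_marked_and_originals_retained(self):
        records = _records({"normal": 5, "mild": 2, "moderate": 5, "severe": 5})
        balanced = oversample_balance(records, seed=0)
        originals = [r for r in balanced if r.duplicate_of is None]
        duplicates = [r for r in balanced if r.duplicate_of is not None]
        assert sorted(r.record_id for r in originals) == sorted(
            r.record_id for r in records
        )
        assert len(duplicates) == 3
        source_ids = {r.record_id for r in records if r.label == "mild"}
        assert all(d.duplicate_of in source_ids for d in duplicates)

    def test_already_balanced_is_identity(self):
        records = _records({c: 4 for c in CLASSES})
        assert oversample_balance(records, seed=1) == records

    def test_single_record_class_is_copied_as_needed(self):
        records = _records({"normal": 10, "mild": 1, "moderate": 10, "severe": 10})
        balanced = oversample_balance(records, seed=2)
        mild = [r for r in balanced if r.label == "mild"]
        assert len(mild) == 10
        assert sum(r.duplicate_of is not None for r in mild) == 9

    def test_deterministic_given_seed(self):
        records = _records({"normal": 9, "mild": 3, "moderate": 5, "severe": 7})
        assert oversample_balance(records, seed=4) == oversample_balance(records, seed=4)

    def test_train_only_mode_leaves_validation_and_test(self):
        records = _records({"normal": 40, "mild": 12, "moderate": 24, "severe": 24})
        split = split_dataset(records, seed=0)
        balanced = balance_training_split(split, seed=0)
        assert balanced.validation == split.validation
        assert balanced.test == split.test
        counts = class_counts(balanced.train)
        assert len(set(counts.values())) == 1


class TestPerClassPartitions:
    def test_weights_normalize_class_sizes(self):
        records = _records({"normal": 100, "mild": 50, "moderate": 50, "severe": 25})
        _, weights = per_class_partitions(records)
        assert weights["normal"] == pytest.approx(100 / 225)
        assert weights["mild"] == pytest.approx(50 / 225)
        assert weights["severe"] == pytest.approx(25 / 225)
        assert sum(weights.values()) == pytest.approx(1.0)

    def test_single_class_gets_weight_one(self):
        parts, weights = per_class_partitions(_records({"mild": 7}))
        assert list(parts) == ["mild"]
        assert weights == {"mild": 1.0}

    def test_weighted_per_class_accuracy_equals_pooled(self):
        rng = np.random.default_rng(0)
        records = _records({"normal": 80, "mild": 30, "moderate": 50, "severe": 40})
        preds = {r.record_id: rng.choice(CLASSES) for r in records}
        parts, weights = per_class_partitions(records)
        pooled = np.mean([preds[r.record_id] == r.label for r in records])
        weighted = sum(
            weights[c] * np.mean([preds[r.record_id] == r.label for r in parts[c]])
            for c in parts
        )
        assert weighted == pytest.approx(pooled, abs=1e-12)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            per_class_partitions([])
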