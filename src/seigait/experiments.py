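"""The four-experiment evaluation protocol over SEI datasets.

Experiment 1 trains every model variant on the (imbalanced) rolling-kernel
SEI dataset and scores the pooled test subset.  Experiment 2 repeats the
training on the much smaller key-frame SEI dataset.  Experiment 3 reuses
the Experiment 1 checkpoints unchanged and feeds the test subset class by
class, reporting plain and size-weighted averages of the per-class
accuracies -- a memorization probe, not a retraining.  Experiment 4
oversamples the dataset to class balance BEFORE splitting (the replication
order; duplicates may cross the train/test boundary, which is exactly why
train-only balancing is the package default elsewhere) and trains only the
best model of each family.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from seigait.classifiers import EvalReport, ModelSpec, build_model, evaluate
from seigait.datasets import (
    DatasetSplit,
    oversample_balance,
    per_class_partitions,
    split_dataset,
)
from seigait.training import TrainConfig, TrainResult, train

logger = logging.getLogger(__name__)

__all__ = ["ExperimentSpec", "ExperimentResult", "run_experiment", "DEFAULT_MODELS", "BEST_MODELS"]

#: All seven comparable variants.
DEFAULT_MODELS: tuple[tuple[str, str], ...] = (
    ("cnn", "5"),
    ("cnn", "6"),
    ("resnet", "18"),
    ("resnet", "34"),
    ("vit", "tiny"),
    ("vit", "small"),
    ("vit", "base"),
)

#: Best-of-family trio used by the balanced-dataset experiment.
BEST_MODELS: tuple[tuple[str, str], ...] = (("cnn", "5"), ("resnet", "18"), ("vit", "small"))


@dataclass(frozen=True)
class ExperimentSpec:
    """Which experiment to run, on which dataset variant, with which models."""

    id: int
    dataset_variant: str = "normal"  # normal | keyframe | balanced
    models: tuple[tuple[str, str], ...] = DEFAULT_MODELS
    seed: int = 0
    input_size: int = 224

    def __post_init__(self):
        if self.id not in (1, 2, 3, 4):
            raise ValueError("experiment id must be 1-4")
        if self.id == 2 and self.dataset_variant != "keyframe":
            raise ValueError("experiment 2 runs on the key-frame dataset")
        if self.id == 4 and self.dataset_variant != "balanced":
            raise ValueError("experiment 4 runs on the balanced dataset")


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    reports: dict[str, EvalReport] = field(default_factory=dict)
    train_results: dict[str, TrainResult] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, report in self.reports.items():
            (outdir / f"report_{name}.json").write_text(
                json.dumps(report.to_dict(), indent=1)
            )
            (outdir / f"report_{name}.txt").write_text(report.summary() + "\n")
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=1))


def run_experiment(
    spec: ExperimentSpec,
    records: Sequence,
    train_config: TrainConfig | None = None,
    model_overrides: dict | None = None,
    trained_models: dict | None = None,
) -> ExperimentResult:
    """Run one experiment on an assembled SEI record list.

    ``records`` is the dataset matching ``spec.dataset_variant`` -- the
    rolling-kernel records for experiments 1 and 3, the key-frame records
    for experiment 2, and the *unbalanced* rolling-kernel records for
    experiment 4 (the oversampling happens here, before splitting, to
    replicate that protocol).  ``trained_models`` lets experiment 3 reuse
    experiment 1's checkpoints; if omitted they are trained here with the
    same seed, which yields identical weights.  ``model_overrides`` forwards
    extra :class:`ModelSpec` fields (e.g. reduced CNN widths).
    """
    train_config = train_config or TrainConfig(seed=spec.seed)
    records = list(records)
    if spec.id == 4:
        records = oversample_balance(records, seed=spec.seed)
    split = split_dataset(records, seed=spec.seed)
    result = ExperimentResult(spec=spec)
    result.provenance = {
        "experiment": spec.id,
        "dataset_variant": spec.dataset_variant,
        "n_records": len(records),
        "split_sizes": split.sizes,
        "seed": spec.seed,
        "train_config": vars(train_config) | {},
        "reused_checkpoints": sorted(trained_models) if trained_models else [],
    }
    overrides = model_overrides or {}
    for family, variant in spec.models:
        name = f"{family}-{variant}"
        mspec = ModelSpec(family, variant, input_size=spec.input_size, **overrides)
        if trained_models and name in trained_models:
            model = trained_models[name]
        else:
            model = build_model(mspec, seed=spec.seed)
            result.train_results[name] = train(model, split, train_config)
        if spec.id == 3:
            partitions, weights = per_class_partitions(split.test)
            report = evaluate(model, split.test)
            # per-class supply is what evaluate reports through its
            # average / weighted-average accuracies; record the weights too
            result.provenance.setdefault("class_weights", {})[name] = weights
        else:
            report = evaluate(model, split.test)
        result.reports[name] = report
        logger.info("experiment %d %s: %.2f%%", spec.id, name, report.accuracy)
    return result
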