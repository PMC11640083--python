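"""Training protocol: AdamW, cross-entropy, patience-based early stopping.

Training runs with no fixed epoch count.  A minimum of 25 epochs guarantees
initial learning; after that, training stops as soon as the validation loss
has not improved for 20 consecutive epochs, and the retained weights are
those of the epoch with the lowest validation loss seen anywhere in the
run.  (On an early-stopped run that global best necessarily lies within the
final patience window.)  A configurable safety cap -- disabled semantics by
default at 500 epochs, logged loudly when hit -- guards against traces that
never plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from seigait.classifiers import Model, records_to_arrays
from seigait.datasets import DatasetSplit
from seigait.nn.layers import softmax_cross_entropy
from seigait.nn.optim import AdamW

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "EarlyStopper", "TrainResult", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the training protocol.

    Defaults: random weight initialization, AdamW, cross-entropy loss,
    learning rate 5e-5, batch size 64, at least 25 epochs, early stopping
    with patience 20 on the validation loss.
    """

    learning_rate: float = 5e-5
    batch_size: int = 64
    weight_decay: float = 0.01
    min_epochs: int = 25
    patience: int = 20
    max_epochs_cap: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.min_epochs < 1 or self.patience < 1:
            raise ValueError("min_epochs and patience must be positive")


class EarlyStopper:
    """Patience rule on a validation-loss trace, with a minimum-epoch floor.

    Feed one loss per epoch (1-based); ``update`` returns True when training
    should stop.  ``best_epoch`` tracks the global argmin (first occurrence),
    which is the checkpoint to retain.
    """

    def __init__(self, min_epochs: int = 25, patience: int = 20):
        self.min_epochs = min_epochs
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        self.epoch += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
        return (
            self.epoch >= self.min_epochs
            and self.epoch - self.best_epoch >= self.patience
        )


@dataclass
class TrainResult:
    model: Model
    best_epoch: int
    stopped_epoch: int
    curves: dict = field(default_factory=dict)  # per-epoch lists

    @property
    def best_val_loss(self) -> float:
        return self.curves["val_loss"][self.best_epoch - 1]


def _epoch_pass(model, x, y, optimizer, batch_size, rng):
    """One training epoch over shuffled batches; returns (loss, accuracy)."""
    order = rng.permutation(len(x))
    losses, correct = [], 0
    for i in range(0, len(order), batch_size):
        idx = order[i : i + batch_size]
        xb, yb = x[idx], y[idx]
        logits = model.forward(xb, training=True, rng=rng)
        loss, dlogits = softmax_cross_entropy(logits, yb)
        optimizer.zero_grad()
        model.backward(dlogits)
        optimizer.step()
        losses.append(loss * len(idx))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return sum(losses) / len(order), correct / len(order)


def _eval_pass(model, x, y, batch_size):
    logits = model.predict_logits(x, batch_size=batch_size)
    loss, _ = softmax_cross_entropy(logits, y)
    return loss, float((logits.argmax(axis=1) == y).mean())


def train(
    model: Model,
    splits: DatasetSplit,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Train a model on a dataset split under the early-stopping protocol.

    Fully seeded: the same seed, model and data reproduce identical curves
    and final weights.  Returns the model restored to its best-validation
    checkpoint, together with per-epoch loss/accuracy curves.
    """
    config = config or TrainConfig()
    if not splits.train:
        raise ValueError("training split is empty")
    if not splits.validation:
        raise ValueError("validation split is empty (early stopping monitors it)")
    rng = np.random.default_rng(config.seed)
    spec = model.spec
    x_tr, y_tr = records_to_arrays(splits.train, spec.input_size, spec.in_channels)
    x_va, y_va = records_to_arrays(splits.validation, spec.input_size, spec.in_channels)
    optimizer = AdamW(
        model.params(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    stopper = EarlyStopper(config.min_epochs, config.patience)
    curves = {k: [] for k in ("train_loss", "train_acc", "val_loss", "val_acc")}
    best_state = model.get_state()
    for epoch in range(1, config.max_epochs_cap + 1):
        tr_loss, tr_acc = _epoch_pass(
            model, x_tr, y_tr, optimizer, config.batch_size, rng
        )
        va_loss, va_acc = _eval_pass(model, x_va, y_va, config.batch_size)
        curves["train_loss"].append(tr_loss)
        curves["train_acc"].append(tr_acc)
        curves["val_loss"].append(va_loss)
        curves["val_acc"].append(va_acc)
        improved = va_loss < stopper.best_loss
        stop = stopper.update(va_loss)
        if improved:
            best_state = model.get_state()
        if stop:
            break
    else:
        logger.warning(
            "training hit the safety cap of %d epochs without exhausting "
            "patience; treat the result with suspicion",
            config.max_epochs_cap,
        )
    model.set_state(best_state)
    return TrainResult(
        model=model,
        best_epoch=stopper.best_epoch,
        stopped_epoch=stopper.epoch,
        curves=curves,
    )
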