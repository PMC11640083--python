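"""The seven shallow image classifiers and their evaluation reports.

Three families are compared on SEI classification: plain CNNs (5 or 6
convolutional blocks, each convolution followed by batch normalization and
dropout), residual networks at depths 18 and 34, and vision transformers in
the standard tiny/small/base dimension sets with 16-pixel patches.  All
take a 4-way softmax head (normal / mild / moderate / severe) and train
from random initialization -- no pretraining.

SEIs are grayscale; the CNN consumes them as one channel while the ResNet
and ViT replicate the channel to three to keep their conventional stems.
The CNN head pools globally before a 256-unit hidden layer, so parameter
counts grow strictly with depth within each family (cnn-5 < cnn-6 <
resnet-18 < resnet-34, vit-tiny < vit-small < vit-base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from seigait.nn.blocks import BasicBlock, VisionTransformerBackbone
from seigait.nn.layers import (
    BatchNorm2d,
    Conv2d,
    Dropout,
    GlobalAvgPool2d,
    Layer,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
)
from seigait.pose import CLASSES

__all__ = [
    "ModelSpec",
    "Model",
    "MODEL_VARIANTS",
    "build_model",
    "EvalReport",
    "evaluate",
    "records_to_arrays",
]

#: The (family, variant) pairs that are constructible.
MODEL_VARIANTS: tuple[tuple[str, str], ...] = (
    ("cnn", "5"),
    ("cnn", "6"),
    ("resnet", "18"),
    ("resnet", "34"),
    ("vit", "tiny"),
    ("vit", "small"),
    ("vit", "base"),
)

_VIT_DIMS = {  # dim, depth, heads, mlp_dim -- the standard tiny/small/base sets
    "tiny": (192, 12, 3, 768),
    "small": (384, 12, 6, 1536),
    "base": (768, 12, 12, 3072),
}
_RESNET_STAGES = {"18": (2, 2, 2, 2), "34": (3, 4, 6, 3)}


@dataclass(frozen=True)
class ModelSpec:
    """Which classifier to build and at what input geometry.

    ``input_size`` defaults to the conventional 224; smaller sizes are valid
    (ViT requires divisibility by the 16-pixel patch) and trade accuracy for
    speed.  ``cnn_channels`` overrides the per-block widths of the CNNs.
    """

    family: str
    variant: str
    num_classes: int = 4
    input_size: int = 224
    cnn_channels: tuple[int, ...] = (16, 32, 64, 128, 256, 512)
    cnn_hidden: int = 256
    dropout_conv: float = 0.25
    dropout_head: float = 0.5

    def __post_init__(self):
        if (self.family, self.variant) not in MODEL_VARIANTS:
            raise ValueError(
                f"unknown model {self.family}-{self.variant}; options: "
                + ", ".join(f"{f}-{v}" for f, v in MODEL_VARIANTS)
            )
        if self.family == "cnn" and self.input_size < 2 ** int(self.variant):
            raise ValueError(
                f"cnn-{self.variant} needs input_size >= {2 ** int(self.variant)} "
                "(one 2x2 pooling per block)"
            )

    @property
    def in_channels(self) -> int:
        return 1 if self.family == "cnn" else 3

    @property
    def name(self) -> str:
        return f"{self.family}-{self.variant}"


class Model:
    """A built network plus its spec; supports weight snapshot/restore."""

    def __init__(self, spec: ModelSpec, net: Layer):
        self.spec = spec
        self.net = net

    def params(self):
        return self.net.params()

    def num_params(self) -> int:
        return self.net.num_params()

    def forward(self, x, training=False, rng=None):
        return self.net.forward(x, training=training, rng=rng)

    def backward(self, grad):
        return self.net.backward(grad)

    def _batchnorms(self):
        return [l for l in _iter_layers(self.net) if isinstance(l, BatchNorm2d)]

    def get_state(self) -> dict:
        return {
            "params": [p.value.copy() for p in self.params()],
            "bn": [
                (bn.running_mean.copy(), bn.running_var.copy())
                for bn in self._batchnorms()
            ],
        }

    def set_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.value[...] = v
        for bn, (rm, rv) in zip(self._batchnorms(), state["bn"]):
            bn.running_mean[...] = rm
            bn.running_var[...] = rv

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size], training=False))
        return np.concatenate(outs)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_logits(x, batch_size).argmax(axis=1)


def _iter_layers(layer):
    yield layer
    for v in vars(layer).values():
        if isinstance(v, Layer):
            yield from _iter_layers(v)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Layer):
                    yield from _iter_layers(item)


def _build_cnn(spec: ModelSpec, rng) -> Layer:
    n_blocks = int(spec.variant)
    widths = spec.cnn_channels[:n_blocks]
    layers: list[Layer] = []
    in_ch = spec.in_channels
    for w in widths:
        layers += [
            Conv2d(in_ch, w, 3, rng=rng),
            BatchNorm2d(w),
            ReLU(),
            MaxPool2d(),
            Dropout(spec.dropout_conv),
        ]
        in_ch = w
    layers += [
        GlobalAvgPool2d(),
        Linear(in_ch, spec.cnn_hidden, rng=rng),
        ReLU(),
        Dropout(spec.dropout_head),
        Linear(spec.cnn_hidden, spec.num_classes, rng=rng),
    ]
    return Sequential(*layers)


def _build_resnet(spec: ModelSpec, rng) -> Layer:
    stages = _RESNET_STAGES[spec.variant]
    layers: list[Layer] = [
        Conv2d(spec.in_channels, 64, 7, stride=2, pad=3, rng=rng),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(),
    ]
    in_ch = 64
    for stage, n_blocks in enumerate(stages):
        out_ch = 64 * 2**stage
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(BasicBlock(in_ch, out_ch, stride=stride, rng=rng))
            in_ch = out_ch
    layers += [GlobalAvgPool2d(), Linear(in_ch, spec.num_classes, rng=rng)]
    return Sequential(*layers)


class _ViTNet(Layer):
    def __init__(self, spec: ModelSpec, rng):
        dim, depth, heads, mlp = _VIT_DIMS[spec.variant]
        self.backbone = VisionTransformerBackbone(
            spec.input_size, 16, spec.in_channels, dim, depth, heads, mlp, rng=rng
        )
        self.head = Linear(dim, spec.num_classes, rng=rng)

    def params(self):
        return self.backbone.params() + self.head.params()

    def forward(self, x, training=False, rng=None):
        return self.head.forward(self.backbone.forward(x, training, rng), training, rng)

    def backward(self, grad):
        return self.backbone.backward(self.head.backward(grad))


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Construct an untrained model with seeded random initialization."""
    rng = np.random.default_rng(seed)
    if spec.family == "cnn":
        net = _build_cnn(spec, rng)
    elif spec.family == "resnet":
        net = _build_resnet(spec, rng)
    else:
        net = _ViTNet(spec, rng)
    return Model(spec, net)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def records_to_arrays(
    records: Sequence,
    input_size: int,
    in_channels: int = 1,
    class_order: Sequence[str] = CLASSES,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack dataset records into (X, y): resized images and class indices.

    Networks see stroke intensity ``1 - pixel`` (figure positive on a zero
    background) rather than raw white-background gray levels; an almost-
    constant-bright input conditions training poorly.
    """
    from skimage.transform import resize

    label_idx = {label: i for i, label in enumerate(class_order)}
    xs, ys = [], []
    for rec in records:
        img = np.asarray(getattr(rec.image, "pixels", rec.image), dtype=np.float32)
        if img.shape != (input_size, input_size):
            img = resize(img, (input_size, input_size), anti_aliasing=True).astype(
                np.float32
            )
        xs.append(1.0 - img)
        ys.append(label_idx[rec.label])
    x = np.stack(xs)[:, None, :, :]
    if in_channels == 3:
        x = np.repeat(x, 3, axis=1)
    return x, np.asarray(ys, dtype=np.int64)


@dataclass
class EvalReport:
    """Accuracy, confusion matrix (rows = true class) and per-class metrics."""

    accuracy: float  # percent
    confusion: np.ndarray  # (4, 4) counts
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    per_class_accuracy: dict[str, float]  # percent, classes present in the data
    average_accuracy: float  # unweighted mean over present classes, percent
    weighted_average_accuracy: float  # size-weighted mean == pooled, percent
    n: int = 0
    class_order: tuple[str, ...] = CLASSES
    curves: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"overall accuracy: {self.accuracy:.2f}%  (n={self.n})",
            f"average / weighted-average per-class accuracy: "
            f"{self.average_accuracy:.2f}% / {self.weighted_average_accuracy:.2f}%",
            "class        prec    rec     f1      acc%    support",
        ]
        for i, label in enumerate(self.class_order):
            support = int(self.confusion[i].sum())
            if not support:
                continue
            lines.append(
                f"{label:<11}{self.precision[label]:7.3f}{self.recall[label]:8.3f}"
                f"{self.f1[label]:8.3f}{self.per_class_accuracy[label]:9.2f}"
                f"{support:9d}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class_accuracy": self.per_class_accuracy,
            "average_accuracy": self.average_accuracy,
            "weighted_average_accuracy": self.weighted_average_accuracy,
            "n": self.n,
        }


def evaluate(
    model: Model,
    records: Sequence,
    batch_size: int = 64,
    class_order: Sequence[str] = CLASSES,
) -> EvalReport:
    """Score a trained model on labeled records.

    The weighted average of per-class accuracies uses test-set class
    proportions as weights and therefore equals the pooled accuracy; the
    plain average treats all present classes equally.
    """
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    x, y = records_to_arrays(
        records, model.spec.input_size, model.spec.in_channels, class_order
    )
    pred = model.predict(x, batch_size=batch_size)
    labels = list(range(len(class_order)))
    conf = confusion_matrix(y, pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, pred, labels=labels, zero_division=0
    )
    row_sums = conf.sum(axis=1)
    present = row_sums > 0
    per_class = {
        class_order[i]: 100.0 * conf[i, i] / row_sums[i]
        for i in labels
        if present[i]
    }
    weights = row_sums[present] / row_sums.sum()
    accs = np.array([per_class[class_order[i]] for i in labels if present[i]])
    return EvalReport(
        accuracy=100.0 * np.trace(conf) / len(y),
        confusion=conf,
        precision={class_order[i]: float(prec[i]) for i in labels},
        recall={class_order[i]: float(rec[i]) for i in labels},
        f1={class_order[i]: float(f1[i]) for i in labels},
        per_class_accuracy=per_class,
        average_accuracy=float(accs.mean()),
        weighted_average_accuracy=float((accs * weights).sum()),
        n=len(y),
        class_order=tuple(class_order),
    )
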