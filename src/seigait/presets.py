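"""Canonical presets for desk-scale (CPU) runs.

The full protocol -- 224-pixel inputs, the published channel widths,
learning rate 5e-5 and open-ended epochs -- is sized for GPU training on
tens of thousands of images.  The reduced-budget preset keeps the same
architecture family and training rules but shrinks the problem to what a
single CPU core handles in minutes: 32-pixel inputs, thinner CNN widths,
lighter dropout (the full rates over-regularize a model this small), a
higher learning rate matched to the shorter schedule, and a tighter
early-stopping window.  Tests and the acceptance script use these presets
so results are reproducible at fixed cost.
"""

from __future__ import annotations

from seigait.classifiers import ModelSpec
from seigait.render import RenderConfig
from seigait.training import TrainConfig

__all__ = [
    "reduced_cnn5_spec",
    "reduced_train_config",
    "reduced_render_config",
]


def reduced_cnn5_spec(input_size: int = 32) -> ModelSpec:
    """The 5-block CNN sized for CPU training on small synthetic cohorts."""
    return ModelSpec(
        "cnn",
        "5",
        input_size=input_size,
        cnn_channels=(8, 16, 32, 64, 128),
        dropout_conv=0.1,
        dropout_head=0.25,
    )


def reduced_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(
        learning_rate=1e-3,
        batch_size=64,
        min_epochs=12,
        patience=8,
        max_epochs_cap=30,
        seed=seed,
    )


def reduced_render_config(canvas: int = 96) -> RenderConfig:
    """Small canvas with the same ~10% margin as the full-size geometry."""
    return RenderConfig(target_height=canvas * 0.9, canvas=(canvas, canvas))
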