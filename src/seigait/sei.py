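"""Skeleton Energy Image synthesis: rolling-kernel averaging and key frames.

A Skeleton Energy Image (SEI) is the pixel-wise arithmetic mean of a fixed
window of K consecutive skeleton images,

    E(i, j) = (1/K) * sum_{n=1..K} S_n(i, j),

with K = 17 frames by default -- at the 10 fps sampling rate roughly 1.5
gait cycles, enough for every limb to pass through its full swing.  Because
each skeleton frame is binary, the SEI's gray levels encode dwell time:
pixels a limb crosses briefly are light, pixels the trunk occupies
throughout are near-black.

A sequence of N >= K skeleton images yields N - K + 1 SEIs via a stride-1
rolling kernel, a cheap data amplification that shows every joint
trajectory from K different phase offsets.  A reduced "key-frame" variant
instead anchors windows only at frames whose inter-frame difference jumps
above 1.5x the running average of the preceding 10 differences (the first
frame is always a key frame); a key frame followed by fewer than 16 frames
-- or whose window covers a frame the pose filter rejected -- produces no
SEI.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from seigait.render import SkeletonImage

__all__ = [
    "SEIConfig",
    "SkeletonEnergyImage",
    "compute_sei",
    "rolling_sei",
    "frame_difference_series",
    "detect_key_frames",
    "keyframe_sei_sequences",
    "save_sei_png",
    "write_sei_index",
]


@dataclass(frozen=True)
class SEIConfig:
    """Kernel and key-frame constants.

    ``kernel``: frames averaged per SEI.  ``keyframe_window``: how many
    preceding inter-frame differences the key-frame rule averages over.
    ``keyframe_factor``: a frame is key when its difference strictly exceeds
    this multiple of that average.  ``keyframe_followers``: frames required
    after a key frame to fill its window (always ``kernel - 1``).
    """

    kernel: int = 17
    keyframe_window: int = 10
    keyframe_factor: float = 1.5
    keyframe_followers: int = 16

    def __post_init__(self):
        if self.kernel < 1:
            raise ValueError("kernel must be >= 1")
        if self.keyframe_followers != self.kernel - 1:
            raise ValueError("keyframe_followers must equal kernel - 1")


@dataclass(frozen=True)
class SkeletonEnergyImage:
    """Mean of one kernel window of skeleton images, with provenance."""

    pixels: np.ndarray
    segment_id: str = ""
    start_index: int = 0
    kernel: int = 17
    variant: str = "normal"  # "normal" | "keyframe"
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _stack(images: Sequence[SkeletonImage]) -> np.ndarray:
    shapes = {im.pixels.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"skeleton images have mismatched shapes: {shapes}")
    return np.stack([im.pixels for im in images])


def compute_sei(
    images: Sequence[SkeletonImage],
    config: SEIConfig | None = None,
    variant: str = "normal",
) -> SkeletonEnergyImage:
    """Average exactly one kernel's worth of skeleton images pixel-wise."""
    config = config or SEIConfig()
    if len(images) != config.kernel:
        raise ValueError(
            f"expected exactly {config.kernel} skeleton images, got {len(images)}"
        )
    stack = _stack(images)
    # baseline-subtracted mean: exact when all images are identical, and
    # better conditioned than a raw sum for near-constant stacks
    base = stack[0]
    mean = base + (stack - base).sum(axis=0) / len(images)
    first = images[0]
    return SkeletonEnergyImage(
        mean,
        segment_id=first.segment_id,
        start_index=first.frame_index,
        kernel=config.kernel,
        variant=variant,
    )


def rolling_sei(
    images: Sequence[SkeletonImage],
    config: SEIConfig | None = None,
    label: str = "",
) -> list[SkeletonEnergyImage]:
    """All N - K + 1 stride-1 kernel windows of a sequence, in order.

    Sequences shorter than the kernel were discarded upstream; hitting one
    here is a programming error, not data to be silently skipped.
    """
    config = config or SEIConfig()
    n, k = len(images), config.kernel
    if n < k:
        raise ValueError(
            f"sequence of {n} skeleton images is shorter than the kernel {k}; "
            "such segments are discarded during pre-processing"
        )
    _stack(images)  # validate shapes up front
    out = []
    # each window goes through compute_sei so rolling windows are
    # bit-identical to the key-frame variant's windows at the same start
    for m in range(n - k + 1):
        sei = compute_sei(images[m : m + k], config)
        out.append(
            SkeletonEnergyImage(
                sei.pixels,
                segment_id=sei.segment_id,
                start_index=sei.start_index,
                kernel=k,
                variant="normal",
                label=label,
            )
        )
    return out


def frame_difference_series(frames) -> np.ndarray:
    """Mean absolute grayscale difference between consecutive sampled frames.

    Accepts a FrameSequence or a plain list of 2-D rasters on a unit scale.
    Returns an array the length of the sequence; entry 0 is NaN (the first
    frame has no predecessor), entry t is the mean |frame_t - frame_{t-1}|.
    """
    rasters = getattr(frames, "frames", frames)
    if len(rasters) < 2:
        raise ValueError("differencing needs at least 2 frames")
    arrays = [np.asarray(f, dtype=float) for f in rasters]
    diffs = np.full(len(arrays), np.nan)
    for t in range(1, len(arrays)):
        if arrays[t].shape != arrays[t - 1].shape:
            raise ValueError(
                f"frame {t} shape {arrays[t].shape} != frame {t-1} shape "
                f"{arrays[t - 1].shape}"
            )
        diffs[t] = np.abs(arrays[t] - arrays[t - 1]).mean()
    return diffs


def detect_key_frames(diffs: np.ndarray, config: SEIConfig | None = None) -> list[int]:
    """Key-frame indices (0-based) from a difference series.

    Frame 0 is always a key frame.  Frame t >= 2 is key iff its difference
    strictly exceeds ``keyframe_factor`` times the mean of the previous up
    to ``keyframe_window`` differences (history truncated, at least one
    prior difference required -- so frame 1, whose difference has no
    predecessor, can never trigger the rule).
    """
    config = config or SEIConfig()
    diffs = np.asarray(diffs, dtype=float)
    keys = [0]
    for t in range(2, len(diffs)):
        lo = max(1, t - config.keyframe_window)
        history = diffs[lo:t]
        if diffs[t] > config.keyframe_factor * history.mean():
            keys.append(t)
    return keys


def keyframe_sei_sequences(
    key_frames: Sequence[int],
    skeleton_images: Mapping[int, SkeletonImage] | Sequence[SkeletonImage],
    config: SEIConfig | None = None,
    label: str = "",
) -> list[SkeletonEnergyImage]:
    """One SEI per key frame whose full window of followers survived filtering.

    ``skeleton_images`` maps the original (pre-filtering) frame index to its
    skeleton image; indices the pose filter rejected are simply absent, and
    any key-frame window touching a missing index yields no SEI.
    """
    config = config or SEIConfig()
    if not isinstance(skeleton_images, Mapping):
        skeleton_images = {im.frame_index: im for im in skeleton_images}
    out = []
    for k in key_frames:
        window = [skeleton_images.get(k + off) for off in range(config.kernel)]
        if any(im is None for im in window):
            continue
        sei = compute_sei(window, config, variant="keyframe")
        out.append(
            SkeletonEnergyImage(
                sei.pixels,
                segment_id=sei.segment_id,
                start_index=k,
                kernel=config.kernel,
                variant="keyframe",
                label=label,
            )
        )
    return out


def save_sei_png(sei: SkeletonEnergyImage, path) -> None:
    """8-bit grayscale PNG export with round-half-up quantization."""
    import imageio.v3 as iio

    data = np.floor(sei.pixels * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def write_sei_index(seis: Sequence[SkeletonEnergyImage], paths, index_path) -> None:
    """Sidecar CSV (segment_id, start_index, variant, label, path) for assembly."""
    with Path(index_path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["segment_id", "start_index", "variant", "label", "path"])
        for sei, p in zip(seis, paths):
            writer.writerow([sei.segment_id, sei.start_index, sei.variant, sei.label, p])
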