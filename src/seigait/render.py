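"""Centering/scaling of pose key points and rasterization of skeleton images.

A raw pose lives in the source video's pixel frame, where the subject's
apparent size and position vary with distance from the camera.  Each frame
is therefore normalized -- the 12 joints are isotropically scaled so their
vertical extent is exactly ``target_height`` pixels (default 360) and the
bounding-box center is moved to the canvas center -- before a headless
stick figure is traced through a fixed bone list.  Normalization makes the
raster invariant to where and how large the subject appeared, which is the
whole point: gray levels in the downstream energy image must come from
movement, not from framing.

Strokes are binary (dark 0.0 on white 1.0, no anti-aliasing): a pixel is
dark iff its center lies within ``line_width / 2`` of a bone segment.  That
keeps single-frame rasters two-valued, so intermediate gray levels in an
energy image can only arise from temporal averaging, and makes rendering
exactly symmetric under mirror poses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from seigait.pose import JointId, PoseFrame

logger = logging.getLogger(__name__)

__all__ = [
    "RenderConfig",
    "SkeletonImage",
    "BONES",
    "NormalizationError",
    "normalize_pose",
    "render_skeleton",
    "save_skeleton_png",
    "load_skeleton_png",
]

#: Bone connectivity of the headless 12-joint skeleton: arms, legs,
#: shoulder girdle, pelvis, and the two ipsilateral trunk edges.
BONES: tuple[tuple[JointId, JointId], ...] = (
    (JointId.RIGHT_SHOULDER, JointId.RIGHT_ELBOW),
    (JointId.RIGHT_ELBOW, JointId.RIGHT_WRIST),
    (JointId.LEFT_SHOULDER, JointId.LEFT_ELBOW),
    (JointId.LEFT_ELBOW, JointId.LEFT_WRIST),
    (JointId.RIGHT_HIP, JointId.RIGHT_KNEE),
    (JointId.RIGHT_KNEE, JointId.RIGHT_FOOT),
    (JointId.LEFT_HIP, JointId.LEFT_KNEE),
    (JointId.LEFT_KNEE, JointId.LEFT_FOOT),
    (JointId.RIGHT_SHOULDER, JointId.LEFT_SHOULDER),
    (JointId.RIGHT_HIP, JointId.LEFT_HIP),
    (JointId.RIGHT_SHOULDER, JointId.RIGHT_HIP),
    (JointId.LEFT_SHOULDER, JointId.LEFT_HIP),
)


class NormalizationError(ValueError):
    """Degenerate pose (zero vertical extent) cannot be height-normalized."""


@dataclass(frozen=True)
class RenderConfig:
    """Raster geometry: 360-px-tall figure centered on a 400x400 white canvas."""

    target_height: float = 360.0
    canvas: tuple[int, int] = (400, 400)  # (height, width)
    line_width: float = 3.0

    def __post_init__(self):
        if self.target_height > self.canvas[0]:
            raise ValueError("target_height exceeds canvas height")
        if self.line_width < 1:
            raise ValueError("line_width must be >= 1")


@dataclass(frozen=True)
class SkeletonImage:
    """One rasterized skeleton frame: float pixels in [0,1], white background."""

    pixels: np.ndarray
    segment_id: str = ""
    frame_index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("SkeletonImage pixels must be a 2-D raster")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("SkeletonImage pixels must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize_pose(
    frame: PoseFrame,
    target_height: float = 360.0,
    canvas: tuple[int, int] = (400, 400),
) -> PoseFrame:
    """Scale a pose to a fixed vertical extent and center it on the canvas.

    A single isotropic factor ``target_height / (max y - min y)`` preserves
    the aspect ratio; the bounding-box center maps to the canvas center
    ``((w-1)/2, (h-1)/2)``.  Idempotent: a pose already normalized maps to
    itself (up to float rounding).
    """
    if len(frame.keypoints) != len(JointId):
        raise NormalizationError(
            f"normalization needs all 12 joints, got {len(frame.keypoints)}"
        )
    xy = frame.xy
    extent = xy[:, 1].max() - xy[:, 1].min()
    if extent <= 0:
        raise NormalizationError("pose has zero vertical extent")
    scale = target_height / extent
    center = (xy.max(axis=0) + xy.min(axis=0)) / 2.0
    h, w = canvas
    canvas_center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    return frame.with_xy((xy - center) * scale + canvas_center)


def _stroke_mask(
    shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray, half_width: float
) -> np.ndarray:
    """Boolean mask of pixels within ``half_width`` of segment p0-p1 (x, y coords)."""
    h, w = shape
    x0 = max(0, int(np.floor(min(p0[0], p1[0]) - half_width - 1)))
    x1 = min(w - 1, int(np.ceil(max(p0[0], p1[0]) + half_width + 1)))
    y0 = max(0, int(np.floor(min(p0[1], p1[1]) - half_width - 1)))
    y1 = min(h - 1, int(np.ceil(max(p0[1], p1[1]) + half_width + 1)))
    mask = np.zeros(shape, dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    d = p1 - p0
    seg_len2 = float(d @ d)
    vx = xs - p0[0]
    vy = ys - p0[1]
    if seg_len2 == 0.0:
        dist2 = vx * vx + vy * vy
    else:
        t = np.clip((vx * d[0] + vy * d[1]) / seg_len2, 0.0, 1.0)
        dist2 = (vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2
    # small slack keeps pixels lying exactly on the stroke boundary stable
    # under float noise from normalization (translation/scale invariance)
    mask[y0 : y1 + 1, x0 : x1 + 1] = dist2 <= half_width**2 + 1e-9
    return mask


def render_skeleton(frame: PoseFrame, config: RenderConfig | None = None) -> SkeletonImage:
    """Trace the headless stick figure of a normalized pose onto the canvas.

    Dark binary strokes (0.0) on a white background (1.0); joints outside
    the canvas are kept (their strokes clip at the border) with a warning.
    """
    config = config or RenderConfig()
    h, w = config.canvas
    xy = frame.xy
    if (xy[:, 0].min() < 0 or xy[:, 0].max() > w - 1
            or xy[:, 1].min() < 0 or xy[:, 1].max() > h - 1):
        logger.warning(
            "frame %d: joints outside the %dx%d canvas; strokes will clip",
            frame.frame_index, h, w,
        )
    coords = {kp.joint: np.array([kp.x, kp.y]) for kp in frame.keypoints}
    dark = np.zeros((h, w), dtype=bool)
    half = config.line_width / 2.0
    for a, b in BONES:
        if a in coords and b in coords:
            dark |= _stroke_mask((h, w), coords[a], coords[b], half)
    pixels = np.ones((h, w), dtype=float)
    pixels[dark] = 0.0
    return SkeletonImage(pixels, frame_index=frame.frame_index)


def save_skeleton_png(image: SkeletonImage, path) -> None:
    """Export as 8-bit grayscale PNG (round-half-up quantization)."""
    import imageio.v3 as iio

    data = np.floor(image.pixels * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def load_skeleton_png(path, segment_id: str = "", frame_index: int = 0) -> SkeletonImage:
    import imageio.v3 as iio

    data = iio.imread(Path(path))
    return SkeletonImage(
        data.astype(float) / 255.0, segment_id=segment_id, frame_index=frame_index
    )
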