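"""Pluggable human-pose-estimation backends.

The pipeline never depends on a particular pose model: anything that maps a
frame raster to named joints with confidences can drive it.  Three backends
matter in practice: ``replay`` feeds previously saved pose files back into
the pipeline (bit-identical downstream results), ``synthetic`` produces
poses from the parametric gait generator, and ``yolov8m`` adapts the
external pretrained detector when its package is installed.  Frames in
which both the patient and a masked medical assistant are visible are
resolved to the single person with the largest bounding box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, runtime_checkable

import numpy as np

from seigait.ingest import FrameSequence
from seigait.pose import PoseFrame, PoseSequence, filter_frame

logger = logging.getLogger(__name__)

__all__ = [
    "PersonDetection",
    "PoseBackend",
    "BackendError",
    "BackendUnavailableError",
    "register_backend",
    "get_backend",
    "available_backends",
    "ReplayBackend",
    "SyntheticBackend",
    "estimate_sequence",
    "select_largest_person",
]


class BackendError(KeyError):
    """Unknown or duplicate backend name."""


class BackendUnavailableError(RuntimeError):
    """The backend exists but its optional dependency is not installed."""


@dataclass(frozen=True)
class PersonDetection:
    """One detected person: raw joints plus an optional bounding box."""

    keypoints: tuple[tuple, ...]  # (joint, x, y, confidence) entries
    bbox: tuple[float, float, float, float] | None = None  # x0, y0, x1, y1

    @property
    def bbox_area(self) -> float:
        if self.bbox is not None:
            x0, y0, x1, y1 = self.bbox
            return max(0.0, x1 - x0) * max(0.0, y1 - y0)
        xs = [float(k[1]) for k in self.keypoints]
        ys = [float(k[2]) for k in self.keypoints]
        if not xs:
            return 0.0
        return (max(xs) - min(xs)) * (max(ys) - min(ys))


@runtime_checkable
class PoseBackend(Protocol):
    """Contract every pose backend satisfies; ``estimate`` is pure per frame."""

    name: str

    def estimate(
        self, frame: np.ndarray | None, frame_index: int = 0
    ) -> list[PersonDetection]: ...

    @property
    def metadata(self) -> dict: ...


_REGISTRY: dict[str, Callable[..., PoseBackend]] = {}


def register_backend(name: str, factory: Callable[..., PoseBackend]) -> None:
    if name in _REGISTRY:
        raise BackendError(f"backend {name!r} already registered")
    _REGISTRY[name] = factory


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def get_backend(name: str, **kwargs) -> PoseBackend:
    """Resolve a backend by name; raise with the available list otherwise."""
    if name not in _REGISTRY:
        raise BackendError(
            f"unknown backend {name!r}; available: {available_backends()}"
        )
    return _REGISTRY[name](**kwargs)


class ReplayBackend:
    """Replays stored pose sequences (the pose CSV/JSON dialects) by frame index.

    Every replayed joint keeps its stored confidence, so a pipeline run over
    replayed poses is bit-identical to the run that produced them.
    """

    name = "replay"

    def __init__(self, sequence: PoseSequence):
        self._by_index: dict[int, PoseFrame] = {
            f.frame_index: f for f in sequence.frames
        }

    @property
    def metadata(self) -> dict:
        return {"frames": len(self._by_index)}

    def estimate(self, frame=None, frame_index: int = 0) -> list[PersonDetection]:
        pf = self._by_index.get(frame_index)
        if pf is None:
            return []
        return [
            PersonDetection(
                tuple((kp.joint, kp.x, kp.y, kp.confidence) for kp in pf.keypoints)
            )
        ]


class SyntheticBackend:
    """Emits poses from the parametric gait generator, keyed by frame index."""

    name = "synthetic"

    def __init__(self, params=None, n_frames: int = 1000):
        from seigait.synthetic import GaitParams, generate_gait_sequence

        self._params = params or GaitParams()
        self._seq = generate_gait_sequence(self._params, n_frames)
        self._by_index = {f.frame_index: f for f in self._seq.frames}

    @property
    def metadata(self) -> dict:
        return {"params": self._params}

    def estimate(self, frame=None, frame_index: int = 0) -> list[PersonDetection]:
        pf = self._by_index.get(frame_index)
        if pf is None:
            return []
        return [
            PersonDetection(
                tuple((kp.joint, kp.x, kp.y, kp.confidence) for kp in pf.keypoints)
            )
        ]


def _yolov8m_factory(**kwargs):
    try:
        from ultralytics import YOLO  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional extra
        raise BackendUnavailableError(
            "the 'yolov8m' backend needs the optional 'ultralytics' package "
            "(pip install ultralytics); use the 'replay' or 'synthetic' "
            "backend to run without pose-model weights"
        ) from exc
    from seigait._yolo_adapter import YoloV8Backend  # pragma: no cover

    return YoloV8Backend(**kwargs)  # pragma: no cover


register_backend("replay", ReplayBackend)
register_backend("synthetic", SyntheticBackend)
register_backend("yolov8m", _yolov8m_factory)


def select_largest_person(
    detections: Iterable[PersonDetection],
) -> PersonDetection | None:
    """The filmed patient is taken as the largest detected person in frame."""
    best, best_area = None, -1.0
    for det in detections:
        area = det.bbox_area
        if area > best_area:
            best, best_area = det, area
    return best


def estimate_sequence(
    backend: PoseBackend,
    frames: FrameSequence,
    threshold: float = 0.5,
) -> PoseSequence:
    """Run pose estimation over a frame sequence and keep clean frames only.

    One PoseFrame per accepted input frame, in input order; frames whose 12
    body joints do not all clear the confidence threshold are omitted.
    Accepted/rejected counts are logged.
    """
    if len(frames) == 0:
        raise ValueError("frame sequence is empty")
    accepted: list[PoseFrame] = []
    rejected = 0
    for i, frame in enumerate(frames.frames):
        detections = backend.estimate(frame, frame_index=i)
        person = select_largest_person(detections)
        pf = (
            filter_frame(person.keypoints, threshold=threshold, frame_index=i)
            if person is not None
            else None
        )
        if pf is None:
            rejected += 1
        else:
            accepted.append(pf)
    logger.info(
        "segment %s: %d frames accepted, %d rejected",
        frames.segment_id,
        len(accepted),
        rejected,
    )
    return PoseSequence(
        frames.segment_id,
        frames.subject_id,
        frames.label or "normal",
        frames.orientation or "forwards",
        accepted,
    )
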