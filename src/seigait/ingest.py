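"""Video pre-processing: segment manifests, frame sampling, short-segment discard.

Videos are manually segmented into clips in which the subject walks in a
single orientation (or transitions between orientations); that judgment is
externalized as a manifest file rather than automated.  Each manifest
segment is sampled at a fixed rate (default 10 frames per second) on the
half-open grid ``start + k/fps, k = 0, 1, ...`` stopping before ``end``, and
segments yielding fewer frames than the energy-image kernel (17) are
discarded because they cannot produce a single energy image downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ManifestEntry",
    "SegmentManifest",
    "FrameSequence",
    "FrameSource",
    "ArrayFrameSource",
    "DirectoryFrameSource",
    "open_video",
    "sample_frames",
    "drop_short_segments",
    "read_manifest",
    "write_manifest",
    "ManifestError",
]

DEFAULT_SAMPLING_FPS = 10.0
MIN_FRAMES = 17


class ManifestError(ValueError):
    """Manifest file malformed or violating segment invariants."""


@dataclass(frozen=True)
class ManifestEntry:
    segment_id: str
    start_s: float
    end_s: float
    orientation: str
    subject_id: str
    label: str

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ManifestError(
                f"segment {self.segment_id}: end {self.end_s} <= start {self.start_s}"
            )


@dataclass
class SegmentManifest:
    """Per-video list of manually delimited, non-overlapping clips."""

    video_id: str
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        spans = sorted((e.start_s, e.end_s, e.segment_id) for e in self.entries)
        for (s0, e0, id0), (s1, e1, id1) in zip(spans, spans[1:]):
            if s1 < e0 - 1e-9:
                raise ManifestError(
                    f"segments {id0} and {id1} overlap within video {self.video_id}"
                )


@dataclass
class FrameSequence:
    """Frames sampled from one segment, with their timestamps."""

    segment_id: str
    frames: list[np.ndarray]
    timestamps: list[float]
    fps: float
    subject_id: str = ""
    label: str = ""
    orientation: str = ""

    def __len__(self) -> int:
        return len(self.frames)


@runtime_checkable
class FrameSource(Protocol):
    """Anything that can serve a raster for an absolute video time."""

    duration: float

    def frame_at(self, t: float) -> np.ndarray: ...


class ArrayFrameSource:
    """In-memory stack of frames at a native rate (synthetic videos, tests)."""

    def __init__(self, frames: Sequence[np.ndarray], native_fps: float):
        if native_fps <= 0:
            raise ValueError("native_fps must be positive")
        self._frames = list(frames)
        self.native_fps = float(native_fps)
        self.duration = len(self._frames) / self.native_fps

    def frame_at(self, t: float) -> np.ndarray:
        idx = int(np.floor(t * self.native_fps + 1e-9))
        if not 0 <= idx < len(self._frames):
            raise IndexError(f"time {t:.3f}s outside video of {self.duration:.3f}s")
        return self._frames[idx]


class DirectoryFrameSource(ArrayFrameSource):
    """A directory of numbered image frames standing in for a video container."""

    def __init__(self, directory, native_fps: float):
        import imageio.v3 as iio

        paths = sorted(Path(directory).glob("*.png"))
        if not paths:
            raise IOError(f"no PNG frames under {directory}")
        super().__init__([iio.imread(p) for p in paths], native_fps)


def open_video(path, native_fps: float | None = None) -> FrameSource:
    """Open an MP4/AVI container, or a frame directory, as a FrameSource.

    Container decoding needs an imageio ffmpeg plugin; when unavailable the
    error says so explicitly rather than failing deep inside sampling.
    """
    path = Path(path)
    if path.is_dir():
        if native_fps is None:
            raise ValueError("native_fps is required for a frame directory")
        return DirectoryFrameSource(path, native_fps)
    try:
        import imageio.v3 as iio

        props = iio.improps(path, plugin="pyav")  # pragma: no cover - needs plugin
        frames = list(iio.imiter(path, plugin="pyav"))  # pragma: no cover
    except Exception as exc:
        raise IOError(
            f"cannot decode video container {path}: {exc}. "
            "Provide pose files or a PNG frame directory instead."
        ) from exc
    fps = native_fps or getattr(props, "fps", None) or 30.0  # pragma: no cover
    return ArrayFrameSource(frames, fps)  # pragma: no cover


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Scalar-per-pixel view of a frame, scaled to [0, 1] floats."""
    arr = np.asarray(frame)
    if arr.ndim == 3:
        from skimage.color import rgb2gray

        arr = rgb2gray(arr[..., :3])
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / 255.0
    return arr.astype(float)


def sample_frames(
    video: FrameSource,
    segment: ManifestEntry,
    fps: float = DEFAULT_SAMPLING_FPS,
    grayscale: bool = False,
) -> FrameSequence:
    """Sample a segment at uniform spacing 1/fps, start-inclusive, end-exclusive.

    The sample grid is ``start + k/fps`` for k = 0, 1, ... while strictly
    before ``end``.  Grayscale conversion is applied at ingest when the
    frames feed key-frame differencing; pose backends receive color frames.
    """
    if fps <= 0:
        raise ValueError("sampling fps must be positive")
    if segment.end_s > video.duration + 1e-9:
        raise ValueError(
            f"segment {segment.segment_id} [{segment.start_s}, {segment.end_s}) "
            f"exceeds video duration {video.duration:.3f}s"
        )
    frames, times = [], []
    k = 0
    while segment.start_s + k / fps < segment.end_s - 1e-9:
        t = segment.start_s + k / fps
        frame = video.frame_at(t)
        frames.append(to_grayscale(frame) if grayscale else np.asarray(frame))
        times.append(t)
        k += 1
    return FrameSequence(
        segment.segment_id,
        frames,
        times,
        fps,
        subject_id=segment.subject_id,
        label=segment.label,
        orientation=segment.orientation,
    )


def drop_short_segments(sequences: Sequence, min_frames: int = MIN_FRAMES) -> list:
    """Filter out sequences with fewer than ``min_frames`` frames, keeping order.

    Works on anything with ``len()`` (FrameSequence or PoseSequence).
    """
    kept = [s for s in sequences if len(s) >= min_frames]
    dropped = len(sequences) - len(kept)
    if dropped:
        logger.warning(
            "discarded %d/%d segments shorter than %d frames",
            dropped,
            len(sequences),
            min_frames,
        )
    return kept


_MANIFEST_COLUMNS = (
    "video_id",
    "segment_id",
    "start_s",
    "end_s",
    "orientation",
    "subject_id",
    "label",
)


def write_manifest(manifests: Sequence[SegmentManifest], path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for man in manifests:
            for e in man.entries:
                writer.writerow(
                    [
                        man.video_id,
                        e.segment_id,
                        repr(e.start_s),
                        repr(e.end_s),
                        e.orientation,
                        e.subject_id,
                        e.label,
                    ]
                )


def read_manifest(path) -> list[SegmentManifest]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ManifestError(f"{path}: empty file, expected header")
        missing = set(_MANIFEST_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ManifestError(f"{path}: missing columns {sorted(missing)}")
        by_video: dict[str, list[ManifestEntry]] = {}
        for row in reader:
            by_video.setdefault(row["video_id"], []).append(
                ManifestEntry(
                    row["segment_id"],
                    float(row["start_s"]),
                    float(row["end_s"]),
                    row["orientation"],
                    row["subject_id"],
                    row["label"],
                )
            )
    return [SegmentManifest(vid, entries) for vid, entries in by_video.items()]
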