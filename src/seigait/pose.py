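"""Pose key-point domain types, confidence filtering, and pose-file I/O.

A detected joint is a triple ``(x, y, p)``: image-pixel coordinates (origin
top-left, y increasing downward, 0-based) and a confidence score in [0, 1].
The pipeline keeps exactly 12 body joints per frame -- shoulders, elbows,
wrists, hips, knees and feet on both sides -- and discards any frame in
which one of them is missing or detected with confidence at or below the
threshold (strictly ``p > threshold`` is required; the default threshold is
0.5). Head and face joints are never used: the source videos are
face-blurred, so the rendered skeleton is headless.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "JointId",
    "KeyPoint",
    "PoseFrame",
    "PoseSequence",
    "CLASSES",
    "ORIENTATIONS",
    "PoseInputError",
    "PoseFileError",
    "filter_frame",
    "validate_sequence",
    "read_pose_file",
    "write_pose_file",
    "read_pose_csv",
    "write_pose_csv",
    "read_pose_json",
    "write_pose_json",
    "COCO_KEYPOINT_NAMES",
    "COCO_TO_JOINT",
]

#: Severity classes, ordered by increasing impairment (UPDRS gait 0-3).
CLASSES: tuple[str, ...] = ("normal", "mild", "moderate", "severe")

#: Walking orientations a video segment may capture.
ORIENTATIONS: tuple[str, ...] = ("forwards", "backwards", "sideways", "transition")


class PoseInputError(ValueError):
    """Malformed pose input (unknown joint, bad confidence, non-finite coords)."""


class PoseFileError(ValueError):
    """A pose file violates the CSV/JSON dialect (missing column/key, bad value)."""


class JointId(IntEnum):
    """The 12 body joints used by the pipeline, with stable codes 0-11.

    The order mirrors the conventional right/left listing: shoulders,
    elbows, wrists, hips, knees, feet.  ``COCO_TO_JOINT`` maps the 17-point
    COCO convention onto these 12; COCO's five head points (nose, eyes,
    ears; indices 0-4) map to nothing and are silently dropped, and COCO
    "ankles" are taken as the feet.
    """

    RIGHT_SHOULDER = 0
    LEFT_SHOULDER = 1
    RIGHT_ELBOW = 2
    LEFT_ELBOW = 3
    RIGHT_WRIST = 4
    LEFT_WRIST = 5
    RIGHT_HIP = 6
    LEFT_HIP = 7
    RIGHT_KNEE = 8
    LEFT_KNEE = 9
    RIGHT_FOOT = 10
    LEFT_FOOT = 11


#: COCO-17 keypoint names by index (the standard detection convention).
COCO_KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: COCO index -> JointId for the 12 body joints; head indices 0-4 absent.
COCO_TO_JOINT: dict[int, JointId] = {
    5: JointId.LEFT_SHOULDER,
    6: JointId.RIGHT_SHOULDER,
    7: JointId.LEFT_ELBOW,
    8: JointId.RIGHT_ELBOW,
    9: JointId.LEFT_WRIST,
    10: JointId.RIGHT_WRIST,
    11: JointId.LEFT_HIP,
    12: JointId.RIGHT_HIP,
    13: JointId.LEFT_KNEE,
    14: JointId.RIGHT_KNEE,
    15: JointId.LEFT_FOOT,
    16: JointId.RIGHT_FOOT,
}

_NAME_TO_JOINT: dict[str, JointId] = {j.name.lower(): j for j in JointId}
# Accept COCO body-part names too ("left_ankle" -> LEFT_FOOT).
_NAME_TO_JOINT.update(
    {COCO_KEYPOINT_NAMES[i].lower(): j for i, j in COCO_TO_JOINT.items()}
)
_HEAD_NAMES = frozenset(n.lower() for n in COCO_KEYPOINT_NAMES[:5])


def coerce_joint(joint) -> JointId | None:
    """Resolve a joint spelled as JointId, name, or COCO name to a JointId.

    Returns ``None`` for head/face joints (they are dropped, not an error).
    Raises :class:`PoseInputError` for anything unrecognized.
    """
    if isinstance(joint, JointId):
        return joint
    if isinstance(joint, str):
        key = joint.strip().lower()
        if key in _HEAD_NAMES:
            return None
        if key in _NAME_TO_JOINT:
            return _NAME_TO_JOINT[key]
        raise PoseInputError(f"unknown joint name: {joint!r}")
    if isinstance(joint, int):
        try:
            return JointId(joint)
        except ValueError:
            raise PoseInputError(f"unknown joint code: {joint!r}") from None
    raise PoseInputError(f"cannot interpret joint identifier: {joint!r}")


@dataclass(frozen=True)
class KeyPoint:
    """One detected joint: coordinates in image pixels plus confidence."""

    joint: JointId
    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise PoseInputError(f"non-finite coordinates for {self.joint.name}")
        if not 0.0 <= self.confidence <= 1.0:
            raise PoseInputError(
                f"confidence {self.confidence} for {self.joint.name} not in [0, 1]"
            )


@dataclass(frozen=True)
class PoseFrame:
    """The joints of one frame; an accepted frame has exactly 12 keypoints."""

    frame_index: int
    keypoints: tuple[KeyPoint, ...]

    def __post_init__(self):
        joints = [kp.joint for kp in self.keypoints]
        if len(set(joints)) != len(joints):
            raise PoseInputError("duplicate joints within a frame")
        object.__setattr__(
            self, "keypoints", tuple(sorted(self.keypoints, key=lambda k: k.joint))
        )

    def __getitem__(self, joint: JointId) -> KeyPoint:
        for kp in self.keypoints:
            if kp.joint == joint:
                return kp
        raise KeyError(joint)

    @property
    def xy(self):
        """(12, 2) float array of coordinates in JointId order (numpy import local)."""
        import numpy as np

        return np.array([[kp.x, kp.y] for kp in self.keypoints], dtype=float)

    def with_xy(self, xy) -> "PoseFrame":
        """Copy of the frame with coordinates replaced row-by-row."""
        return PoseFrame(
            self.frame_index,
            tuple(
                replace(kp, x=float(px), y=float(py))
                for kp, (px, py) in zip(self.keypoints, xy)
            ),
        )


@dataclass
class PoseSequence:
    """An ordered run of pose frames from one manually segmented video clip."""

    segment_id: str
    subject_id: str
    label: str
    orientation: str
    frames: list[PoseFrame] = field(default_factory=list)

    def __post_init__(self):
        if self.label not in CLASSES:
            raise PoseInputError(
                f"label {self.label!r} not one of {CLASSES}"
            )
        if self.orientation not in ORIENTATIONS:
            raise PoseInputError(
                f"orientation {self.orientation!r} not one of {ORIENTATIONS}"
            )
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise PoseInputError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def filter_frame(
    raw_keypoints: Iterable[tuple],
    threshold: float = 0.5,
    frame_index: int = 0,
) -> PoseFrame | None:
    """Keep a frame only if all 12 body joints clear the confidence threshold.

    ``raw_keypoints`` is an iterable of ``(joint, x, y, confidence)`` where the
    joint may be a :class:`JointId`, a joint name, or a COCO-17 name.  Head
    joints are dropped.  A body joint is valid only with confidence strictly
    greater than ``threshold``; a frame missing any of the 12 valid body
    joints is rejected (``None``).  Unknown joint identifiers raise
    :class:`PoseInputError` -- an input error, not a rejection.
    """
    kept: dict[JointId, KeyPoint] = {}
    for entry in raw_keypoints:
        joint_raw, x, y, conf = entry
        joint = coerce_joint(joint_raw)
        if joint is None:
            continue
        if joint in kept:
            raise PoseInputError(f"duplicate joint {joint.name} in raw keypoints")
        kp = KeyPoint(joint, float(x), float(y), float(conf))
        if kp.confidence > threshold:
            kept[joint] = kp
    if len(kept) < len(JointId):
        return None
    return PoseFrame(frame_index, tuple(kept.values()))


def validate_sequence(seq: PoseSequence, min_frames: int = 17) -> bool:
    """A sequence survives only with at least ``min_frames`` retained frames.

    Sequences shorter than the energy-image kernel cannot produce a single
    energy image and are discarded wholesale.
    """
    return len(seq.frames) >= min_frames


# ---------------------------------------------------------------------------
# Pose file dialects
#
# CSV: one row per keypoint with columns
#   segment_id, subject_id, label, orientation, frame_index, joint, x, y, confidence
# JSON: {"sequences": [{segment_id, subject_id, label, orientation,
#                       "frames": [{"frame_index": i,
#                                   "keypoints": [{joint, x, y, confidence}]}]}]}
# Round-trips preserve coordinates at full float precision (JSON repr / CSV repr).
# ---------------------------------------------------------------------------

_CSV_COLUMNS = (
    "segment_id",
    "subject_id",
    "label",
    "orientation",
    "frame_index",
    "joint",
    "x",
    "y",
    "confidence",
)


def write_pose_csv(sequences: Sequence[PoseSequence], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for seq in sequences:
            for frame in seq.frames:
                for kp in frame.keypoints:
                    writer.writerow(
                        [
                            seq.segment_id,
                            seq.subject_id,
                            seq.label,
                            seq.orientation,
                            frame.frame_index,
                            kp.joint.name.lower(),
                            repr(kp.x),
                            repr(kp.y),
                            repr(kp.confidence),
                        ]
                    )


def read_pose_csv(path) -> list[PoseSequence]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PoseFileError(f"{path}: empty file, expected header row")
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise PoseFileError(f"{path}: missing columns {sorted(missing)}")
        # group rows by (segment, frame) preserving first-seen order
        seq_meta: dict[str, tuple[str, str, str]] = {}
        frames: dict[str, dict[int, list[KeyPoint]]] = {}
        for row in reader:
            sid = row["segment_id"]
            joint = coerce_joint(row["joint"])
            if joint is None:
                raise PoseFileError(f"{path}: head joint {row['joint']!r} in pose file")
            meta = (row["subject_id"], row["label"], row["orientation"])
            if sid in seq_meta and seq_meta[sid] != meta:
                raise PoseFileError(f"{path}: inconsistent metadata for segment {sid}")
            seq_meta.setdefault(sid, meta)
            fi = int(row["frame_index"])
            frames.setdefault(sid, {}).setdefault(fi, []).append(
                KeyPoint(joint, float(row["x"]), float(row["y"]), float(row["confidence"]))
            )
    out = []
    for sid, meta in seq_meta.items():
        subject, label, orientation = meta
        ordered = [
            PoseFrame(fi, tuple(kps)) for fi, kps in sorted(frames[sid].items())
        ]
        out.append(PoseSequence(sid, subject, label, orientation, ordered))
    return out


def write_pose_json(sequences: Sequence[PoseSequence], path) -> None:
    doc = {
        "sequences": [
            {
                "segment_id": seq.segment_id,
                "subject_id": seq.subject_id,
                "label": seq.label,
                "orientation": seq.orientation,
                "frames": [
                    {
                        "frame_index": frame.frame_index,
                        "keypoints": [
                            {
                                "joint": kp.joint.name.lower(),
                                "x": kp.x,
                                "y": kp.y,
                                "confidence": kp.confidence,
                            }
                            for kp in frame.keypoints
                        ],
                    }
                    for frame in seq.frames
                ],
            }
            for seq in sequences
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_pose_json(path) -> list[PoseSequence]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PoseFileError(f"{path}: invalid JSON ({exc})") from exc
    if "sequences" not in doc:
        raise PoseFileError(f"{path}: missing top-level key 'sequences'")
    out = []
    for sdoc in doc["sequences"]:
        for key in ("segment_id", "subject_id", "label", "orientation", "frames"):
            if key not in sdoc:
                raise PoseFileError(f"{path}: sequence missing key {key!r}")
        frames = []
        for fdoc in sdoc["frames"]:
            if "frame_index" not in fdoc or "keypoints" not in fdoc:
                raise PoseFileError(
                    f"{path}: frame missing 'frame_index' or 'keypoints'"
                )
            kps = []
            for kdoc in fdoc["keypoints"]:
                joint = coerce_joint(kdoc["joint"])
                if joint is None:
                    raise PoseFileError(
                        f"{path}: head joint {kdoc['joint']!r} in pose file"
                    )
                kps.append(
                    KeyPoint(
                        joint,
                        float(kdoc["x"]),
                        float(kdoc["y"]),
                        float(kdoc.get("confidence", 1.0)),
                    )
                )
            frames.append(PoseFrame(int(fdoc["frame_index"]), tuple(kps)))
        out.append(
            PoseSequence(
                sdoc["segment_id"],
                sdoc["subject_id"],
                sdoc["label"],
                sdoc["orientation"],
                frames,
            )
        )
    return out


def write_pose_file(sequences: Sequence[PoseSequence], path) -> None:
    """Write sequences in the dialect implied by the file suffix (.csv / .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        write_pose_json(sequences, path)
    else:
        write_pose_csv(sequences, path)


def read_pose_file(path) -> list[PoseSequence]:
    """Read sequences in the dialect implied by the file suffix (.csv / .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_pose_json(path)
    return read_pose_csv(path)
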