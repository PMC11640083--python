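"""Parametric generator of labeled 12-joint gait sequences.

A planar (sagittal-view) kinematic chain stands in for a walking subject:
hips, knees and feet -- and the contralateral arm chain -- are driven by
phase-offset sinusoids at a given cadence, the trunk is tilted forward by a
fixed lean angle, and Gaussian jitter perturbs every joint coordinate.
Severity classes differ monotonically in these controls, mirroring the
clinical picture the pipeline is meant to pick up: a more stooped trunk,
reduced arm swing, slower cadence and shorter, lower steps as severity
grows, plus larger tremor jitter.

This is a pipeline fixture, not a biomechanical gait model: it produces
class-separable skeleton kinematics with the right qualitative signatures
and deterministic seeding, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from seigait.ingest import ManifestEntry, SegmentManifest
from seigait.pose import CLASSES, JointId, KeyPoint, PoseFrame, PoseSequence

__all__ = [
    "GaitParams",
    "SeverityProfile",
    "generate_gait_sequence",
    "generate_cohort",
    "synthetic_video_frames",
]

# segment lengths in "video" pixels (ballpark proportions of a standing adult)
TRUNK_LEN = 85.0
UPPER_ARM = 45.0
FOREARM = 40.0
THIGH = 70.0
SHANK = 70.0
HIP_HALFWIDTH = 10.0
SHOULDER_HALFWIDTH = 14.0


@dataclass(frozen=True)
class GaitParams:
    """Controls of one synthetic walker.

    ``trunk_lean`` in degrees from vertical (0 = upright); ``arm_swing`` is
    the shoulder-angle amplitude in degrees; ``cadence`` in gait cycles per
    second; ``step_length`` and ``foot_lift`` as fractions of leg length;
    ``tremor_jitter`` the per-coordinate Gaussian sigma in pixels.
    """

    label: str = "normal"
    trunk_lean: float = 0.0
    arm_swing: float = 35.0
    cadence: float = 1.0
    step_length: float = 0.50
    foot_lift: float = 0.15
    crouch: float = 0.0
    tremor_jitter: float = 0.3
    fps: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        for name in ("arm_swing", "step_length", "foot_lift", "crouch", "tremor_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.label not in CLASSES:
            raise ValueError(f"label {self.label!r} not one of {CLASSES}")


_DEFAULTS: dict[str, dict] = {
    "normal": dict(trunk_lean=0.0, arm_swing=35.0, cadence=1.0,
                   step_length=0.50, foot_lift=0.15, crouch=0.0, tremor_jitter=0.3),
    "mild": dict(trunk_lean=4.0, arm_swing=25.0, cadence=0.85,
                 step_length=0.40, foot_lift=0.12, crouch=8.0, tremor_jitter=0.8),
    "moderate": dict(trunk_lean=8.0, arm_swing=15.0, cadence=0.70,
                     step_length=0.30, foot_lift=0.08, crouch=16.0, tremor_jitter=1.4),
    "severe": dict(trunk_lean=12.0, arm_swing=6.0, cadence=0.50,
                   step_length=0.18, foot_lift=0.04, crouch=25.0, tremor_jitter=2.0),
}

# narrower gaps for robustness testing ("hard mode")
_HARD = {
    "normal": dict(trunk_lean=1.0, arm_swing=26.0, cadence=0.95,
                   step_length=0.44, foot_lift=0.13, crouch=3.0, tremor_jitter=1.0),
    "mild": dict(trunk_lean=4.0, arm_swing=22.0, cadence=0.87,
                 step_length=0.38, foot_lift=0.11, crouch=8.0, tremor_jitter=1.3),
    "moderate": dict(trunk_lean=7.0, arm_swing=18.0, cadence=0.79,
                     step_length=0.32, foot_lift=0.09, crouch=13.0, tremor_jitter=1.6),
    "severe": dict(trunk_lean=10.0, arm_swing=14.0, cadence=0.71,
                   step_length=0.26, foot_lift=0.07, crouch=18.0, tremor_jitter=1.9),
}


@dataclass
class SeverityProfile:
    """Class defaults with monotone severity encoding.

    Trunk lean must strictly increase and arm swing and cadence strictly
    decrease from normal through severe; violating parameter sets are
    rejected because downstream separability tests rely on the ordering.
    """

    params: dict[str, GaitParams] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(CLASSES) - set(self.params)
        if missing:
            raise ValueError(f"profile missing classes: {sorted(missing)}")
        seq = [self.params[c] for c in CLASSES]
        if not all(a.trunk_lean < b.trunk_lean for a, b in zip(seq, seq[1:])):
            raise ValueError("trunk_lean must strictly increase with severity")
        if not all(a.arm_swing > b.arm_swing for a, b in zip(seq, seq[1:])):
            raise ValueError("arm_swing must strictly decrease with severity")
        if not all(a.cadence > b.cadence for a, b in zip(seq, seq[1:])):
            raise ValueError("cadence must strictly decrease with severity")

    @classmethod
    def default(cls) -> "SeverityProfile":
        return cls({c: GaitParams(label=c, **_DEFAULTS[c]) for c in CLASSES})

    @classmethod
    def hard(cls) -> "SeverityProfile":
        """Narrow class gaps, for stress-testing classifier robustness."""
        return cls({c: GaitParams(label=c, **_HARD[c]) for c in CLASSES})


def _pose_at(params: GaitParams, t: float) -> dict[JointId, np.ndarray]:
    """Joint coordinates (x, y) of the chain at time t, before jitter.

    Image convention: y grows downward; the subject faces +x.  The walker
    stays in place (treadmill view); the pelvis bobs at twice the cadence.
    """
    phi = 2.0 * np.pi * params.cadence * t
    lean = np.deg2rad(params.trunk_lean)
    leg = THIGH + SHANK
    swing_amp = 0.6 * params.step_length  # leg angle amplitude, radians
    arm_amp = np.deg2rad(params.arm_swing)

    root = np.array([200.0, 230.0 + 1.5 * np.cos(2 * phi)])  # pelvis center
    up = np.array([np.sin(lean), -np.cos(lean)])  # trunk direction (tilted fwd)
    neck = root + TRUNK_LEN * up

    joints: dict[JointId, np.ndarray] = {}
    # a small sagittal-projection offset separates left/right chains
    for side, sign, phase in (("RIGHT", +1, 0.0), ("LEFT", -1, np.pi)):
        hip = root + np.array([sign * HIP_HALFWIDTH, 0.0])
        shoulder = neck + np.array([sign * SHOULDER_HALFWIDTH, 0.0])
        theta = swing_amp * np.sin(phi + phase)  # thigh angle from vertical
        crouch = np.deg2rad(params.crouch)  # flexed-posture knee bend
        knee = hip + THIGH * np.array([np.sin(theta + crouch), np.cos(theta + crouch)])
        # shank angles back under the body; swing phase lifts the foot
        shank_angle = theta - 0.5 * crouch
        lift = params.foot_lift * leg * max(0.0, np.sin(phi + phase))
        foot = knee + SHANK * np.array([np.sin(shank_angle), np.cos(shank_angle)])
        foot = foot - np.array([0.0, lift])
        # arms swing opposite to the ipsilateral leg, hanging from shoulders
        alpha = arm_amp * np.sin(phi + phase + np.pi)
        elbow = shoulder + UPPER_ARM * np.array([np.sin(alpha), np.cos(alpha)])
        wrist = elbow + FOREARM * np.array(
            [np.sin(alpha + 0.3), np.cos(alpha + 0.3)]
        )
        joints[JointId[f"{side}_HIP"]] = hip
        joints[JointId[f"{side}_KNEE"]] = knee
        joints[JointId[f"{side}_FOOT"]] = foot
        joints[JointId[f"{side}_SHOULDER"]] = shoulder
        joints[JointId[f"{side}_ELBOW"]] = elbow
        joints[JointId[f"{side}_WRIST"]] = wrist
    return joints


def generate_gait_sequence(
    params: GaitParams,
    n_frames: int,
    segment_id: str = "seg0",
    subject_id: str = "subj0",
    orientation: str = "sideways",
) -> PoseSequence:
    """Sample the kinematic chain at ``fps``; deterministic given the seed.

    All 12 joints are emitted every frame with confidence 1.0.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(params.seed)
    frames = []
    for i in range(n_frames):
        joints = _pose_at(params, i / params.fps)
        noise = rng.normal(0.0, params.tremor_jitter, size=(len(JointId), 2))
        kps = tuple(
            KeyPoint(j, float(joints[j][0] + noise[j][0]), float(joints[j][1] + noise[j][1]), 1.0)
            for j in JointId
        )
        frames.append(PoseFrame(i, kps))
    return PoseSequence(segment_id, subject_id, params.label, orientation, frames)


def generate_cohort(
    profile: SeverityProfile | None = None,
    sequences_per_class: int | Mapping[str, int] = 10,
    frames_per_sequence: int = 60,
    seed: int = 0,
) -> tuple[list[PoseSequence], list[SegmentManifest]]:
    """Labeled sequences for all classes, plus a matching segment manifest.

    Each simulated subject perturbs its class defaults by a bounded random
    factor (+-5%), small enough that the profile's severity ordering holds
    between classes.  Fully deterministic given the seed.
    """
    profile = profile or SeverityProfile.default()
    if isinstance(sequences_per_class, int):
        counts = {c: sequences_per_class for c in CLASSES}
    else:
        counts = dict(sequences_per_class)
    if any(v < 1 for v in counts.values()):
        raise ValueError("sequence counts must be >= 1")
    rng = np.random.default_rng(seed)
    sequences: list[PoseSequence] = []
    manifests: list[SegmentManifest] = []
    for label in CLASSES:
        base = profile.params[label]
        for k in range(counts.get(label, 0)):
            factors = rng.uniform(0.95, 1.05, size=6)
            params = replace(
                base,
                trunk_lean=base.trunk_lean * factors[0],
                arm_swing=base.arm_swing * factors[1],
                cadence=base.cadence * factors[2],
                step_length=base.step_length * factors[3],
                foot_lift=base.foot_lift * factors[4],
                crouch=base.crouch * factors[5],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            subject = f"{label}_subj{k:03d}"
            segment = f"{label}_seg{k:03d}"
            seq = generate_gait_sequence(
                params, frames_per_sequence, segment_id=segment, subject_id=subject
            )
            sequences.append(seq)
            manifests.append(
                SegmentManifest(
                    video_id=f"{subject}_video",
                    entries=[
                        ManifestEntry(
                            segment, 0.0, frames_per_sequence / base.fps,
                            "sideways", subject, label,
                        )
                    ],
                )
            )
    return sequences, manifests


def synthetic_video_frames(
    seq: PoseSequence,
    shape: tuple[int, int] = (400, 400),
    line_width: float = 3.0,
) -> list[np.ndarray]:
    """Rasterize a pose sequence into grayscale stick-figure "video" frames.

    Frames are drawn at the raw (unnormalized) coordinates, dark figure on
    white, so the ingest stage and key-frame differencing can be exercised
    without a real video file.
    """
    from seigait.render import RenderConfig, render_skeleton

    config = RenderConfig(
        target_height=min(shape) - 1, canvas=shape, line_width=line_width
    )
    return [render_skeleton(f, config).pixels for f in seq.frames]
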