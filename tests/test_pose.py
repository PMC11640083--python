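"""Key-point filtering rules and pose-file round trips."""

import random

import numpy as np
import pytest

from seigait.pose import (
    CLASSES,
    COCO_KEYPOINT_NAMES,
    JointId,
    KeyPoint,
    PoseFileError,
    PoseFrame,
    PoseInputError,
    PoseSequence,
    filter_frame,
    read_pose_file,
    validate_sequence,
    write_pose_file,
)
from tests.conftest import standing_keypoints


class TestFilterFrame:
    def test_all_high_confidence_accepted(self, raw_body_keypoints):
        frame = filter_frame(raw_body_keypoints)
        assert frame is not None
        assert len(frame.keypoints) == 12

    def test_one_low_confidence_joint_rejects_frame(self, raw_body_keypoints):
        kps = [
            (j, x, y, 0.4 if j == JointId.LEFT_WRIST else c)
            for j, x, y, c in raw_body_keypoints
        ]
        assert filter_frame(kps) is None

    def test_coco17_input_keeps_exactly_the_12_body_joints(self):
        # 5 head points + 12 body points, all confident
        kps = [(name, 10.0 * i, 5.0 * i, 0.8) for i, name in enumerate(COCO_KEYPOINT_NAMES)]
        frame = filter_frame(kps)
        assert frame is not None
        assert len(frame.keypoints) == 12
        assert {kp.joint for kp in frame.keypoints} == set(JointId)

    def test_confidence_exactly_at_threshold_is_rejected(self, raw_body_keypoints):
        kps = [(j, x, y, 0.5) for j, x, y, _ in raw_body_keypoints]
        assert filter_frame(kps, threshold=0.5) is None

    def test_malformed_joint_name_is_an_input_error_not_a_rejection(self):
        with pytest.raises(PoseInputError):
            filter_frame([("left_flipper", 0, 0, 0.9)] + standing_keypoints())

    def test_idempotent_on_accepted_frames(self, raw_body_keypoints):
        first = filter_frame(raw_body_keypoints)
        again = filter_frame(
            [(kp.joint, kp.x, kp.y, kp.confidence) for kp in first.keypoints]
        )
        assert again == first

    def test_acceptance_invariant_to_input_order(self, raw_body_keypoints):
        shuffled = raw_body_keypoints.copy()
        random.Random(3).shuffle(shuffled)
        assert filter_frame(shuffled) == filter_frame(raw_body_keypoints)

    def test_acceptance_frequency_matches_independent_joint_model(self):
        # each joint passes iff its Uniform(0,1) confidence > 0.5, so a frame
        # survives with probability (1 - 0.5)^12
        rng = np.random.default_rng(42)
        n = 10_000
        base = standing_keypoints()
        accepted = 0
        for _ in range(n):
            confs = rng.random(12)
            kps = [(j, x, y, c) for (j, x, y, _), c in zip(base, confs)]
            accepted += filter_frame(kps, threshold=0.5) is not None
        p = 0.5**12
        sd = np.sqrt(n * p * (1 - p))
        assert abs(accepted - n * p) < 5 * sd + 1


class TestValidateSequence:
    @pytest.mark.parametrize("n,ok", [(17, True), (16, False), (0, False), (30, True)])
    def test_minimum_retained_frames(self, n, ok):
        frames = [
            PoseFrame(i, tuple(KeyPoint(j, 10.0 * j + i, 5.0 * j) for j in JointId))
            for i in range(n)
        ]
        seq = PoseSequence("s", "p", "mild", "forwards", frames)
        assert validate_sequence(seq) is ok


class TestPoseTypes:
    def test_confidence_outside_unit_interval_rejected(self):
        with pytest.raises(PoseInputError):
            KeyPoint(JointId.LEFT_HIP, 0, 0, 1.5)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(PoseInputError):
            KeyPoint(JointId.LEFT_HIP, np.nan, 0, 0.9)

    def test_duplicate_joint_rejected(self):
        kp = KeyPoint(JointId.LEFT_HIP, 0, 0, 0.9)
        with pytest.raises(PoseInputError):
            PoseFrame(0, (kp, kp))

    def test_unknown_label_rejected(self):
        with pytest.raises(PoseInputError):
            PoseSequence("s", "p", "terrible", "forwards", [])

    def test_frame_index_must_increase(self):
        f = PoseFrame(3, tuple(KeyPoint(j, j, j + 1.0) for j in JointId))
        with pytest.raises(PoseInputError):
            PoseSequence("s", "p", "mild", "forwards", [f, f])


class TestPoseFiles:
    @pytest.mark.parametrize("suffix", ["csv", "json"])
    def test_round_trip_identity(self, tmp_path, walking_sequence, suffix):
        path = tmp_path / f"poses.{suffix}"
        write_pose_file([walking_sequence], path)
        back = read_pose_file(path)
        assert back == [walking_sequence]

    def test_17x12_sequence_yields_204_csv_rows(self, tmp_path):
        frames = [
            PoseFrame(i, tuple(KeyPoint(j, 1.0 * j, 2.0 + j) for j in JointId))
            for i in range(17)
        ]
        seq = PoseSequence("s", "p", "severe", "backwards", frames)
        path = tmp_path / "poses.csv"
        write_pose_file([seq], path)
        rows = path.read_text().strip().splitlines()
        assert len(rows) == 1 + 17 * 12

    @pytest.mark.parametrize("suffix", ["csv", "json"])
    def test_empty_sequence_list_round_trips(self, tmp_path, suffix):
        path = tmp_path / f"empty.{suffix}"
        write_pose_file([], path)
        assert read_pose_file(path) == []

    def test_unknown_joint_name_is_a_parse_error(self, tmp_path, walking_sequence):
        path = tmp_path / "poses.csv"
        write_pose_file([walking_sequence], path)
        text = path.read_text().replace("right_wrist", "antenna", 1)
        path.write_text(text)
        with pytest.raises(PoseInputError):
            read_pose_file(path)

    def test_missing_column_error_names_the_field(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("segment_id,subject_id,label\n")
        with pytest.raises(PoseFileError, match="orientation"):
            read_pose_file(path)

    def test_class_labels_are_the_four_severity_levels(self):
        assert CLASSES == ("normal", "mild", "moderate", "severe")
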