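"""Synthetic gait generator: determinism, periodicity, severity encoding."""

import numpy as np
import pytest

from seigait.datasets import class_counts, oversample_balance
from seigait.pipeline import build_sei_records
from seigait.pose import CLASSES, JointId, write_pose_file
from seigait.presets import reduced_render_config
from seigait.synthetic import (
    GaitParams,
    SeverityProfile,
    generate_cohort,
    generate_gait_sequence,
    synthetic_video_frames,
)


class TestGenerateSequence:
    def test_frame_and_joint_counts(self):
        seq = generate_gait_sequence(GaitParams(), 17)
        assert len(seq) == 17
        assert all(len(f.keypoints) == 12 for f in seq.frames)
        assert all(kp.confidence == 1.0 for f in seq.frames for kp in f.keypoints)

    def test_deterministic_given_seed(self):
        a = generate_gait_sequence(GaitParams(seed=5), 30)
        b = generate_gait_sequence(GaitParams(seed=5), 30)
        assert a == b
        c = generate_gait_sequence(GaitParams(seed=6), 30)
        assert a != c

    @pytest.mark.parametrize("cadence,expected_lag", [(1.0, 10), (0.5, 20)])
    def test_foot_height_period_is_fps_over_cadence(self, cadence, expected_lag):
        params = GaitParams(cadence=cadence, tremor_jitter=0.0, fps=10.0)
        seq = generate_gait_sequence(params, 80)
        y = np.array([f[JointId.RIGHT_FOOT].y for f in seq.frames])
        y = y - y.mean()
        ac = np.correlate(y, y, mode="full")[len(y) - 1 :]
        lags = np.arange(5, 36)
        assert lags[np.argmax(ac[5:36])] == expected_lag

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GaitParams(cadence=0.0)
        with pytest.raises(ValueError):
            GaitParams(arm_swing=-1.0)
        with pytest.raises(ValueError):
            generate_gait_sequence(GaitParams(), 0)


class TestSeverityProfile:
    def test_default_and_hard_profiles_satisfy_monotone_ordering(self):
        for profile in (SeverityProfile.default(), SeverityProfile.hard()):
            leans = [profile.params[c].trunk_lean for c in CLASSES]
            swings = [profile.params[c].arm_swing for c in CLASSES]
            cadences = [profile.params[c].cadence for c in CLASSES]
            assert leans == sorted(leans) and len(set(leans)) == 4
            assert swings == sorted(swings, reverse=True)
            assert cadences == sorted(cadences, reverse=True)

    def test_violating_ordering_rejected(self):
        params = {c: SeverityProfile.default().params[c] for c in CLASSES}
        import dataclasses

        params["severe"] = dataclasses.replace(params["severe"], trunk_lean=0.0)
        with pytest.raises(ValueError, match="trunk_lean"):
            SeverityProfile(params)


class TestGenerateCohort:
    def test_counts_and_manifest_alignment(self):
        seqs, manifests = generate_cohort(
            sequences_per_class=3, frames_per_sequence=20, seed=0
        )
        assert len(seqs) == 12
        assert len(manifests) == 12
        assert class_counts(seqs) == {c: 3 for c in CLASSES}
        for seq, man in zip(seqs, manifests):
            assert man.entries[0].segment_id == seq.segment_id
            assert man.entries[0].label == seq.label

    def test_pose_files_byte_identical_for_same_seed(self, tmp_path):
        for name in ("a", "b"):
            seqs, _ = generate_cohort(
                sequences_per_class=2, frames_per_sequence=20, seed=9
            )
            write_pose_file(seqs, tmp_path / f"{name}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_imbalanced_request_balances_to_majority(self):
        seqs, _ = generate_cohort(
            sequences_per_class={"normal": 8, "mild": 2, "moderate": 4, "severe": 4},
            frames_per_sequence=20,
            seed=1,
        )
        records = build_sei_records(seqs, reduced_render_config(48))
        balanced = oversample_balance(records, seed=1)
        counts = class_counts(balanced)
        assert len(set(counts.values())) == 1
        assert sum(counts.values()) == 4 * max(counts.values())


@pytest.fixture(scope="module")
def cohort():
    seqs, _ = generate_cohort(sequences_per_class=10, frames_per_sequence=40, seed=4)
    return {c: [s for s in seqs if s.label == c] for c in CLASSES}


class TestSeverityRecovery:
    def test_recovered_trunk_lean_increases_with_severity(self, cohort):
        def mean_lean(seqs):
            vals = []
            for s in seqs:
                for f in s.frames:
                    sx = (f[JointId.LEFT_SHOULDER].x + f[JointId.RIGHT_SHOULDER].x) / 2
                    sy = (f[JointId.LEFT_SHOULDER].y + f[JointId.RIGHT_SHOULDER].y) / 2
                    hx = (f[JointId.LEFT_HIP].x + f[JointId.RIGHT_HIP].x) / 2
                    hy = (f[JointId.LEFT_HIP].y + f[JointId.RIGHT_HIP].y) / 2
                    vals.append(np.degrees(np.arctan2(sx - hx, hy - sy)))
            return np.mean(vals)

        leans = [mean_lean(cohort[c]) for c in CLASSES]
        assert all(a < b for a, b in zip(leans, leans[1:]))

    def test_mean_foot_displacement_decreases_with_severity(self, cohort):
        def mean_disp(seqs):
            vals = []
            for s in seqs:
                xy = np.array(
                    [
                        [[f[j].x, f[j].y] for j in (JointId.LEFT_FOOT, JointId.RIGHT_FOOT)]
                        for f in s.frames
                    ]
                )
                vals.append(np.abs(np.diff(xy, axis=0)).mean())
            return np.mean(vals)

        disps = [mean_disp(cohort[c]) for c in CLASSES]
        assert all(a > b for a, b in zip(disps, disps[1:]))

    def test_normal_sei_center_of_mass_sits_higher_than_severe(self, cohort):
        def mean_com(seqs):
            records = build_sei_records(seqs, reduced_render_config())
            vals = []
            for r in records:
                dark = 1.0 - r.image
                rows = np.arange(dark.shape[0])
                vals.append((dark.sum(axis=1) * rows).sum() / dark.sum())
            return np.mean(vals)

        com_normal = mean_com(cohort["normal"][:4])
        com_severe = mean_com(cohort["severe"][:4])
        assert com_normal < com_severe  # smaller row index = higher in the image


class TestSyntheticVideo:
    def test_frames_match_sequence_length_and_are_grayscale(self, walking_sequence):
        frames = synthetic_video_frames(walking_sequence, shape=(64, 64))
        assert len(frames) == len(walking_sequence)
        assert frames[0].shape == (64, 64)
        assert set(np.unique(frames[0])) <= {0.0, 1.0}
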