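"""Energy-image arithmetic, the rolling kernel, and key-frame detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seigait.render import SkeletonImage
from seigait.sei import (
    SEIConfig,
    compute_sei,
    detect_key_frames,
    frame_difference_series,
    keyframe_sei_sequences,
    rolling_sei,
)


def _images(n, shape=(6, 6), seed=0, segment="seg"):
    rng = np.random.default_rng(seed)
    return [
        SkeletonImage(rng.random(shape), segment_id=segment, frame_index=i)
        for i in range(n)
    ]


def _brute_force_mean(images):
    out = np.zeros_like(images[0].pixels)
    h, w = out.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = sum(im.pixels[i, j] for im in images) / len(images)
    return out


class TestComputeSEI:
    def test_seventeen_identical_images_return_the_input(self):
        base = np.random.default_rng(1).random((5, 5))
        sei = compute_sei([SkeletonImage(base, frame_index=i) for i in range(17)])
        np.testing.assert_array_equal(sei.pixels, base)

    def test_one_dark_pixel_in_seventeen_whites(self):
        images = [SkeletonImage(np.ones((4, 4)), frame_index=i) for i in range(17)]
        dark = np.ones((4, 4))
        dark[2, 3] = 0.0
        images[5] = SkeletonImage(dark, frame_index=5)
        sei = compute_sei(images)
        assert sei.pixels[2, 3] == pytest.approx(16 / 17, abs=1e-15)
        assert sei.pixels[0, 0] == 1.0

    def test_matches_brute_force_oracle(self):
        images = _images(17, seed=3)
        sei = compute_sei(images)
        assert np.abs(sei.pixels - _brute_force_mean(images)).max() < 1e-12

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="17"):
            compute_sei(_images(16))

    def test_shape_mismatch_rejected(self):
        images = _images(16) + [SkeletonImage(np.ones((3, 3)), frame_index=16)]
        with pytest.raises(ValueError, match="shape"):
            compute_sei(images)

    def test_permutation_invariance(self):
        images = _images(17, seed=5)
        rng = np.random.default_rng(9)
        shuffled = [images[i] for i in rng.permutation(17)]
        np.testing.assert_allclose(
            compute_sei(images).pixels, compute_sei(shuffled).pixels, atol=1e-12
        )

    def test_pixel_range_conservation(self):
        images = _images(17, seed=11)
        sei = compute_sei(images)
        stack = np.stack([im.pixels for im in images])
        assert (sei.pixels >= stack.min()).all()
        assert (sei.pixels <= stack.max()).all()


class TestRollingSEI:
    def test_exactly_seventeen_frames_give_one_sei(self):
        assert len(rolling_sei(_images(17))) == 1

    def test_twenty_frames_give_four_seis_with_consecutive_starts(self):
        seis = rolling_sei(_images(20))
        assert len(seis) == 4
        assert [s.start_index for s in seis] == [0, 1, 2, 3]

    def test_sixteen_frames_error_references_upstream_discard(self):
        with pytest.raises(ValueError, match="discard"):
            rolling_sei(_images(16))

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(min_value=17, max_value=100))
    def test_count_law(self, n):
        assert len(rolling_sei(_images(n, shape=(2, 2)))) == n - 16

    def test_windows_match_direct_means(self):
        images = _images(25, seed=7)
        seis = rolling_sei(images)
        for m in (0, 4, 8):
            direct = np.stack([im.pixels for im in images[m : m + 17]]).mean(axis=0)
            np.testing.assert_allclose(seis[m].pixels, direct, atol=1e-12)

    def test_output_order_follows_frame_order(self):
        images = _images(19, seed=2)
        rev = rolling_sei(images[::-1])
        fwd = rolling_sei(images)
        assert not np.allclose(fwd[0].pixels, rev[0].pixels)


class TestFrameDifference:
    def test_identical_frames_give_zero(self):
        frames = [np.ones((4, 4))] * 3
        diffs = frame_difference_series(frames)
        assert np.isnan(diffs[0])
        assert diffs[1] == 0.0

    def test_black_to_white_gives_one(self):
        diffs = frame_difference_series([np.zeros((4, 4)), np.ones((4, 4))])
        assert diffs[1] == 1.0

    def test_checkerboard_inversion_gives_one(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        diffs = frame_difference_series([board.astype(float), 1.0 - board])
        assert diffs[1] == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            frame_difference_series([np.zeros((4, 4)), np.zeros((3, 3))])

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            frame_difference_series([np.zeros((4, 4))])


class TestDetectKeyFrames:
    def test_constant_differences_yield_only_first_frame(self):
        diffs = np.array([np.nan] + [0.7] * 30)
        assert detect_key_frames(diffs) == [0]

    def test_jump_above_factor_is_flagged(self):
        diffs = np.array([np.nan] + [1.0] * 10 + [2.0])
        assert detect_key_frames(diffs) == [0, 11]

    def test_jump_exactly_at_factor_not_flagged(self):
        diffs = np.array([np.nan] + [1.0] * 10 + [1.5])
        assert detect_key_frames(diffs) == [0]

    def test_all_zero_differences_yield_only_first_frame(self):
        diffs = np.array([np.nan] + [0.0] * 20)
        assert detect_key_frames(diffs) == [0]

    def test_history_truncated_to_available(self):
        # at t=2 only one prior difference exists
        diffs = np.array([np.nan, 0.1, 1.0])
        assert detect_key_frames(diffs) == [0, 2]


class TestKeyframeSequences:
    def test_key_frame_at_start_of_17_frame_segment(self):
        images = _images(17)
        seis = keyframe_sei_sequences([0], images)
        assert len(seis) == 1
        assert seis[0].variant == "keyframe"

    def test_key_frame_without_16_followers_forms_nothing(self):
        images = _images(20)
        assert keyframe_sei_sequences([4], images) == []

    def test_window_with_pose_rejected_frame_forms_nothing(self):
        images = {im.frame_index: im for im in _images(40)}
        del images[9]  # rejected by pose filtering
        assert keyframe_sei_sequences([0], images) == []  # window 0-16 covers 9
        assert len(keyframe_sei_sequences([20], images)) == 1  # window 20-36 clean

    def test_keyframe_seis_subset_of_rolling_when_nothing_rejected(self):
        images = _images(30, seed=13)
        rolling = {s.start_index: s.pixels for s in rolling_sei(images)}
        for sei in keyframe_sei_sequences([0, 5, 9], images):
            np.testing.assert_array_equal(sei.pixels, rolling[sei.start_index])


class TestSEIConfig:
    def test_followers_must_match_kernel(self):
        with pytest.raises(ValueError):
            SEIConfig(kernel=17, keyframe_followers=10)

    def test_defaults(self):
        cfg = SEIConfig()
        assert (cfg.kernel, cfg.keyframe_window, cfg.keyframe_factor,
                cfg.keyframe_followers) == (17, 10, 1.5, 16)
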