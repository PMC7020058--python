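"""Tests of cleaning, smoothing, side selection and feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bitekit.keypoint_io import KeypointSequence
from bitekit.preprocess import (
    BODY_PAIRS,
    CleaningConfig,
    UnrecoverablePointError,
    assemble_features,
    clean_sequence,
    select_mouth_side,
    smooth_sequence,
)
from bitekit.synth import SimConfig, simulate_meal


def make_sequence(n=30, fps=25.0, seed=0, conf=0.9):
    """A stationary 12-point sequence with small positional noise."""
    rng = np.random.default_rng(seed)
    base = np.concatenate(
        [rng.uniform(100, 600, size=(8, 2)), 300 + rng.uniform(-20, 20, size=(4, 2))]
    )
    pts = base[None, :, :] + rng.normal(0, 1.0, size=(n, 12, 2))
    arr = np.dstack([pts, np.full((n, 12, 1), conf)])
    return KeypointSequence(body=arr[:, :8], mouth=arr[:, 8:], fps=fps)


class TestCleanSequence:
    def test_gap_filled_from_previous_frame(self):
        seq = make_sequence()
        wrist_before = seq.body[4, 7, :2].copy()
        seq.body[5:8, 7] = [np.nan, np.nan, 0.0]
        out = clean_sequence(seq)
        for f in (5, 6, 7):
            np.testing.assert_array_equal(out.body[f, 7, :2], wrist_before)
        assert not out.missing_mask().any()

    def test_fully_valid_sequence_unchanged(self):
        seq = make_sequence()
        assert clean_sequence(seq) == seq

    def test_one_frame_spike_replaced_by_previous_value(self):
        seq = make_sequence()
        cfg = CleaningConfig()
        thr = cfg.jump_fraction * np.hypot(*seq.frame_size)
        elbow_before = seq.body[9, 6, :2].copy()
        seq.body[10, 6, :2] += [thr + 220.0, 0.0]  # half-frame spike, one frame
        # brute-force oracle: frames whose displacement from the previous
        # frame exceeds the threshold
        disp = np.linalg.norm(np.diff(seq.body[:, 6, :2], axis=0), axis=1)
        flagged = np.nonzero(disp > thr)[0] + 1
        assert list(flagged) == [10, 11]  # out-jump and return
        out = clean_sequence(seq, cfg)
        np.testing.assert_array_equal(out.body[10, 6, :2], elbow_before)

    def test_never_detected_point_raises_with_name(self):
        seq = make_sequence()
        seq.mouth[:, 1] = [np.nan, np.nan, 0.0]
        with pytest.raises(UnrecoverablePointError, match="mouth_B"):
            clean_sequence(seq)

    def test_low_confidence_treated_as_missing(self):
        seq = make_sequence()
        prev = seq.body[2, 3, :2].copy()
        seq.body[3, 3, 2] = 0.05  # below the 0.1 floor
        out = clean_sequence(seq)
        np.testing.assert_array_equal(out.body[3, 3, :2], prev)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_on_degraded_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = make_sequence(n=40, seed=seed)
        drop = rng.random((40, 12)) < 0.1
        drop[0] = False  # keep one anchor frame per point
        pts = seq.points()
        pts[drop, 0] = np.nan
        pts[drop, 1] = np.nan
        pts[drop, 2] = 0.0
        spike = rng.random((40, 12)) < 0.05
        pts[spike, 0] = rng.uniform(0, 720, spike.sum())
        pts[spike, 1] = rng.uniform(0, 576, spike.sum())
        seq.body, seq.mouth = pts[:, :8], pts[:, 8:]
        once = clean_sequence(seq)
        twice = clean_sequence(once)
        assert twice == once


class TestSmoothSequence:
    def test_zero_smoothing_is_identity(self):
        seq = make_sequence()
        out = smooth_sequence(seq, CleaningConfig(spline_smoothing=0.0))
        np.testing.assert_allclose(out.points()[:, :, :2], seq.points()[:, :, :2])

    def test_cv_smoothing_reproduces_quadratic_trajectory(self):
        n = 900
        t = np.arange(n, dtype=float)
        seq = make_sequence(n=n)
        pts = seq.points()
        pts[:, :, 0] = 200 + 0.3 * t[:, None] - 2e-4 * (t**2)[:, None]
        pts[:, :, 1] = 300 + 0.1 * t[:, None] + 1e-4 * (t**2)[:, None]
        seq.body, seq.mouth = pts[:, :8], pts[:, 8:]
        out = smooth_sequence(seq, CleaningConfig(spline_smoothing=None))
        np.testing.assert_allclose(
            out.points()[:, :, :2], pts[:, :, :2], atol=1e-6
        )

    def test_explicit_smoothing_reduces_noise_variance(self):
        seq = make_sequence(n=200, seed=3)
        out = smooth_sequence(seq, CleaningConfig(spline_smoothing=2.0))
        x_in = seq.body[:, 7, 0]
        x_out = out.body[:, 7, 0]
        assert x_out.var() < x_in.var()

    def test_too_short_sequence_rejected(self):
        seq = make_sequence(n=3)
        with pytest.raises(ValueError, match="at least"):
            smooth_sequence(seq, CleaningConfig(spline_degree=3))

    def test_missing_values_rejected(self):
        seq = make_sequence()
        seq.body[5, 7] = [np.nan, np.nan, 0.0]
        with pytest.raises(ValueError, match="clean"):
            smooth_sequence(seq)


class TestSelectMouthSide:
    def test_higher_confidence_corner_wins(self):
        seq = make_sequence()
        seq.mouth[:, 0, 2] = 0.9  # A
        seq.mouth[:, 2, 2] = 0.4  # C
        assert select_mouth_side(seq) == "left"
        seq.mouth[:, 0, 2] = 0.3
        assert select_mouth_side(seq) == "right"

    def test_tie_goes_left(self):
        seq = make_sequence()
        seq.mouth[:, 0, 2] = 0.5
        seq.mouth[:, 2, 2] = 0.5
        assert select_mouth_side(seq) == "left"

    def test_never_detected_corners_rejected(self):
        seq = make_sequence()
        seq.mouth[:, 0, 2] = 0.0
        seq.mouth[:, 2, 2] = 0.0
        with pytest.raises(ValueError, match="corner"):
            select_mouth_side(seq)

    def test_recovers_generator_visible_side(self):
        """Selected side equals the simulated camera side in >=99% of seeds."""
        hits = 0
        n = 200
        for seed in range(n):
            side = "left" if seed % 2 == 0 else "right"
            seq, _ = simulate_meal(
                SimConfig(duration_s=10.0, rate_profile=(0.5, 0, 0),
                          visible_side=side, seed=seed)
            )
            hits += select_mouth_side(seq) == side
        assert hits >= 0.99 * n


class TestAssembleFeatures:
    def test_translation_invariance_exact(self):
        seq = make_sequence()
        feats = assemble_features(seq, "left")
        moved = seq.copy()
        moved.body[:, :, :2] += [40.0, -13.0]
        moved.mouth[:, :, :2] += [40.0, -13.0]
        feats2 = assemble_features(moved, "left")
        # invariant by construction; tolerance covers float rounding only
        np.testing.assert_allclose(feats2.body_stream, feats.body_stream,
                                   rtol=0, atol=1e-9)
        np.testing.assert_allclose(feats2.mouth_stream, feats.mouth_stream,
                                   rtol=0, atol=1e-9)

    def test_degenerate_frame_all_zero(self):
        seq = make_sequence(n=5)
        pts = seq.points()
        pts[2, :, :2] = 123.0  # every point collapsed to one location
        seq.body, seq.mouth = pts[:, :8], pts[:, 8:]
        feats = assemble_features(seq, "left")
        np.testing.assert_array_equal(feats.body_stream[2], 0.0)
        np.testing.assert_array_equal(feats.mouth_stream[2], 0.0)

    def test_distances_match_brute_force(self):
        seq = make_sequence(seed=9)
        feats = assemble_features(seq, "right")
        frame = 7
        body = seq.body[frame, :, :2]
        expected = [
            np.sqrt(((body[i] - body[j]) ** 2).sum())
            for i in range(8)
            for j in range(i + 1, 8)
        ]
        np.testing.assert_allclose(feats.body_stream[frame, 16:], expected)
        mouth = seq.mouth[frame, [1, 3, 2], :2]  # B, D, corner C
        expected_m = [
            np.sqrt(((mouth[i] - mouth[j]) ** 2).sum())
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        np.testing.assert_allclose(feats.mouth_stream[frame, 6:], expected_m)

    def test_neck_and_layout_conventions(self):
        seq = make_sequence()
        feats = assemble_features(seq, "left")
        np.testing.assert_array_equal(feats.body_stream[:, 2:4], 0.0)  # neck origin
        assert feats.body_stream.shape[1] == 16 + len(BODY_PAIRS)
        assert feats.mouth_stream.shape[1] == 9

    def test_missing_values_rejected(self):
        seq = make_sequence()
        seq.body[5, 7] = [np.nan, np.nan, 0.0]
        with pytest.raises(ValueError, match="clean"):
            assemble_features(seq, "left")


def test_pipeline_deterministic(noisy_meal):
    (seq, _), _ = noisy_meal
    cfg = CleaningConfig()
    a = assemble_features(smooth_sequence(clean_sequence(seq, cfg), cfg), "left")
    b = assemble_features(smooth_sequence(clean_sequence(seq, cfg), cfg), "left")
    np.testing.assert_array_equal(a.body_stream, b.body_stream)
    np.testing.assert_array_equal(a.mouth_stream, b.mouth_stream)
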