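"""Unit tests for the video keypoint pipeline."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmix import body25
from gaitmix.errors import (
    DegenerateGeometryError,
    FormatError,
    InsufficientFramesError,
)
from gaitmix.io import list_keypoint_frames, write_keypoint_frames
from gaitmix.synthetic import PostureSimParams, simulate_keypoints
from gaitmix.types import KeypointSequence
from gaitmix.video import (
    extract_posture_features,
    filter_frames,
    joint_angle,
    parse_openpose_json,
    posture_angle_series,
    segment_reference_angle,
    spatiotemporal_params,
    wavelet_denoise,
)


def write_frame(path, people):
    with open(path, "w") as fh:
        json.dump({"version": 1.3, "people": people}, fh)


def person(points_xyc):
    return {"pose_keypoints_2d": [v for triple in points_xyc for v in triple]}


class TestParseOpenposeJson:
    def test_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(1)
        pts = [(float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)), 0.9)] * 25
        write_frame(tmp_path / "f_000000000000_keypoints.json", [person(pts)])
        seq = parse_openpose_json([tmp_path / "f_000000000000_keypoints.json"])
        np.testing.assert_array_equal(seq.points[0, 0], pts[0][:2])
        assert seq.confidence[0, 0] == 0.9

    def test_empty_people_gives_unusable_frame(self, tmp_path):
        write_frame(tmp_path / "f_000000000000_keypoints.json", [])
        seq = parse_openpose_json([tmp_path / "f_000000000000_keypoints.json"])
        assert np.all(seq.confidence == 0)

    def test_multiple_people_largest_bbox_retained(self, tmp_path):
        small = person([(10.0 + i * 0.5, 10.0, 0.9) for i in range(25)])
        big = person([(100.0 + i * 20.0, 100.0 + i * 10.0, 0.9) for i in range(25)])
        write_frame(tmp_path / "f_000000000000_keypoints.json", [small, big])
        seq = parse_openpose_json([tmp_path / "f_000000000000_keypoints.json"])
        assert seq.points[0, 1, 0] == pytest.approx(120.0)

    def test_malformed_json_names_the_file(self, tmp_path):
        bad = tmp_path / "f_000000000000_keypoints.json"
        bad.write_text("{not json")
        with pytest.raises(FormatError, match="f_000000000000"):
            parse_openpose_json([bad])

    def test_wrong_keypoint_count_rejected(self, tmp_path):
        write_frame(
            tmp_path / "f_000000000000_keypoints.json",
            [{"pose_keypoints_2d": [1.0] * 30}],
        )
        with pytest.raises(FormatError):
            parse_openpose_json([tmp_path / "f_000000000000_keypoints.json"])

    def test_generator_write_read_round_trip_identical(self, tmp_path, clean_posture_sim):
        seq = clean_posture_sim.sequence
        write_keypoint_frames(tmp_path, seq)
        back = parse_openpose_json(
            list_keypoint_frames(tmp_path), fps=seq.fps, image_height=seq.image_height
        )
        np.testing.assert_array_equal(back.points, seq.points)
        np.testing.assert_array_equal(back.confidence, seq.confidence)


class TestFilterFrames:
    def _sequence(self, conf_value, n=200):
        pts = np.ones((n, 25, 2))
        conf = np.full((n, 25), conf_value)
        return KeypointSequence(fps=60.0, points=pts, confidence=conf)

    def test_all_confident_frames_retained(self):
        fseq = filter_frames(self._sequence(1.0))
        assert fseq.retained_fraction == 1.0
        assert fseq.sequence.n_frames == 200

    def test_all_zero_confidence_raises(self):
        with pytest.raises(InsufficientFramesError):
            filter_frames(self._sequence(0.0))

    def test_dropout_matches_injected_fraction(self):
        sim = simulate_keypoints(PostureSimParams(dropout_fraction=0.10, seed=2))
        fseq = filter_frames(sim.sequence)
        assert fseq.retained_fraction == pytest.approx(0.90, abs=0.02)
        # longest run is the contiguous middle
        assert np.all(np.diff(fseq.frame_indices) == 1)


class TestJointAngle:
    @pytest.mark.parametrize(
        "a,b,c,expected",
        [
            ((0, 0), (1, 0), (2, 0), 180.0),
            ((0, 0), (0, 1), (1, 1), 90.0),
            ((1, 0), (0, 0), (math.cos(math.pi / 3), math.sin(math.pi / 3)), 60.0),
        ],
    )
    def test_exact_cases(self, a, b, c, expected):
        assert joint_angle(np.array(a), np.array(b), np.array(c)) == pytest.approx(expected)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angle(np.array([1.0, 1.0]), np.array([1.0, 1.0]), np.array([0.0, 0.0]))

    @given(
        st.floats(-50, 50), st.floats(-50, 50),
        st.floats(0.1, 10), st.floats(0, 2 * math.pi),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_translation_rotation_scaling(self, tx, ty, scale, rot):
        a, b, c = np.array([0.0, 0.0]), np.array([1.0, 0.3]), np.array([0.5, 2.0])
        base = joint_angle(a, b, c)
        r = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
        t = np.array([tx, ty])

        def xf(p):
            return scale * (r @ p) + t

        assert joint_angle(xf(a), xf(b), xf(c)) == pytest.approx(base, abs=1e-6)


class TestSegmentReferenceAngle:
    def test_vertical_segment_vs_vertical(self):
        assert segment_reference_angle(
            np.array([0.0, 0.0]), np.array([0.0, 2.0]), "vertical"
        ) == pytest.approx(0.0)

    def test_45_degree_segment(self):
        assert segment_reference_angle(
            np.array([0.0, 0.0]), np.array([1.0, 1.0]), "vertical"
        ) == pytest.approx(45.0)

    def test_horizontal_respects_travel_direction(self):
        p, q = np.array([0.0, 0.0]), np.array([-1.0, 0.0])
        assert segment_reference_angle(p, q, "horizontal", travel_sign=-1) == pytest.approx(0.0)
        assert segment_reference_angle(p, q, "horizontal", travel_sign=1) == pytest.approx(180.0)


class TestWaveletDenoise:
    def test_constant_series_unchanged(self):
        x = np.full(128, 42.0)
        np.testing.assert_allclose(wavelet_denoise(x), x, atol=1e-9)

    def test_zero_threshold_round_trip(self):
        x = np.random.default_rng(0).standard_normal(200)
        np.testing.assert_allclose(wavelet_denoise(x, threshold=0.0), x, atol=1e-9)

    def test_clean_sinusoid_survives_thresholding(self):
        t = np.arange(0, 4.0, 1 / 60)
        x = 10.0 * np.sin(2 * np.pi * 1.0 * t)
        out = wavelet_denoise(x)
        rmse = np.sqrt(np.mean((out - x) ** 2))
        assert rmse < 0.01 * 10.0

    def test_denoising_improves_fidelity_on_noisy_sinusoid(self):
        t = np.arange(0, 4.0, 1 / 60)
        clean = 10.0 * np.sin(2 * np.pi * 1.0 * t)
        wins = 0
        for seed in range(20):
            noisy = clean + np.random.default_rng(seed).normal(0, 10.0 / math.sqrt(10), t.size)
            out = wavelet_denoise(noisy)
            if np.sqrt(np.mean((out - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2)):
                wins += 1
        assert wins == 20

    def test_short_series_identity_fallback(self):
        x = np.arange(8.0)
        np.testing.assert_array_equal(wavelet_denoise(x), x)


class TestPostureSeries:
    def test_static_upright_pose_knee_straight_and_zero_lean(self):
        p = PostureSimParams(
            knee_mean=180.0, knee_half=0, ankle_half=0, elbow_half=0,
            thigh_swing_half=0, arm_swing_half=0, head_bob_half=0,
            trunk_lean=0.0, trunk_sway_half=0, keypoint_noise_sd=0.0,
            dropout_fraction=0.0, seed=1,
        )
        sim = simulate_keypoints(p)
        fseq = filter_frames(sim.sequence)
        series = posture_angle_series(fseq)
        np.testing.assert_allclose(series["knee"].values, 180.0, atol=1e-4)
        np.testing.assert_allclose(series["body_lean"].values, 0.0, atol=1e-4)

    def test_static_pose_variances_zero(self):
        # a fully static pose has no heel strikes, so the time-series half of
        # the extractor is exercised directly: every denoised angle series
        # must have (numerically) zero variance
        p = PostureSimParams(
            knee_half=0, ankle_half=0, elbow_half=0, thigh_swing_half=0,
            arm_swing_half=0, head_bob_half=0, trunk_sway_half=0,
            keypoint_noise_sd=0.0, dropout_fraction=0.0, seed=1,
        )
        sim = simulate_keypoints(p)
        fseq = filter_frames(sim.sequence)
        series = posture_angle_series(fseq)
        for name in ("knee", "ankle", "elbow", "upper_arm_trunk"):
            den = wavelet_denoise(series[name].values)
            assert den.var(ddof=1) == pytest.approx(0.0, abs=1e-9)

    def test_head_pitch_shift_moves_head_to_ground(self):
        base = PostureSimParams(keypoint_noise_sd=1.0, seed=4)
        delta = 7.0
        lowered = PostureSimParams(
            head_pitch_offset=base.head_pitch_offset + delta, keypoint_noise_sd=1.0, seed=4
        )
        pf0 = extract_posture_features(simulate_keypoints(base).sequence, 4.5)
        pf1 = extract_posture_features(simulate_keypoints(lowered).sequence, 4.5)
        assert pf0.head_to_ground_mean - pf1.head_to_ground_mean == pytest.approx(delta, abs=1.0)


class TestSpatiotemporal:
    def test_scale_step_length_and_speed_identity(self, clean_posture_sim):
        sim = clean_posture_sim
        fseq = filter_frames(sim.sequence)
        st_res = spatiotemporal_params(fseq, walkway_length=sim.params.walk_distance)
        assert st_res.scale_m_per_px == pytest.approx(1 / sim.scale_px_per_m, rel=0.01)
        assert st_res.step_length_m == pytest.approx(sim.step_length_m, rel=0.05)
        assert st_res.step_speed_mps == pytest.approx(
            st_res.step_length_m * st_res.cadence_steps_per_s, abs=1e-9
        )
        assert st_res.cadence_steps_per_s == pytest.approx(sim.cadence, rel=0.05)

    def test_heel_height_positive_and_sane(self, clean_posture_sim):
        fseq = filter_frames(clean_posture_sim.sequence)
        st_res = spatiotemporal_params(fseq, walkway_length=5.0)
        assert 0.0 < st_res.heel_height_m < 0.5


class TestEndToEndRecovery:
    def test_angle_means_within_two_degrees_at_3px_noise(self):
        errs_htg, errs_calf = [], []
        for seed in range(20):
            p = PostureSimParams(keypoint_noise_sd=3.0, seed=seed)
            sim = simulate_keypoints(p)
            pf = extract_posture_features(sim.sequence, walkway_length=4.5)
            errs_htg.append(pf.head_to_ground_mean - sim.truth["head_to_ground"].mean())
            errs_calf.append(pf.calf_to_vertical_mean - sim.truth["calf_to_vertical"].mean())
        assert np.max(np.abs(errs_htg)) < 2.0
        assert np.max(np.abs(errs_calf)) < 2.0
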