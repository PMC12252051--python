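"""Standardization chain: outlier repair, smoothing, normalization,
velocities, gait-cycle segmentation, and end-to-end invariances."""

import numpy as np
import pytest

import gaitlens as gl
from gaitlens.preprocessing import (PreprocessConfig, UnrecoverableJointError,
                                    _resample_cycle, compute_velocities,
                                    denoise, normalize_skeleton,
                                    preprocess_sequence,
                                    remove_joint_outliers,
                                    segment_gait_cycles)
from gaitlens.schema import DEFAULT_SCHEMA
from gaitlens.synthetic import corrupt
from gaitlens.types import SkeletonSequence


def _clean_seq(frames=120, seed=0, cycle_period=7, frame_rate=10.0):
    cfg = gl.CohortConfig(n_subjects=1, frames_per_recording=frames,
                          seed=seed, noise_sd=0.0, occlusion_rate=0.0,
                          cycle_period=cycle_period, frame_rate=frame_rate,
                          class_list=(gl.PathologySpec("none"),))
    return gl.generate_cohort(cfg)[0]


def _raw_capture_seq(frames=300, seed=0):
    """Emulates raw 30 Hz capture: ~20-frame gait cycles before any
    downsampling to 7-frame instances."""
    return _clean_seq(frames=frames, seed=seed, cycle_period=20,
                      frame_rate=30.0)


class TestOutlierRepair:
    def test_clean_sequence_unchanged(self):
        seq = _clean_seq()
        out = remove_joint_outliers(seq)
        assert np.array_equal(out.positions, seq.positions)

    def test_sentinel_restored_near_ground_truth(self):
        seq = _raw_capture_seq()
        bad = corrupt(seq, noise_sd=0.0, occlusion_rate=0.03, seed=9)
        repaired = remove_joint_outliers(bad)
        clean = bad.meta["clean_positions"]
        occ = bad.meta["occluded"]
        torso = seq.meta["gait_params"]["torso_len"]
        err = np.abs(repaired.positions - clean).max(axis=2)
        interior = occ.copy()
        interior[[0, -1]] = False  # ends use nearest-valid copy, not interp
        assert err[interior].max() <= 0.10 * torso
        assert err[occ].max() <= 0.20 * torso

    def test_consecutive_displacements_interpolated_monotone(self):
        seq = _raw_capture_seq()
        pos = seq.positions.copy()
        j = DEFAULT_SCHEMA.index("r_wrist")
        anchor_a, anchor_b = pos[19, j].copy(), pos[22, j].copy()
        pos[20, j] += 3.0
        pos[21, j] += 3.0
        bad = seq.copy()
        bad.positions = pos
        repaired = remove_joint_outliers(bad)
        for axis in range(3):
            lo, hi = sorted((anchor_a[axis], anchor_b[axis]))
            assert lo - 1e-9 <= repaired.positions[20, j, axis] <= hi + 1e-9
            assert lo - 1e-9 <= repaired.positions[21, j, axis] <= hi + 1e-9
        err = np.abs(repaired.positions[[20, 21], j] - seq.positions[[20, 21], j])
        assert err.max() <= 0.10 * seq.meta["gait_params"]["torso_len"]

    def test_joint_outlying_everywhere_rejected(self):
        seq = _clean_seq(frames=30)
        pos = seq.positions.copy()
        pos[:, DEFAULT_SCHEMA.index("l_wrist")] += 50.0
        bad = seq.copy()
        bad.positions = pos
        with pytest.raises(UnrecoverableJointError, match="l_wrist"):
            remove_joint_outliers(bad)


class TestDenoise:
    def test_window_one_is_identity(self):
        seq = _clean_seq()
        out = denoise(seq, PreprocessConfig(smoothing_window=1))
        assert np.array_equal(out.positions, seq.positions)

    def test_variance_reduced_on_noisy_constant(self, rng):
        pos = np.zeros((200, 18, 3)) + rng.normal(0, 0.1, size=(200, 18, 3))
        seq = SkeletonSequence(pos, 10.0, "s")
        out = denoise(seq, PreprocessConfig(smoothing_window=5))
        assert out.positions.var() < seq.positions.var()

    def test_sinusoid_attenuation_matches_closed_form(self):
        # moving-average gain at frequency f: sin(pi f w) / (w sin(pi f))
        f, w, n = 0.1, 3, 400
        t = np.arange(n)
        pos = np.zeros((n, 18, 3))
        pos[:, 0, 0] = np.sin(2 * np.pi * f * t)
        seq = SkeletonSequence(pos, 10.0, "s")
        out = denoise(seq, PreprocessConfig(smoothing_window=w))
        interior = out.positions[w:-w, 0, 0]
        gain = np.ptp(interior) / np.ptp(pos[w:-w, 0, 0])
        expected = abs(np.sin(np.pi * f * w) / (w * np.sin(np.pi * f)))
        assert abs(gain - expected) / expected < 0.01

    def test_window_longer_than_sequence_rejected(self):
        seq = _clean_seq(frames=5)
        with pytest.raises(ValueError, match="smoothing_window"):
            denoise(seq, PreprocessConfig(smoothing_window=7))


class TestNormalize:
    def test_idempotent(self):
        out1 = normalize_skeleton(_clean_seq())
        out2 = normalize_skeleton(out1)
        assert np.abs(out2.positions - out1.positions).max() < 1e-12

    def test_scale_invariance(self):
        seq = _clean_seq()
        scaled = seq.copy()
        scaled.positions = seq.positions * 2.0
        a = normalize_skeleton(seq)
        b = normalize_skeleton(scaled)
        assert np.abs(a.positions - b.positions).max() < 1e-9

    def test_torso_lengths_hit_target(self):
        target = 1.0
        for seed, scale in ((0, 0.9), (1, 1.3)):
            seq = _clean_seq(seed=seed)
            seq.positions *= scale
            out = normalize_skeleton(seq, PreprocessConfig(
                normalization_target=target))
            neck = DEFAULT_SCHEMA.index("neck")
            torso = np.linalg.norm(out.positions[:, neck], axis=1)
            assert abs(np.median(torso) - target) < 1e-9

    def test_degenerate_skeleton_rejected(self):
        seq = SkeletonSequence(np.zeros((10, 18, 3)), 10.0, "s")
        with pytest.raises(ValueError, match="degenerate"):
            normalize_skeleton(seq)


class TestVelocities:
    def test_static_skeleton_zero(self):
        seq = SkeletonSequence(np.ones((10, 18, 3)), 10.0, "s")
        assert np.array_equal(compute_velocities(seq), np.zeros((9, 18, 3)))

    def test_uniform_translation_exact(self):
        v = np.array([0.3, -0.1, 0.05])
        pos = np.arange(10)[:, None, None] * v + np.zeros((10, 18, 3))
        seq = SkeletonSequence(pos, 10.0, "s")
        vel = compute_velocities(seq)
        assert np.allclose(vel, v, atol=1e-12)

    def test_sinusoid_matches_discrete_difference(self):
        t = np.arange(50)
        pos = np.zeros((50, 18, 3))
        pos[:, 5, 2] = np.sin(0.3 * t)
        vel = compute_velocities(SkeletonSequence(pos, 10.0, "s"))
        expected = np.sin(0.3 * (t[1:] )) - np.sin(0.3 * t[:-1])
        assert np.allclose(vel[:, 5, 2], expected, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_velocities(SkeletonSequence(np.zeros((1, 18, 3)), 10.0, "s"))


class TestSegmentation:
    def test_fixed_stride_count_arithmetic(self):
        seq = _clean_seq(frames=71)  # 70 velocity frames
        cfg = PreprocessConfig(segmentation_mode="fixed_stride")
        vel = compute_velocities(normalize_skeleton(seq))
        inst = segment_gait_cycles(vel, seq, cfg)
        assert len(inst) == 10
        assert all(i.velocities.shape == (7, 18, 3) for i in inst)

    def test_too_short_sequence_yields_nothing(self):
        seq = _clean_seq(frames=7)  # 6 velocity frames
        cfg = PreprocessConfig(segmentation_mode="fixed_stride")
        vel = compute_velocities(normalize_skeleton(seq))
        assert segment_gait_cycles(vel, seq, cfg) == []

    def test_heel_strike_matches_generator_phase(self):
        hits = total = 0
        for seed in range(4):
            seq = _clean_seq(frames=140, seed=seed)
            true_starts = seq.meta["cycle_starts"]
            norm = normalize_skeleton(denoise(seq))
            vel = compute_velocities(norm)
            segment_gait_cycles(vel, norm, PreprocessConfig())
            detected = norm.meta["detected_cycle_starts"]
            for d in detected:
                total += 1
                hits += int(np.min(np.abs(true_starts - d)) <= 1.0)
        assert total > 10
        assert hits / total >= 0.90

    def test_resample_preserves_endpoints(self):
        vel = np.linspace(0, 1, 11)[:, None, None] * np.ones((11, 18, 3))
        out = _resample_cycle(vel, 7)
        assert out.shape == (7, 18, 3)
        assert np.allclose(out[0], vel[0]) and np.allclose(out[-1], vel[-1])

    def test_temporal_edges_connect_same_joint(self):
        seq = _clean_seq(frames=30)
        inst = preprocess_sequence(seq)[0]
        for (j1, t1), (j2, t2) in inst.temporal_edges:
            assert j1 == j2 and t2 == t1 + 1


class TestEndToEndInvariance:
    def test_translation_and_scale_invariance(self):
        seq = _clean_seq(frames=100)
        moved = seq.copy()
        moved.positions = seq.positions * 3.7 + np.array([5.0, -2.0, 11.0])
        a = preprocess_sequence(seq)
        b = preprocess_sequence(moved)
        assert len(a) == len(b) > 0
        for ia, ib in zip(a, b):
            assert np.abs(ia.velocities - ib.velocities).max() <= 1e-6
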