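import numpy as np
import pytest

from pawss.boxes import Box, decompose_grid
from pawss.scaling import (
    PointPairSample,
    fuse_scale_sets,
    incremental_scale_set,
    klt_scale_set,
    level1_candidates,
    level2_candidates,
    pairwise_scale_ratio,
    track_patch_points,
)
from pawss.synthetic import SceneSpec, generate_sequence


class TestIncrementalScaleSet:
    def test_contains_previous_scale(self):
        s = incremental_scale_set(0.8, 1.003, 11)
        assert np.any(np.isclose(s, 0.8))

    def test_table_parameter_extremes(self):
        s = incremental_scale_set(1.0, 1.003, 11)
        assert len(s) == 11
        assert s[0] == pytest.approx(1.003**-5)
        assert s[-1] == pytest.approx(1.003**5)
        assert s[0] == pytest.approx(0.985134, abs=1e-5)
        assert s[-1] == pytest.approx(1.015090, abs=1e-5)

    def test_geometric_symmetry(self):
        s = incremental_scale_set(1.7, 1.01, 9)
        assert s[0] * s[-1] == pytest.approx(1.7**2)

    def test_even_count_rejected(self):
        with pytest.raises(ValueError):
            incremental_scale_set(1.0, 1.003, 10)


class TestKltScaleSet:
    def test_unit_ratio_collapses_to_previous_scale(self):
        np.testing.assert_allclose(klt_scale_set(1.0, 11), np.ones(11))

    def test_uniform_spacing_up_to_ratio(self):
        s = klt_scale_set(1.5, 11)
        np.testing.assert_allclose(s, np.linspace(1.0, 1.5, 11))

    def test_endpoints_exact(self):
        s = klt_scale_set(0.7, 5)
        assert s[0] == 1.0
        assert s[-1] == 0.7


class TestFusedScaleSet:
    def test_always_contains_previous_scale(self):
        s_r = incremental_scale_set(1.2, 1.003, 11)
        fused = fuse_scale_sets(s_r, klt_scale_set(1.4, 11), 1.2)
        assert np.any(np.isclose(fused, 1.2))
        fused_a = fuse_scale_sets(s_r, None, 1.2)
        assert np.any(np.isclose(fused_a, 1.2))

    def test_deduplicates_union(self):
        s_r = incremental_scale_set(1.0, 1.003, 11)
        fused = fuse_scale_sets(s_r, klt_scale_set(1.0, 11), 1.0)
        assert len(fused) == 11  # all KLT multipliers collapse onto 1.0


class TestPairwiseScaleRatio:
    def make_sample(self, prev, cur, well=None):
        prev = np.asarray(prev, dtype=float)
        cur = np.asarray(cur, dtype=float)
        if well is None:
            well = np.ones(len(prev), dtype=bool)
        return PointPairSample(prev, cur, well)

    def test_uniform_scaling_recovered_exactly(self, rng):
        pts = rng.random((40, 2)) * 50
        sample = self.make_sample(pts, (pts - 25) * 2.0 + 25)
        assert pairwise_scale_ratio(sample) == pytest.approx(2.0)

    def test_pure_translation_gives_unity(self, rng):
        pts = rng.random((40, 2)) * 50
        sample = self.make_sample(pts, pts + [7.0, -3.0])
        assert pairwise_scale_ratio(sample) == pytest.approx(1.0)

    def test_invariant_to_rigid_rotation(self, rng):
        pts = rng.random((30, 2)) * 50
        theta = 0.8
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        sample = self.make_sample(pts, pts @ R.T + [4.0, 9.0])
        assert pairwise_scale_ratio(sample) == pytest.approx(1.0, abs=1e-12)

    def test_low_tracked_ratio_falls_back_to_unity(self, rng):
        pts = rng.random((20, 2)) * 50
        well = np.zeros(20, dtype=bool)
        well[:8] = True  # 40 % < 0.5
        sample = self.make_sample(pts, pts * 3.0, well)
        assert pairwise_scale_ratio(sample) == 1.0

    def test_median_robust_to_outliers(self, rng):
        """80 % inliers scaled 1.5x, 20 % random: estimate within 2 %."""
        for _ in range(20):
            pts = rng.random((100, 2)) * 48
            cur = (pts - 24) * 1.5 + 24
            idx = rng.choice(100, 20, replace=False)
            cur[idx] = rng.random((20, 2)) * 48
            sample = self.make_sample(pts, cur)
            assert pairwise_scale_ratio(sample) == pytest.approx(1.5, rel=0.02)


class TestTrackPatchPoints:
    def textured_frames(self, shift=(0, 0)):
        spec = SceneSpec(frame_size=(96, 96), n_frames=1, target_size=(48, 48), seed=5)
        frame, _ = generate_sequence(spec)
        frame = frame[0]
        shifted = np.roll(frame, (shift[1], shift[0]), axis=(0, 1))
        return frame, shifted

    def test_identical_frames_zero_displacement(self, rng):
        frame, _ = self.textured_frames()
        box = Box(24, 24, 48, 48)
        sample = track_patch_points(frame, frame, box, decompose_grid(box), 5, rng)
        assert sample.tracked_ratio > 0.9
        disp = sample.points_cur - sample.points_prev
        assert np.abs(disp[sample.well_tracked]).max() < 0.1

    def test_translation_recovered(self, rng):
        frame, shifted = self.textured_frames(shift=(3, 0))
        box = Box(24, 24, 48, 48)
        sample = track_patch_points(frame, shifted, box, decompose_grid(box), 5, rng)
        assert sample.tracked_ratio > 0.8
        disp = sample.points_cur[sample.well_tracked] - sample.points_prev[sample.well_tracked]
        np.testing.assert_allclose(disp.mean(axis=0), [3.0, 0.0], atol=0.2)

    def test_textureless_frame_tracks_nothing(self, rng):
        frame = np.full((96, 96, 3), 128, dtype=np.uint8)
        box = Box(24, 24, 48, 48)
        sample = track_patch_points(frame, frame, box, decompose_grid(box), 5, rng)
        assert sample.tracked_ratio < 0.1
        assert pairwise_scale_ratio(sample) == 1.0


class TestTwoLevelCandidates:
    def test_level2_position_count_single_scale(self):
        groups = level2_candidates((50, 50), (20, 20), [1.0], r_s=5, frame_shape=(100, 100))
        assert len(groups) == 1
        assert len(groups[0][1]) == 11 * 11

    def test_level2_count_bounded_by_product(self):
        scales = np.linspace(0.9, 1.3, 22)
        groups = level2_candidates((50, 50), (20, 20), scales, r_s=5, frame_shape=(100, 100))
        total = sum(len(tls) for _, tls, _, _ in groups)
        assert total <= 22 * 121

    def test_level1_degenerate_stride_keeps_previous_box(self):
        box = Box(40, 40, 20, 20)
        r_w = 20
        tls, w, h = level1_candidates(
            box, 1.0, (20, 20), r_w, stride=2 * r_w + 1, frame_shape=(100, 100)
        )
        assert len(tls) == 1
        assert (tls[0] == [40, 40]).all()

    def test_out_of_frame_window_raises(self):
        box = Box(500, 500, 20, 20)
        with pytest.raises(ValueError):
            level1_candidates(box, 1.0, (20, 20), 10, 2, frame_shape=(100, 100))
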