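import numpy as np
import pytest

from pawss.boxes import Box, decompose_grid
from pawss.segmentation import (
    ColourModel,
    N_COLOUR_BINS,
    colour_bin_map,
    init_colour_model,
    posterior_map,
    surround_ring_mask,
    update_colour_model,
    update_patch_weights,
)

from conftest import brute_force_posterior


def two_colour_frame(fg=(224, 16, 16), bg=(16, 16, 224), box=Box(20, 20, 20, 20), size=(64, 64)):
    frame = np.zeros(size + (3,), dtype=np.uint8)
    frame[:] = bg
    x0, x1, y0, y1 = box.clipped(size[1], size[0])
    frame[y0:y1, x0:x1] = fg
    return frame


def uniform_model(delta=0.1):
    u = np.full(N_COLOUR_BINS, 1.0 / N_COLOUR_BINS)
    return ColourModel(fg=u.copy(), bg=u.copy(), delta=delta)


class TestInit:
    def test_separable_colours_concentrate_histograms(self):
        box = Box(20, 20, 20, 20)
        frame = two_colour_frame(box=box)
        model = init_colour_model(frame, box)
        red_bin = colour_bin_map(np.array([[[224, 16, 16]]], dtype=np.uint8))[0, 0]
        blue_bin = colour_bin_map(np.array([[[16, 16, 224]]], dtype=np.uint8))[0, 0]
        assert model.fg[red_bin] > 0.4
        assert model.bg[blue_bin] > 0.4
        assert model.fg.sum() == pytest.approx(1.0)
        assert model.bg.sum() == pytest.approx(1.0)

    def test_box_covering_frame_falls_back_to_smoothing(self):
        frame = two_colour_frame()
        model = init_colour_model(frame, Box(0, 0, 64, 64))
        np.testing.assert_allclose(model.bg, 1.0 / N_COLOUR_BINS)

    def test_histograms_match_brute_force_region_counts(self, random_frame):
        box = Box(18, 22, 18, 16)
        model = init_colour_model(random_frame, box)
        bins = colour_bin_map(random_frame)
        x0, x1, y0, y1 = box.clipped(64, 64)
        fg_counts = np.ones(N_COLOUR_BINS)  # add-one smoothing
        for yy in range(y0, y1):
            for xx in range(x0, x1):
                fg_counts[bins[yy, xx]] += 1
        np.testing.assert_allclose(model.fg, fg_counts / fg_counts.sum(), atol=1e-12)
        ring = surround_ring_mask((64, 64), box)
        bg_counts = np.ones(N_COLOUR_BINS)
        for yy in range(64):
            for xx in range(64):
                if ring[yy, xx]:
                    bg_counts[bins[yy, xx]] += 1
        np.testing.assert_allclose(model.bg, bg_counts / bg_counts.sum(), atol=1e-12)


class TestPosterior:
    def test_equal_likelihoods_give_half(self, random_frame):
        post = posterior_map(uniform_model(), random_frame, Box(0, 0, 64, 64))
        np.testing.assert_allclose(post, 0.5)

    def test_likelihood_ratio_two_gives_two_thirds(self):
        frame = np.zeros((8, 8, 3), dtype=np.uint8)
        bin0 = colour_bin_map(frame)[0, 0]
        fg = np.full(N_COLOUR_BINS, 0.5 / (N_COLOUR_BINS - 1))
        bg = np.full(N_COLOUR_BINS, 0.75 / (N_COLOUR_BINS - 1))
        fg[bin0], bg[bin0] = 0.5, 0.25
        model = ColourModel(fg=fg, bg=bg, delta=0.1)
        post = posterior_map(model, frame, Box(0, 0, 8, 8))
        np.testing.assert_allclose(post, 2.0 / 3.0)

    def test_transition_prior_from_certain_foreground(self, random_frame):
        """prev = 1 with equal likelihoods yields the fg-fg transition prior."""
        prev = np.ones((64, 64))
        post = posterior_map(uniform_model(), random_frame, Box(0, 0, 64, 64), prev)
        np.testing.assert_allclose(post, 0.6)

    def test_matches_brute_force_loop(self, random_frame, rng):
        fg = rng.random(N_COLOUR_BINS) + 1e-3
        bg = rng.random(N_COLOUR_BINS) + 1e-3
        model = ColourModel(fg=fg / fg.sum(), bg=bg / bg.sum(), delta=0.1)
        prev = rng.random((64, 64))
        region = Box(5, 9, 40, 30)
        got = posterior_map(model, random_frame, region, prev)
        want = brute_force_posterior(model, random_frame, region, prev)
        np.testing.assert_allclose(got, want, atol=1e-10)
        assert np.all(got >= 0) and np.all(got <= 1)


class TestModelUpdate:
    def test_equal_weights_reduce_to_plain_histogram(self, random_frame):
        box = Box(10, 10, 28, 28)
        grid = decompose_grid(box)
        model = uniform_model(delta=1.0)
        updated = update_colour_model(model, random_frame, box, np.full(49, 0.7), grid)
        bins = colour_bin_map(random_frame)
        x0, x1, y0, y1 = box.clipped(64, 64)
        plain = np.bincount(bins[y0:y1, x0:x1].ravel(), minlength=N_COLOUR_BINS)
        np.testing.assert_allclose(updated.fg, plain / plain.sum(), atol=1e-12)

    def test_delta_zero_leaves_model_unchanged(self, random_frame):
        box = Box(10, 10, 28, 28)
        model = uniform_model(delta=0.0)
        updated = update_colour_model(
            model, random_frame, box, np.ones(49), decompose_grid(box)
        )
        np.testing.assert_array_equal(updated.fg, model.fg)
        np.testing.assert_array_equal(updated.bg, model.bg)

    def test_zero_weight_patch_contributes_nothing(self):
        """Two-patch toy: only the weighted patch's colour enters the update."""
        frame = np.zeros((8, 16, 3), dtype=np.uint8)
        frame[:, :8] = (224, 16, 16)
        frame[:, 8:] = (16, 224, 16)
        box = Box(0, 0, 16, 8)
        grid = decompose_grid(box, rows=1, cols=2)
        model = uniform_model(delta=1.0)
        updated = update_colour_model(model, frame, box, np.array([1.0, 0.0]), grid)
        red_bin = colour_bin_map(frame)[0, 0]
        green_bin = colour_bin_map(frame)[0, 8]
        assert updated.fg[red_bin] == pytest.approx(1.0)
        assert updated.fg[green_bin] == pytest.approx(0.0)

    def test_all_zero_weights_skip_fg_update(self, random_frame):
        box = Box(10, 10, 28, 28)
        model = uniform_model(delta=0.5)
        updated = update_colour_model(
            model, random_frame, box, np.zeros(49), decompose_grid(box)
        )
        np.testing.assert_array_equal(updated.fg, model.fg)

    def test_weighted_update_matches_brute_force(self, random_frame, rng):
        box = Box(6, 8, 30, 26)
        grid = decompose_grid(box)
        weights = rng.random(49)
        model = uniform_model(delta=0.3)
        got = update_colour_model(model, random_frame, box, weights, grid)
        bins = colour_bin_map(random_frame)
        empirical = np.zeros(N_COLOUR_BINS)
        total = 0.0
        for w_i, (rx, ry, rw, rh) in zip(weights, grid.rects):
            for yy in range(ry, ry + rh):
                for xx in range(rx, rx + rw):
                    empirical[bins[yy, xx]] += w_i
                    total += w_i
        expected_fg = 0.3 * empirical / total + 0.7 * model.fg
        np.testing.assert_allclose(got.fg, expected_fg / expected_fg.sum(), atol=1e-10)


class TestPatchWeights:
    def grid(self):
        return decompose_grid(Box(0, 0, 14, 14), rows=1, cols=2)

    def test_full_posterior_formula(self):
        grid = decompose_grid(Box(0, 0, 28, 28))
        w_prev = np.full(49, 0.4)
        post = np.ones((64, 64))
        w = update_patch_weights(w_prev, post, grid, delta=0.1)
        np.testing.assert_allclose(w, 0.1 * 1.0 + 0.9 * 0.4)

    def test_hand_computed_two_patch_case(self):
        """Patch means (0.8, 0.4) with delta 0.1 blend to (1.0, 0.95)."""
        post = np.zeros((14, 14))
        post[:, :7] = 0.8
        post[:, 7:] = 0.4
        w = update_patch_weights(np.ones(2), post, self.grid(), delta=0.1)
        np.testing.assert_allclose(w, [1.0, 0.95])

    def test_delta_one_converges_in_one_step(self):
        post = np.zeros((14, 14))
        post[:, :7] = 0.6
        post[:, 7:] = 0.3
        w = update_patch_weights(np.ones(2), post, self.grid(), delta=1.0)
        np.testing.assert_allclose(w, [1.0, 0.5])

    def test_all_zero_posterior_leaves_weights(self):
        w_prev = np.array([0.3, 0.9])
        w = update_patch_weights(w_prev, np.zeros((14, 14)), self.grid(), delta=0.1)
        np.testing.assert_array_equal(w, w_prev)

    def test_weights_stay_in_unit_interval_and_max_normalised(self, rng):
        """Random posterior streams keep w in [0,1]; w_bar max is 1 each frame."""
        grid = decompose_grid(Box(0, 0, 28, 28))
        w = np.ones(49)
        for _ in range(30):
            post = rng.random((32, 32))
            varpi = np.array(
                [post[ry : ry + rh, rx : rx + rw].mean() for rx, ry, rw, rh in grid.rects]
            )
            w_bar = varpi / varpi.max()
            assert w_bar.max() == pytest.approx(1.0)
            w = update_patch_weights(w, post, grid, delta=0.1)
            assert np.all(w >= 0.0) and np.all(w <= 1.0 + 1e-12)

    def test_matches_brute_force_patch_means(self, rng):
        grid = decompose_grid(Box(3, 5, 26, 22))
        post = rng.random((64, 64))
        w_prev = rng.random(49)
        got = update_patch_weights(w_prev, post, grid, delta=0.25)
        varpi = np.zeros(49)
        for i, (rx, ry, rw, rh) in enumerate(grid.rects):
            acc = [post[yy, xx] for yy in range(ry, ry + rh) for xx in range(rx, rx + rw)]
            varpi[i] = np.mean(acc)
        expected = 0.25 * varpi / varpi.max() + 0.75 * w_prev
        np.testing.assert_allclose(got, expected, atol=1e-10)
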