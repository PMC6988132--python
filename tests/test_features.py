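import numpy as np
import pytest

from pawss.boxes import Box
from pawss.features import (
    FrameFeatures,
    build_descriptor,
    colour_histogram,
    descriptor_length,
    gradient_histogram,
)

from conftest import brute_force_colour_histogram, brute_force_gradient_histogram


def uniform_image(rgb, size=(32, 32)):
    img = np.zeros(size + (3,), dtype=np.uint8)
    img[:] = rgb
    return img


class TestColourHistogram:
    def test_pure_red_rgb_one_hot(self):
        img = uniform_image((255, 0, 0))
        h = colour_histogram(img, Box(0, 0, 16, 16), space="rgb")
        # top R bin, bottom G and B bins each carry 1/3 after normalisation
        assert h[7] == pytest.approx(1 / 3)
        assert h[8] == pytest.approx(1 / 3)  # G bin 0
        assert h[16] == pytest.approx(1 / 3)  # B bin 0
        assert h.sum() == pytest.approx(1.0)

    def test_half_red_half_blue_split(self):
        img = uniform_image((255, 0, 0))
        img[:, 16:] = (0, 0, 255)
        h = colour_histogram(img, Box(0, 0, 32, 32), space="rgb")
        # R marginal: half the pixels in top bin, half in bottom
        assert h[7] == pytest.approx(h[0])
        assert h[23] == pytest.approx(h[16])

    @pytest.mark.parametrize("space", ["rgb", "hsv"])
    def test_matches_brute_force_binning(self, random_frame, space):
        rect = Box(13, 9, 16, 16)
        got = colour_histogram(random_frame, rect, space=space)
        want = brute_force_colour_histogram(random_frame, rect, space)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_empty_rect_rejected(self, random_frame):
        with pytest.raises(ValueError):
            colour_histogram(random_frame, Box(100, 100, 10, 10))


class TestGradientHistogram:
    def test_flat_rect_is_all_zero(self):
        img = uniform_image((128, 128, 128))
        h = gradient_histogram(img, Box(4, 4, 10, 10))
        assert np.all(h == 0)

    def test_horizontal_step_edge_votes_at_90_degrees(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[16:] = 255  # dark above, bright below: gradient points down (+y)
        h = gradient_histogram(img, Box(0, 0, 32, 32))
        assert h[4] == pytest.approx(1.0)  # bin containing 90 degrees

    def test_matches_brute_force_voting(self, random_frame):
        rect = Box(7, 21, 20, 14)
        got = gradient_histogram(random_frame, rect)
        want = brute_force_gradient_histogram(random_frame, rect)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestBuildDescriptor:
    def test_length_hsv_plus_gradient(self, random_frame):
        d = build_descriptor(random_frame, Box(0, 0, 49, 49), np.ones(49))
        assert d.shape == (49 * 36,)
        assert descriptor_length("hsv", True, 49) == 1764

    def test_identity_weights_concatenate_blocks(self, random_frame):
        box = Box(2, 3, 42, 35)
        d = build_descriptor(random_frame, box, np.ones(49), space="rgb")
        from pawss.boxes import decompose_grid

        grid = decompose_grid(box)
        first = np.concatenate(
            [
                colour_histogram(random_frame, Box(*grid.rects[0]), "rgb"),
                gradient_histogram(random_frame, Box(*grid.rects[0])),
            ]
        )
        np.testing.assert_allclose(d[:40], first)

    def test_zero_weights_give_zero_vector(self, random_frame):
        d = build_descriptor(random_frame, Box(0, 0, 50, 50), np.zeros(49))
        assert np.all(d == 0)

    def test_linear_in_single_weight(self, random_frame):
        """Doubling one patch weight doubles that block and nothing else."""
        box = Box(5, 5, 40, 40)
        w = np.ones(49)
        base = build_descriptor(random_frame, box, w)
        w[10] = 2.0
        scaled = build_descriptor(random_frame, box, w)
        blk = slice(10 * 36, 11 * 36)
        np.testing.assert_allclose(scaled[blk], 2.0 * base[blk])
        mask = np.ones(len(base), dtype=bool)
        mask[blk] = False
        np.testing.assert_array_equal(scaled[mask], base[mask])

    def test_histograms_translation_invariant_on_constant_texture(self):
        img = uniform_image((40, 200, 90), size=(64, 64))
        a = build_descriptor(img, Box(1, 1, 21, 21), np.ones(49))
        b = build_descriptor(img, Box(30, 25, 21, 21), np.ones(49))
        np.testing.assert_allclose(a, b)

    def test_weight_length_mismatch_rejected(self, random_frame):
        with pytest.raises(ValueError):
            build_descriptor(random_frame, Box(0, 0, 50, 50), np.ones(10))


class TestFrameFeatures:
    """The integral-image fast path must agree with the direct route."""

    @pytest.mark.parametrize("space,use_grad", [("hsv", True), ("rgb", True), ("hsv", False)])
    def test_matches_direct_descriptor(self, random_frame, rng, space, use_grad):
        ff = FrameFeatures(random_frame, space, use_grad)
        w = rng.random(49)
        for tl in [(2, 3), (-5, 10), (30, 28)]:
            X = ff.descriptors(np.array([tl]), 30, 28, w)
            ref = build_descriptor(
                random_frame, Box(tl[0], tl[1], 30, 28), w, space, use_grad
            )
            np.testing.assert_allclose(X[0], ref, atol=1e-9)

    def test_batch_shape(self, random_frame):
        ff = FrameFeatures(random_frame)
        tls = np.array([[0, 0], [5, 5], [10, 2]])
        X = ff.descriptors(tls, 20, 21, np.ones(49))
        assert X.shape == (3, 1764)
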