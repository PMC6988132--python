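import numpy as np
import pytest

from pawss.boxes import Box


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_frame(rng):
    """Random 64x64 colour frame for oracle-equivalence checks."""
    return rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)


@pytest.fixture
def centre_box():
    return Box(10, 12, 40, 36)


def brute_force_colour_histogram(image, rect, space):
    """Independent per-pixel binning loop (no vectorised shortcuts)."""
    from skimage.color import rgb2hsv

    x0, x1, y0, y1 = rect.clipped(image.shape[1], image.shape[0])
    if space == "rgb":
        bins_per_channel = (8, 8, 8)
        values = image.astype(np.float64) / 255.0
    else:
        bins_per_channel = (8, 8, 4)
        values = rgb2hsv(image.astype(np.float64) / 255.0)
    hist = [np.zeros(n) for n in bins_per_channel]
    for yy in range(y0, y1):
        for xx in range(x0, x1):
            for c, n in enumerate(bins_per_channel):
                b = min(int(values[yy, xx, c] * n), n - 1)
                hist[c][b] += 1.0
    out = np.concatenate(hist)
    return out / out.sum()


def brute_force_gradient_histogram(image, rect):
    """Independent per-pixel magnitude-weighted orientation voting."""
    grey = image.astype(np.float64) / 255.0 @ np.array([0.299, 0.587, 0.114])
    height, width = grey.shape
    x0, x1, y0, y1 = rect.clipped(width, height)
    hist = np.zeros(16)
    for yy in range(y0, y1):
        for xx in range(x0, x1):
            xm, xp = max(xx - 1, 0), min(xx + 1, width - 1)
            ym, yp = max(yy - 1, 0), min(yy + 1, height - 1)
            gx = (grey[yy, xp] - grey[yy, xm]) / 2.0
            gy = (grey[yp, xx] - grey[ym, xx]) / 2.0
            mag = np.hypot(gx, gy)
            ang = np.degrees(np.arctan2(gy, gx)) % 360.0
            hist[min(int(ang / 22.5), 15)] += mag
    total = hist.sum()
    return hist / total if total > 0 else hist


def brute_force_posterior(model, frame, rect, prev):
    """Per-pixel recursive-Bayes posterior loop."""
    x0, x1, y0, y1 = rect.clipped(frame.shape[1], frame.shape[0])
    out = np.zeros((y1 - y0, x1 - x0))
    for yy in range(y0, y1):
        for xx in range(x0, x1):
            r, g, b = (int(v) >> 5 for v in frame[yy, xx])
            bin_i = (r << 6) | (g << 3) | b
            p_prev = 0.5 if prev is None else float(prev[yy, xx])
            prior = model.p_fg_fg * p_prev + model.p_fg_bg * (1.0 - p_prev)
            num = model.fg[bin_i] * prior
            den = num + model.bg[bin_i] * (1.0 - prior)
            out[yy - y0, xx - x0] = num / den if den > 0 else prior
    return out
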