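"""Recursive-Bayes colour segmentation and patch weighting.

A global foreground/background colour model discriminates target pixels from
surround pixels inside the tracked box.  Colours are quantised to a joint
RGB histogram with 8 bins per channel (512 bins).  The model keeps

* ``fg``: p(y | c = 1), the foreground colour likelihood,
* ``bg``: p(y | c = 0), the background colour likelihood,
* class-transition priors p(c_t = 1 | c_{t-1} = 1) = 0.6 and
  p(c_t = 1 | c_{t-1} = 0) = 0.4,
* an update factor ``delta`` in [0, 1] blending new evidence into the model.

Per pixel, the foreground posterior is the recursive-Bayes update

    prior = 0.6 * prev + 0.4 * (1 - prev)
    posterior = fg(y) * prior / (fg(y) * prior + bg(y) * (1 - prior))

with ``prev`` the previous frame's posterior at the same image location
(0.5 where undefined).  The foreground histogram is refreshed each frame from
the winning box, every pixel's count weighted by the weight of the patch it
falls in, and blended with factor ``delta``; the background histogram is
refreshed symmetrically from a surrounding ring with uniform unit weights.

Patch weights are the per-patch mean posterior, normalised so the strongest
patch has weight exactly 1 each frame, then blended over time with the same
``delta`` — patches that persistently cover background decay towards 0 and
their feature blocks are suppressed in the descriptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .boxes import Box, PatchGrid

logger = logging.getLogger(__name__)

N_COLOUR_BINS = 512  # 8 x 8 x 8 joint RGB

TRANSITION_FG_FG = 0.6  # p(c_t=1 | c_{t-1}=1)
TRANSITION_FG_BG = 0.4  # p(c_t=1 | c_{t-1}=0)


def colour_bin_map(frame: np.ndarray) -> np.ndarray:
    """Joint 512-bin colour index per pixel (8 bins per RGB channel)."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) colour frame")
    if frame.dtype != np.uint8:
        frame = np.clip(frame, 0, 255).astype(np.uint8)
    r = frame[..., 0].astype(np.intp) >> 5
    g = frame[..., 1].astype(np.intp) >> 5
    b = frame[..., 2].astype(np.intp) >> 5
    return (r << 6) | (g << 3) | b


@dataclass(frozen=True)
class ColourModel:
    """Foreground/background colour likelihoods with transition priors."""

    fg: np.ndarray  # p(y | c=1), sums to 1
    bg: np.ndarray  # p(y | c=0), sums to 1
    delta: float
    p_fg_fg: float = TRANSITION_FG_FG
    p_fg_bg: float = TRANSITION_FG_BG

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")


def surround_ring_mask(
    frame_shape: Tuple[int, int],
    box: Box,
    margin_frac: float = 0.4,
    ring_frac: float = 0.5,
) -> np.ndarray:
    """Boolean mask of the background ring around ``box``.

    The ring excludes a margin gap of ``margin_frac`` times the box dimensions
    on each side and extends a further ``ring_frac`` times the box dimensions.
    Falls back to whole-frame-minus-box when the ring is entirely outside the
    frame.
    """
    height, width = frame_shape[:2]
    x, y, w, h = box.int_rect()
    gx, gy = margin_frac * w, margin_frac * h
    rx, ry = ring_frac * w, ring_frac * h
    inner = Box(x - gx, y - gy, w + 2 * gx, h + 2 * gy)
    outer = Box(x - gx - rx, y - gy - ry, w + 2 * (gx + rx), h + 2 * (gy + ry))
    mask = np.zeros((height, width), dtype=bool)
    ox0, ox1, oy0, oy1 = outer.clipped(width, height)
    if ox0 < ox1 and oy0 < oy1:
        mask[oy0:oy1, ox0:ox1] = True
    ix0, ix1, iy0, iy1 = inner.clipped(width, height)
    if ix0 < ix1 and iy0 < iy1:
        mask[iy0:iy1, ix0:ix1] = False
    if not mask.any():
        logger.warning(
            "background ring entirely outside frame; falling back to "
            "whole-frame-minus-box background region"
        )
        mask[:, :] = True
        bx0, bx1, by0, by1 = box.clipped(width, height)
        if bx0 < bx1 and by0 < by1:
            mask[by0:by1, bx0:bx1] = False
    return mask


def _normalised_counts(bins: np.ndarray, smooth: float = 1.0) -> np.ndarray:
    counts = np.bincount(bins.ravel(), minlength=N_COLOUR_BINS).astype(np.float64)
    counts += smooth  # Laplace smoothing keeps likelihood ratios finite
    return counts / counts.sum()


def init_colour_model(
    frame: np.ndarray,
    box: Box,
    margin_frac: float = 0.4,
    ring_frac: float = 0.5,
    delta: float = 0.1,
) -> ColourModel:
    """Initialise fg/bg histograms from inside the box and its surround ring."""
    height, width = np.shape(frame)[:2]
    bins = colour_bin_map(frame)
    x0, x1, y0, y1 = box.clipped(width, height)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("initial box lies entirely outside the frame")
    fg = _normalised_counts(bins[y0:y1, x0:x1])
    ring = surround_ring_mask((height, width), box, margin_frac, ring_frac)
    if ring.any():
        bg = _normalised_counts(bins[ring])
    else:  # box covers the whole frame: smoothing only
        bg = np.full(N_COLOUR_BINS, 1.0 / N_COLOUR_BINS)
    return ColourModel(fg=fg, bg=bg, delta=delta)


def posterior_map(
    model: ColourModel,
    frame: np.ndarray,
    region: Box,
    prev: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-pixel foreground posterior over ``region``.

    ``prev`` is the previous posterior as a full-frame array in image
    coordinates (``None`` or value 0.5 for the first frame / fresh pixels).
    Returns the posterior for the clipped region, aligned to
    ``region.clipped(...)`` bounds.
    """
    height, width = np.shape(frame)[:2]
    x0, x1, y0, y1 = region.clipped(width, height)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("posterior region lies entirely outside the frame")
    bins = colour_bin_map(frame)[y0:y1, x0:x1]
    if prev is None:
        prev_region = np.full(bins.shape, 0.5)
    else:
        prev_region = np.asarray(prev, dtype=np.float64)[y0:y1, x0:x1]
    prior = model.p_fg_fg * prev_region + model.p_fg_bg * (1.0 - prev_region)
    fg_lik = model.fg[bins]
    bg_lik = model.bg[bins]
    num = fg_lik * prior
    den = num + bg_lik * (1.0 - prior)
    # bins with both likelihoods zero (impossible under smoothing) fall back
    # to the prior
    return np.where(den > 0, np.divide(num, den, out=prior.copy(), where=den > 0), prior)


def update_colour_model(
    model: ColourModel,
    frame: np.ndarray,
    box: Box,
    weights: np.ndarray,
    grid: PatchGrid,
    margin_frac: float = 0.4,
    ring_frac: float = 0.5,
) -> ColourModel:
    """Blend patch-weighted box evidence (fg) and ring evidence (bg) into the model.

    The empirical foreground distribution counts every pixel with the weight
    of the patch containing it (weights are the previous frame's weights),
    normalised by the weighted total pixel count.  Both histograms are blended
    with factor ``delta`` and re-normalised.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (grid.n_patches,):
        raise ValueError("weights length does not match the patch grid")
    height, width = np.shape(frame)[:2]
    bins = colour_bin_map(frame)

    empirical = np.zeros(N_COLOUR_BINS)
    total = 0.0
    for w_i, (rx, ry, rw, rh) in zip(weights, grid.rects):
        rect = Box(rx, ry, rw, rh)
        x0, x1, y0, y1 = rect.clipped(width, height)
        if x0 >= x1 or y0 >= y1:
            continue
        empirical += w_i * np.bincount(
            bins[y0:y1, x0:x1].ravel(), minlength=N_COLOUR_BINS
        )
        total += w_i * (x1 - x0) * (y1 - y0)

    if total > 0:
        fg = model.delta * (empirical / total) + (1.0 - model.delta) * model.fg
        fg = fg / fg.sum()
    else:
        logger.warning("all-zero patch weights: skipping foreground model update")
        fg = model.fg

    ring = surround_ring_mask((height, width), box, margin_frac, ring_frac)
    if ring.any():
        ring_hist = np.bincount(bins[ring].ravel(), minlength=N_COLOUR_BINS).astype(
            np.float64
        )
        bg = model.delta * (ring_hist / ring_hist.sum()) + (1.0 - model.delta) * model.bg
        bg = bg / bg.sum()
    else:
        bg = model.bg
    return replace(model, fg=fg, bg=bg)


def update_patch_weights(
    weights: np.ndarray,
    posterior: np.ndarray,
    grid: PatchGrid,
    delta: float,
) -> np.ndarray:
    """Blend per-patch mean posteriors into the patch weights.

    ``posterior`` is a full-frame array (image coordinates) covering all grid
    rects.  The per-patch mean posterior is normalised so the maximum weight
    update is exactly 1, then blended: ``w_t = delta * w_bar + (1 - delta) *
    w_{t-1}``.  If every patch mean is zero the weights are returned unchanged.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (grid.n_patches,):
        raise ValueError("weights length does not match the patch grid")
    posterior = np.asarray(posterior, dtype=np.float64)
    height, width = posterior.shape

    varpi = np.zeros(grid.n_patches)
    for i, (rx, ry, rw, rh) in enumerate(grid.rects):
        x0, x1, y0, y1 = Box(rx, ry, rw, rh).clipped(width, height)
        if x0 >= x1 or y0 >= y1:
            continue
        varpi[i] = posterior[y0:y1, x0:x1].mean()

    top = varpi.max()
    if top <= 0:
        logger.warning("all patch posteriors zero: leaving weights unchanged")
        return weights.copy()
    w_bar = varpi / top
    return delta * w_bar + (1.0 - delta) * weights
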