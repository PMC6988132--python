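"""Two-level candidate sampling and scale-set construction.

The tracker localises in two passes:

* **level 1** — candidates at the previous frame's scale, centres on a
  coarse grid (stride 2 by default) covering a square window of half-extent
  ``r_w`` around the previous box centre.  The best-scoring candidate is not
  the final answer but the search centre for level 2.
* **level 2** — candidates at every scale in a fused scale set, centres on a
  dense (stride-1) grid of half-extent ``r_s`` (5 px) around the level-1
  winner.

Two complementary scale sets feed level 2:

* the incremental set ``S_r = {lambda^m * s_prev}`` for symmetric integer
  ``m`` — small geometric steps around the previous scale (``lambda`` is
  slightly above 1, 1.003 by default), covering gradual drift;
* the KLT set ``S_p``: random points are drawn inside every patch of the
  previous box, tracked by pyramidal Lucas-Kanade, and the median pairwise
  distance ratio between frames estimates an abrupt scale change ``s_p``;
  ``n_p`` multipliers uniformly span [1, s_p].  When fewer than half the
  points track well the estimate is distrusted and ``s_p = 1``, so the set
  degenerates to the previous scale.

The fused set is the deduplicated union; it always contains the previous
scale, so the tracker can never be forced into a scale change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .boxes import Box, PatchGrid, round_half_up
from .features import luma
from .lk import track_points


@dataclass(frozen=True)
class PointPairSample:
    """Matched point sets between consecutive frames with per-point status."""

    points_prev: np.ndarray  # (N, 2) of (x, y)
    points_cur: np.ndarray  # (N, 2)
    well_tracked: np.ndarray  # (N,) bool

    def __post_init__(self) -> None:
        if len(self.points_prev) != len(self.points_cur) or len(
            self.points_prev
        ) != len(self.well_tracked):
            raise ValueError("matched point arrays must have equal lengths")

    @property
    def tracked_ratio(self) -> float:
        n = len(self.well_tracked)
        return float(self.well_tracked.sum()) / n if n else 0.0


def incremental_scale_set(s_prev: float, lambda_: float, n_r: int) -> np.ndarray:
    """Geometric scales ``{lambda^m * s_prev}``, m symmetric around 0, sorted."""
    if s_prev <= 0:
        raise ValueError("s_prev must be positive")
    if lambda_ <= 1.0:
        raise ValueError("lambda must be greater than 1")
    if n_r < 1 or n_r % 2 == 0:
        raise ValueError("n_r must be a positive odd number (symmetric exponents)")
    half = (n_r - 1) // 2
    m = np.arange(-half, half + 1)
    return np.sort(lambda_**m * s_prev)


def klt_scale_set(s_p: float, n_p: int) -> np.ndarray:
    """``n_p`` multipliers uniformly spanning [1, s_p] (or [s_p, 1]).

    The values multiply the previous frame's scale; endpoints are exactly 1
    and ``s_p``.
    """
    if s_p <= 0:
        raise ValueError("s_p must be positive")
    if n_p < 2:
        raise ValueError("n_p must be at least 2")
    i = np.arange(n_p)
    return 1.0 + i * (s_p - 1.0) / (n_p - 1)


def fuse_scale_sets(
    s_r: np.ndarray, s_p_multipliers: np.ndarray | None, s_prev: float
) -> np.ndarray:
    """Union of the incremental set and the KLT multipliers applied to s_prev."""
    values = np.asarray(s_r, dtype=np.float64)
    if s_p_multipliers is not None:
        values = np.concatenate([values, np.asarray(s_p_multipliers) * s_prev])
    # dedup on a fine grid so lambda^0 * s_prev and 1 * s_prev collapse
    _, idx = np.unique(np.round(values, 12), return_index=True)
    return np.sort(values[np.sort(idx)])


def sample_grid_points(grid: PatchGrid, n_pt: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_pt`` points uniformly inside each patch (row-major order)."""
    points = np.empty((grid.n_patches * n_pt, 2))
    for i, (x, y, w, h) in enumerate(grid.rects):
        points[i * n_pt : (i + 1) * n_pt, 0] = x + rng.random(n_pt) * w
        points[i * n_pt : (i + 1) * n_pt, 1] = y + rng.random(n_pt) * h
    return points


def track_patch_points(
    frame_prev: np.ndarray,
    frame_cur: np.ndarray,
    box_prev: Box,
    grid: PatchGrid,
    n_pt: int,
    rng: np.random.Generator,
    win: int = 21,
    levels: int = 3,
    fb_threshold: float = 1.0,
) -> PointPairSample:
    """Sample points on the previous box's patches and track them forward.

    A point is well-tracked iff the forward and backward Lucas-Kanade passes
    both succeed and the forward-backward error is below ``fb_threshold``
    pixels.
    """
    if np.shape(frame_prev)[:2] != np.shape(frame_cur)[:2]:
        raise ValueError("frames must have the same dimensions")
    points = sample_grid_points(grid, n_pt, rng)
    grey_prev = luma(frame_prev)
    grey_cur = luma(frame_cur)
    fwd, status_f = track_points(grey_prev, grey_cur, points, win=win, levels=levels)
    back, status_b = track_points(grey_cur, grey_prev, fwd, win=win, levels=levels)
    fb_err = np.hypot(back[:, 0] - points[:, 0], back[:, 1] - points[:, 1])
    well = status_f & status_b & (fb_err < fb_threshold)
    return PointPairSample(points_prev=points, points_cur=fwd, well_tracked=well)


def pairwise_scale_ratio(
    sample: PointPairSample,
    eps: float = 1e-6,
    min_tracked_ratio: float = 0.5,
) -> float:
    """Median pairwise distance ratio of well-tracked points.

    All ordered pairs (i != j) contribute; the median of the sorted ratio set
    is the lower middle element for even counts.  Falls back to 1.0 when the
    tracked ratio is below ``min_tracked_ratio`` or no valid pairs exist.
    """
    if sample.tracked_ratio < min_tracked_ratio:
        return 1.0
    prev = sample.points_prev[sample.well_tracked]
    cur = sample.points_cur[sample.well_tracked]
    if len(prev) < 2:
        return 1.0
    diff_prev = prev[:, None, :] - prev[None, :, :]
    diff_cur = cur[:, None, :] - cur[None, :, :]
    iu = np.triu_indices(len(prev), k=1)
    d_prev = np.hypot(diff_prev[..., 0], diff_prev[..., 1])[iu]
    d_cur = np.hypot(diff_cur[..., 0], diff_cur[..., 1])[iu]
    valid = d_prev > eps
    if not valid.any():
        return 1.0
    ratios = d_cur[valid] / d_prev[valid]
    # every unordered pair appears twice in the i != j ratio set
    v = np.sort(np.concatenate([ratios, ratios]))
    return float(v[(len(v) - 1) // 2])


def scaled_box_size(
    base_wh: Tuple[int, int], scale: float, min_side: int = 7
) -> Tuple[int, int]:
    """Integer box size at ``scale`` relative to the frame-1 box (aspect kept)."""
    w = max(min_side, round_half_up(base_wh[0] * scale))
    h = max(min_side, round_half_up(base_wh[1] * scale))
    return w, h


def _centre_grid(
    centre: Tuple[float, float], half_extent: int, stride: int
) -> np.ndarray:
    # symmetric about zero so the previous position is always a candidate
    k = half_extent // stride
    offsets = stride * np.arange(-k, k + 1)
    cx = round_half_up(centre[0]) + offsets
    cy = round_half_up(centre[1]) + offsets
    gx, gy = np.meshgrid(cx, cy)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def _filter_visible(
    top_lefts: np.ndarray, w: int, h: int, frame_shape: Tuple[int, int]
) -> np.ndarray:
    height, width = frame_shape
    x = top_lefts[:, 0]
    y = top_lefts[:, 1]
    keep = (x + w > 0) & (y + h > 0) & (x < width) & (y < height)
    return top_lefts[keep]


def level1_candidates(
    box_prev: Box,
    s_prev: float,
    base_wh: Tuple[int, int],
    r_w: int,
    stride: int,
    frame_shape: Tuple[int, int],
    min_side: int = 7,
) -> Tuple[np.ndarray, int, int]:
    """Fixed-scale candidate top-lefts on a coarse grid around ``box_prev``.

    Returns ``(top_lefts, w, h)``; raises when the whole window has left the
    frame.
    """
    if r_w < 1 or stride < 1:
        raise ValueError("r_w and stride must be at least 1")
    w, h = scaled_box_size(base_wh, s_prev, min_side)
    centres = _centre_grid((box_prev.cx, box_prev.cy), r_w, stride)
    tls = np.stack(
        [
            centres[:, 0] - round_half_up(w / 2),
            centres[:, 1] - round_half_up(h / 2),
        ],
        axis=1,
    ).astype(np.intp)
    tls = _filter_visible(tls, w, h, frame_shape)
    if len(tls) == 0:
        raise ValueError("level-1 search window lies entirely outside the frame")
    return tls, w, h


def level2_candidates(
    centre: Tuple[float, float],
    base_wh: Tuple[int, int],
    scales: Sequence[float],
    r_s: int,
    frame_shape: Tuple[int, int],
    min_side: int = 7,
) -> list[Tuple[float, np.ndarray, int, int]]:
    """Multi-scale dense candidates around the level-1 winner's centre.

    Returns a list of ``(scale, top_lefts, w, h)`` per fused scale; duplicate
    boxes (same centre and integer size from near-identical scales) are
    removed across scales, keeping the first occurrence.
    """
    if r_s < 1:
        raise ValueError("r_s must be at least 1")
    seen: set[Tuple[int, int, int, int]] = set()
    out = []
    for s in scales:
        w, h = scaled_box_size(base_wh, float(s), min_side)
        centres = _centre_grid(centre, r_s, 1)
        tls = np.stack(
            [
                centres[:, 0] - round_half_up(w / 2),
                centres[:, 1] - round_half_up(h / 2),
            ],
            axis=1,
        ).astype(np.intp)
        tls = _filter_visible(tls, w, h, frame_shape)
        keep = []
        for tx, ty in tls:
            key = (int(tx), int(ty), w, h)
            if key not in seen:
                seen.add(key)
                keep.append((tx, ty))
        if keep:
            out.append((float(s), np.asarray(keep, dtype=np.intp), w, h))
    if not out:
        raise ValueError("level-2 search window lies entirely outside the frame")
    return out
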