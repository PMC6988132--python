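"""Sparse pyramidal Lucas-Kanade point tracking.

Iterative Lucas-Kanade with a Gaussian image pyramid (Bouguet-style,
coarse-to-fine): for each point a fixed template window is sampled in the
previous frame at every pyramid level, and the flow that registers it in the
current frame is refined by Newton iterations on the 2x2 normal equations.
All points are processed in one vectorised batch; interpolation is bilinear
(``scipy.ndimage.map_coordinates``).

A point's status is good when its spatial-gradient matrix is well conditioned
(minimum eigenvalue per pixel above a threshold) and the tracked location
stays inside the frame.  Callers wanting a robust "well-tracked" criterion
additionally run the tracker backwards and threshold the forward-backward
error (see :func:`pawss.scaling.track_patch_points`).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import pyramid_reduce


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(img, dtype=np.float64)]
    for _ in range(1, levels):
        nxt = pyramid_reduce(pyr[-1], downscale=2, channel_axis=None)
        if min(nxt.shape) < 8:
            break
        pyr.append(nxt)
    return pyr


def track_points(
    img_prev: np.ndarray,
    img_cur: np.ndarray,
    points: np.ndarray,
    win: int = 21,
    levels: int = 3,
    n_iters: int = 10,
    eps: float = 0.01,
    min_eig: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Track ``points`` (``(N, 2)`` of x, y) from ``img_prev`` to ``img_cur``.

    Both images are single-channel float arrays of the same shape.  Returns
    ``(tracked_points, status)`` where ``status`` flags points with usable
    texture that stayed inside the frame.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.size == 0:
        return points.copy(), np.zeros(0, dtype=bool)
    if np.shape(img_prev) != np.shape(img_cur):
        raise ValueError("frames must have the same shape")

    pyr_prev = _pyramid(img_prev, levels)
    pyr_cur = _pyramid(img_cur, levels)
    n_levels = min(len(pyr_prev), len(pyr_cur))

    half = win // 2
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1]
    dx = dx.ravel()[None, :]
    dy = dy.ravel()[None, :]
    n_window = dx.size

    n = points.shape[0]
    flow = np.zeros((n, 2))  # (x, y) flow in current-level pixel units
    status = np.ones(n, dtype=bool)

    for level in range(n_levels - 1, -1, -1):
        prev_l = pyr_prev[level]
        cur_l = pyr_cur[level]
        gy_l, gx_l = np.gradient(prev_l)
        p_l = points / (2.0**level)

        tx = p_l[:, 0:1] + dx
        ty = p_l[:, 1:2] + dy
        coords = np.stack([ty.ravel(), tx.ravel()])
        template = ndimage.map_coordinates(prev_l, coords, order=1, mode="nearest")
        template = template.reshape(n, n_window)
        ix = ndimage.map_coordinates(gx_l, coords, order=1, mode="nearest").reshape(
            n, n_window
        )
        iy = ndimage.map_coordinates(gy_l, coords, order=1, mode="nearest").reshape(
            n, n_window
        )
        gxx = np.sum(ix * ix, axis=1)
        gxy = np.sum(ix * iy, axis=1)
        gyy = np.sum(iy * iy, axis=1)
        trace = gxx + gyy
        root = np.sqrt(np.maximum((gxx - gyy) ** 2 + 4 * gxy**2, 0.0))
        eig_min = (trace - root) / (2.0 * n_window)
        det = gxx * gyy - gxy * gxy
        ok = (eig_min > min_eig) & (det > 0)
        status &= ok

        for _ in range(n_iters):
            qx = tx + flow[:, 0:1]
            qy = ty + flow[:, 1:2]
            warped = ndimage.map_coordinates(
                cur_l, np.stack([qy.ravel(), qx.ravel()]), order=1, mode="nearest"
            ).reshape(n, n_window)
            diff = template - warped
            bx = np.sum(diff * ix, axis=1)
            by = np.sum(diff * iy, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                step_x = np.where(ok, (gyy * bx - gxy * by) / det, 0.0)
                step_y = np.where(ok, (gxx * by - gxy * bx) / det, 0.0)
            flow[:, 0] += step_x
            flow[:, 1] += step_y
            if np.max(np.abs(step_x)) < eps and np.max(np.abs(step_y)) < eps:
                break

        if level > 0:
            flow *= 2.0

    tracked = points + flow
    height, width = np.shape(img_prev)
    inside = (
        (tracked[:, 0] >= 0)
        & (tracked[:, 0] <= width - 1)
        & (tracked[:, 1] >= 0)
        & (tracked[:, 1] <= height - 1)
    )
    return tracked, status & inside
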