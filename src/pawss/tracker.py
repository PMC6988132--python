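"""Frame-by-frame tracking loop.

Each frame runs two phases:

**evaluation** — level-1 fixed-scale search over a wide window locates a
search centre; sparse points tracked by Lucas-Kanade from the previous box
estimate an abrupt scale change; level-2 multi-scale search over the fused
scale set within a small window commits the winning box and scale.

**learning** — unless the confidence gate fires, the colour model is updated
from the winning box (pixels weighted by the previous frame's patch weights),
the per-pixel foreground posterior is refreshed inside the box, patch weights
are re-derived from it, and the structured SVM absorbs a pattern of samples
around the winner.

Frames are pre-scaled so the minimum side of the initial box reaches 32 px;
all reported boxes are converted back to original coordinates at the
boundary.  Runs are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from .boxes import Box, decompose_grid, round_half_up
from .config import TrackerConfig
from .features import FrameFeatures, descriptor_length
from .scaling import (
    scaled_box_size,
    fuse_scale_sets,
    incremental_scale_set,
    klt_scale_set,
    level1_candidates,
    level2_candidates,
    pairwise_scale_ratio,
    track_patch_points,
)
from .segmentation import (
    init_colour_model,
    posterior_map,
    update_colour_model,
    update_patch_weights,
)
from .svm import StructuredSVM

logger = logging.getLogger(__name__)


class TrackingFailure(RuntimeError):
    """Raised when no candidate box remains inside the frame."""


def _prescale_frame(frame: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return np.asarray(frame)
    height, width = np.shape(frame)[:2]
    out_shape = (round_half_up(height * factor), round_half_up(width * factor))
    scaled = resize(
        np.asarray(frame, dtype=np.float64),
        out_shape + (3,),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def _argbest(scores: np.ndarray, tie_keys: np.ndarray) -> int:
    """Index of the maximum score; near-exact ties broken by smallest key."""
    top = scores.max()
    tied = np.flatnonzero(scores >= top - 1e-12)
    if len(tied) == 1:
        return int(tied[0])
    return int(tied[np.lexsort(tie_keys[:, tied])[0]])


class PawssTracker:
    """Online single-object tracker over an image sequence.

    Parameters
    ----------
    frame : first frame as an (H, W, 3) uint8 array
    init_box : first-frame bounding box in original image coordinates
    config : :class:`~pawss.config.TrackerConfig`
    """

    def __init__(
        self,
        frame: np.ndarray,
        init_box: Box,
        config: Optional[TrackerConfig] = None,
        debug_dir: Optional[str] = None,
    ):
        self.debug_dir = debug_dir
        self.config = config if config is not None else TrackerConfig()
        cfg = self.config
        height, width = np.shape(frame)[:2]
        if (
            init_box.x < 0
            or init_box.y < 0
            or init_box.x + init_box.w > width
            or init_box.y + init_box.h > height
        ):
            raise ValueError("initial box must lie inside the frame")

        min_side = min(init_box.w, init_box.h)
        self.pre_scale = 1.0 if min_side >= cfg.min_box_side else cfg.min_box_side / min_side
        self._frame_shape = np.shape(frame)[:2]

        frame_s = _prescale_frame(frame, self.pre_scale)
        self.scaled_shape = frame_s.shape[:2]
        f = self.pre_scale
        box_s = Box(init_box.x * f, init_box.y * f, init_box.w * f, init_box.h * f, scale=1.0)
        bx, by, bw, bh = box_s.int_rect()
        self.base_wh = (bw, bh)
        self.r_w = round_half_up((bw + bh) / 2.0)

        self.rng = np.random.default_rng(cfg.seed)
        self.weights = np.ones(cfg.n_patches)
        self.colour_model = init_colour_model(
            frame_s, box_s, cfg.margin_frac, cfg.ring_frac, cfg.delta
        )
        self.posterior = np.full(self.scaled_shape, 0.5)
        dim = descriptor_length(cfg.colour_space, cfg.use_gradient, cfg.n_patches)
        self.svm = StructuredSVM(
            n_features=dim,
            C=cfg.C,
            budget=cfg.budget,
            n_optimize=cfg.n_optimize,
            rng=self.rng,
        )
        self.box = Box(bx, by, bw, bh, scale=1.0)
        self.frame_prev = frame_s
        self.frames_gated = 0
        self.frame_index = 0

        feats = FrameFeatures(frame_s, cfg.colour_space, cfg.use_gradient)
        self._learn(feats, self.box)

    # ------------------------------------------------------------------
    @property
    def current_box(self) -> Box:
        """Current box in original image coordinates."""
        f = self.pre_scale
        return Box(
            self.box.x / f,
            self.box.y / f,
            self.box.w / f,
            self.box.h / f,
            scale=self.box.scale,
        )

    # ------------------------------------------------------------------
    def _learning_offsets(self) -> List[Tuple[int, int]]:
        cfg = self.config
        offsets = [(0, 0)]
        seen = {(0, 0)}
        for k in range(1, cfg.svm_radii + 1):
            r = self.r_w * k / cfg.svm_radii
            for a in range(cfg.svm_angles):
                theta = 2.0 * math.pi * a / cfg.svm_angles
                off = (round_half_up(r * math.cos(theta)), round_half_up(r * math.sin(theta)))
                if off not in seen:
                    seen.add(off)
                    offsets.append(off)
        return offsets

    #: scale factors for the learning pattern's shrunken negatives
    LEARN_SCALE_STEPS = (0.90, 0.95)

    def _learn(self, feats: FrameFeatures, box: Box) -> None:
        """Train the SVM on a neighbourhood of the winning box.

        The pattern holds the winner (anchor), a polar grid of translated
        boxes at the winner's scale, and two shrunken boxes at the winner's
        centre.  The search is over position *and* scale, so the structural
        constraints must cover scale too: without shrink-side negatives the
        learner is free to prefer smaller, background-free boxes and the
        scale estimate ratchets down under zoom.  Grow-side negatives are
        deliberately absent — an over-grown box already loses score through
        background contamination of its border patches, and penalising larger
        boxes would suppress catch-up whenever the tracker briefly lags a
        zoom.
        """
        cfg = self.config
        x, y, w, h = box.int_rect()
        offsets = self._learning_offsets()
        height, width = self.scaled_shape
        anchor_box = Box(x, y, w, h, scale=box.scale)
        X_parts, boxes = [], []
        tls = []
        for dx, dy in offsets:
            tx, ty = x + dx, y + dy
            if tx + w <= 0 or ty + h <= 0 or tx >= width or ty >= height:
                continue
            tls.append((tx, ty))
            boxes.append(Box(tx, ty, w, h, scale=box.scale))
        X_parts.append(
            feats.descriptors(
                np.asarray(tls, dtype=np.intp), w, h, self.weights, cfg.rows, cfg.cols
            )
        )
        min_side = max(cfg.rows, cfg.cols)
        for f in self.LEARN_SCALE_STEPS:
            s = box.scale * f
            sw, sh = scaled_box_size(self.base_wh, s, min_side)
            if (sw, sh) == (w, h):
                continue
            tx = round_half_up(anchor_box.cx - sw / 2.0)
            ty = round_half_up(anchor_box.cy - sh / 2.0)
            if tx + sw <= 0 or ty + sh <= 0 or tx >= width or ty >= height:
                continue
            boxes.append(Box(tx, ty, sw, sh, scale=s))
            X_parts.append(
                feats.descriptors(
                    np.array([[tx, ty]], dtype=np.intp),
                    sw,
                    sh,
                    self.weights,
                    cfg.rows,
                    cfg.cols,
                )
            )
        X = np.concatenate(X_parts, axis=0)
        loss = np.array([1.0 - anchor_box.iou(b) for b in boxes])
        loss[0] = 0.0
        self.svm.learn(X, anchor=0, loss=loss, n_reprocess=cfg.n_reprocess)

    # ------------------------------------------------------------------
    def track(self, frame: np.ndarray) -> Tuple[Box, float]:
        """Process the next frame; returns (box in original coordinates, score)."""
        if np.shape(frame)[:2] != self._frame_shape:
            raise ValueError("all frames must share the first frame's dimensions")
        cfg = self.config
        frame_s = _prescale_frame(frame, self.pre_scale)
        feats = FrameFeatures(frame_s, cfg.colour_space, cfg.use_gradient)
        self.frame_index += 1

        prev_box = self.box
        s_prev = prev_box.scale

        # ---- level 1: fixed-scale coarse search -----------------------
        tls1, w1, h1 = level1_candidates(
            prev_box,
            s_prev,
            self.base_wh,
            self.r_w,
            cfg.level1_stride,
            self.scaled_shape,
            min_side=max(cfg.rows, cfg.cols),
        )
        X1 = feats.descriptors(tls1, w1, h1, self.weights, cfg.rows, cfg.cols)
        scores1 = self.svm.score(X1)
        cx1 = tls1[:, 0] + w1 / 2.0
        cy1 = tls1[:, 1] + h1 / 2.0
        dist1 = np.hypot(cx1 - prev_box.cx, cy1 - prev_box.cy)
        i1 = _argbest(scores1, np.stack([dist1]))
        centre1 = (cx1[i1], cy1[i1])

        # ---- scale sets ----------------------------------------------
        s_r = incremental_scale_set(s_prev, cfg.lam, cfg.n_r)
        s_p_mult = None
        if cfg.use_klt_scales:
            grid_prev = decompose_grid(prev_box, cfg.rows, cfg.cols)
            sample = track_patch_points(
                self.frame_prev,
                frame_s,
                prev_box,
                grid_prev,
                cfg.n_pt,
                self.rng,
                win=cfg.lk_win,
                levels=cfg.lk_levels,
            )
            s_p = pairwise_scale_ratio(sample)
            s_p_mult = klt_scale_set(s_p, cfg.n_p)
        scales = fuse_scale_sets(s_r, s_p_mult, s_prev)
        # visit scales nearest the previous scale first: boxes whose integer
        # size coincides across scales then carry the most conservative label
        scales = scales[np.argsort(np.abs(np.log(scales / s_prev)), kind="stable")]

        # ---- level 2: multi-scale fine search -------------------------
        groups = level2_candidates(
            centre1,
            self.base_wh,
            scales,
            cfg.r_s,
            self.scaled_shape,
            min_side=max(cfg.rows, cfg.cols),
        )
        all_scores, all_dist, all_dscale, all_boxes = [], [], [], []
        for s, tls, w, h in groups:
            X = feats.descriptors(tls, w, h, self.weights, cfg.rows, cfg.cols)
            sc = self.svm.score(X)
            cx = tls[:, 0] + w / 2.0
            cy = tls[:, 1] + h / 2.0
            all_scores.append(sc)
            all_dist.append(np.hypot(cx - prev_box.cx, cy - prev_box.cy))
            all_dscale.append(np.full(len(tls), abs(math.log(s / s_prev))))
            all_boxes.extend(Box(tx, ty, w, h, scale=s) for tx, ty in tls)
        scores2 = np.concatenate(all_scores)
        tie = np.stack([np.concatenate(all_dscale), np.concatenate(all_dist)])
        i2 = _argbest(scores2, tie)
        best_box = all_boxes[i2]
        best_score = float(scores2[i2])

        # ---- confidence gate ------------------------------------------
        do_learn = True
        if cfg.eta_gate and self.svm.n_support > 0:
            win1_box = Box(
                tls1[i1, 0], tls1[i1, 1], w1, h1, scale=s_prev
            )
            far = np.array([win1_box.iou(Box(tx, ty, w1, h1)) < 0.5 for tx, ty in tls1])
            if far.any():
                span = scores1.max() - scores1.min()
                if span > 1e-12:
                    margin = (scores1[i1] - scores1[far].max()) / span
                    if margin < cfg.eta:
                        do_learn = False
                        self.frames_gated += 1
                        logger.info(
                            "frame %d: learning gated (margin %.3f < eta %.2f)",
                            self.frame_index,
                            margin,
                            cfg.eta,
                        )

        # ---- learning phase -------------------------------------------
        if do_learn:
            grid_t = decompose_grid(best_box, cfg.rows, cfg.cols)
            self.colour_model = update_colour_model(
                self.colour_model,
                frame_s,
                best_box,
                self.weights,
                grid_t,
                cfg.margin_frac,
                cfg.ring_frac,
            )
            x0, x1, y0, y1 = best_box.clipped(self.scaled_shape[1], self.scaled_shape[0])
            region_post = posterior_map(
                self.colour_model, frame_s, best_box, self.posterior
            )
            self.posterior[y0:y1, x0:x1] = region_post
            self.weights = update_patch_weights(
                self.weights, self.posterior, grid_t, cfg.delta
            )
            self._learn(feats, best_box)

        if self.debug_dir is not None:
            self._write_debug_maps()

        self.box = best_box
        self.frame_prev = frame_s
        return self.current_box, best_score

    def _write_debug_maps(self) -> None:
        """Dump the posterior map and a patch-weight thumbnail as PNGs."""
        import imageio.v3 as iio
        from pathlib import Path

        cfg = self.config
        out = Path(self.debug_dir)
        out.mkdir(parents=True, exist_ok=True)
        post = np.clip(np.rint(self.posterior * 255), 0, 255).astype(np.uint8)
        iio.imwrite(out / f"posterior_{self.frame_index:04d}.png", post)
        thumb = self.weights.reshape(cfg.rows, cfg.cols)
        thumb = np.clip(np.rint(thumb * 255), 0, 255).astype(np.uint8)
        thumb = np.kron(thumb, np.ones((16, 16), dtype=np.uint8))
        iio.imwrite(out / f"weights_{self.frame_index:04d}.png", thumb)


def track_sequence(
    frames: Sequence[np.ndarray],
    init_box: Box,
    config: Optional[TrackerConfig] = None,
    debug_dir: Optional[str] = None,
) -> Tuple[List[Box], List[float]]:
    """Track through a full sequence; frame 1's output is the initial box."""
    if len(frames) == 0:
        raise ValueError("empty sequence")
    tracker = PawssTracker(frames[0], init_box, config, debug_dir=debug_dir)
    boxes = [tracker.current_box]
    scores = [0.0]
    for frame in frames[1:]:
        box, score = tracker.track(frame)
        boxes.append(box)
        scores.append(score)
    return boxes, scores
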