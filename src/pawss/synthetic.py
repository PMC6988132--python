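"""Deterministic synthetic test sequences with exact ground truth.

Emulates the challenge factors of instrument tracking in endoscopic video at
toy scale: a textured rectangular target over a textured background, smooth
translation, incremental scale drift, abrupt scale jumps, partial occlusion
by a background-coloured occluder, and global illumination drift.

Targets and background carry seeded value-noise textures (smooth random
fields), because sparse point tracking needs image gradients; flat colours
are available as a degenerate mode to exercise the low-texture fallback.
The target texture is a fixed master field resampled to the current box
size, so a scale change in the spec appears as a true optical zoom of the
object.  Per-frame ground-truth boxes follow in closed form from the motion
path and scale profile, and identical seeds give byte-identical frames.

Colour separability between foreground and background is a knob: the
background palette can be pulled towards the foreground palette, and the
induced Bayes error of the two colour distributions is computable from the
master textures (see :func:`colour_bayes_error`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from .boxes import Box, round_half_up
from .segmentation import N_COLOUR_BINS, colour_bin_map

MASTER_TEXTURE_SIZE = 192


def value_noise(shape: Tuple[int, int], cells: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field in [0, 1]: coarse noise bilinearly upsampled."""
    coarse = rng.random((cells, cells))
    return resize(coarse, shape, order=1, anti_aliasing=False, mode="edge")


def _colourise(field: np.ndarray, c0: Sequence[float], c1: Sequence[float]) -> np.ndarray:
    c0 = np.asarray(c0, dtype=np.float64)
    c1 = np.asarray(c1, dtype=np.float64)
    return c0 + field[..., None] * (c1 - c0)


@dataclass(frozen=True)
class OccluderSpec:
    """Partial occlusion of the target by a background-coloured rectangle.

    Covers ``coverage`` of the target box width from the given side during
    frames ``[start, stop)``.
    """

    start: int
    stop: int
    coverage: float = 0.4
    side: str = "right"  # 'left' | 'right' | 'top' | 'bottom'


@dataclass
class SceneSpec:
    """Full specification of a synthetic sequence (ground truth in closed form)."""

    frame_size: Tuple[int, int] = (200, 150)  # (width, height)
    n_frames: int = 30
    target_size: Tuple[int, int] = (48, 48)  # (width, height) at scale 1
    centres: np.ndarray = None  # type: ignore[assignment]  # (n_frames, 2)
    scales: np.ndarray = None  # type: ignore[assignment]  # (n_frames,)
    fg_colours: Tuple[Sequence[float], Sequence[float]] = (
        (190.0, 40.0, 30.0),
        (255.0, 140.0, 60.0),
    )
    bg_colours: Tuple[Sequence[float], Sequence[float]] = (
        (25.0, 60.0, 170.0),
        (90.0, 130.0, 230.0),
    )
    separation: float = 1.0  # 1 = palettes as given, 0 = background == foreground
    target_inset: float = 0.06  # bg margin inside the GT box, fraction per side
    noise_cells: int = 10
    flat: bool = False  # degenerate texture-free mode
    occluder: Optional[OccluderSpec] = None
    illumination: np.ndarray = None  # type: ignore[assignment]  # per-frame gain
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_frames
        if n < 1:
            raise ValueError("n_frames must be at least 1")
        if self.centres is None:
            cx = self.frame_size[0] / 2.0
            cy = self.frame_size[1] / 2.0
            self.centres = np.tile([cx, cy], (n, 1)).astype(np.float64)
        self.centres = np.asarray(self.centres, dtype=np.float64)
        if self.scales is None:
            self.scales = np.ones(n)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        if self.illumination is None:
            self.illumination = np.ones(n)
        self.illumination = np.asarray(self.illumination, dtype=np.float64)
        if self.centres.shape != (n, 2) or self.scales.shape != (n,):
            raise ValueError("centres/scales must cover every frame")
        if self.illumination.shape != (n,):
            raise ValueError("illumination profile must cover every frame")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must be in [0, 1]")
        if not 0.0 <= self.target_inset < 0.5:
            raise ValueError("target_inset must be in [0, 0.5)")
        for t in range(n):
            box = self.ground_truth_box(t)
            w, h = self.frame_size
            if box.intersection_area(Box(0, 0, w, h)) < 0.5 * box.area:
                raise ValueError(
                    f"frame {t}: target leaves the frame by more than half"
                )

    # -- closed-form ground truth --------------------------------------
    def box_size(self, t: int) -> Tuple[int, int]:
        s = float(self.scales[t])
        return (
            max(1, round_half_up(self.target_size[0] * s)),
            max(1, round_half_up(self.target_size[1] * s)),
        )

    def ground_truth_box(self, t: int) -> Box:
        w, h = self.box_size(t)
        cx, cy = self.centres[t]
        return Box(round_half_up(cx - w / 2.0), round_half_up(cy - h / 2.0), w, h)

    def rendered_target_rect(self, t: int) -> Box:
        """The painted target rect: the GT box minus the background inset.

        Real annotation boxes bound the object with a little background
        visible inside them (that margin is what patch weighting exists to
        suppress), so the renderer keeps a proportional inset.
        """
        box = self.ground_truth_box(t)
        ix = round_half_up(box.w * self.target_inset)
        iy = round_half_up(box.h * self.target_inset)
        return Box(box.x + ix, box.y + iy, max(1, box.w - 2 * ix), max(1, box.h - 2 * iy))

    def ground_truth_boxes(self) -> List[Box]:
        return [self.ground_truth_box(t) for t in range(self.n_frames)]

    # -- palettes -------------------------------------------------------
    def effective_bg_colours(self) -> Tuple[np.ndarray, np.ndarray]:
        """Background palette pulled towards the foreground by 1 - separation."""
        out = []
        for bg_c, fg_c in zip(self.bg_colours, self.fg_colours):
            bg_c = np.asarray(bg_c, dtype=np.float64)
            fg_c = np.asarray(fg_c, dtype=np.float64)
            out.append(fg_c + self.separation * (bg_c - fg_c))
        return out[0], out[1]


def _master_fields(spec: SceneSpec) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    size = (spec.frame_size[1], spec.frame_size[0])
    if spec.flat:
        bg_field = np.full(size, 0.5)
        fg_field = np.full((MASTER_TEXTURE_SIZE, MASTER_TEXTURE_SIZE), 0.5)
    else:
        bg_field = value_noise(size, spec.noise_cells, rng)
        fg_field = value_noise(
            (MASTER_TEXTURE_SIZE, MASTER_TEXTURE_SIZE), spec.noise_cells, rng
        )
    return fg_field, bg_field


def generate_sequence(spec: SceneSpec) -> Tuple[List[np.ndarray], List[Box]]:
    """Render the sequence; returns (uint8 RGB frames, ground-truth boxes)."""
    fg_field, bg_field = _master_fields(spec)
    bg0, bg1 = spec.effective_bg_colours()
    background = _colourise(bg_field, bg0, bg1)
    width, height = spec.frame_size

    frames: List[np.ndarray] = []
    boxes: List[Box] = []
    for t in range(spec.n_frames):
        frame = background.copy()
        box = spec.ground_truth_box(t)
        target = spec.rendered_target_rect(t)
        w, h = int(target.w), int(target.h)
        patch_field = resize(
            fg_field, (h, w), order=1, anti_aliasing=False, mode="edge"
        )
        patch = _colourise(patch_field, spec.fg_colours[0], spec.fg_colours[1])
        x0, x1, y0, y1 = target.clipped(width, height)
        px0 = x0 - int(target.x)
        py0 = y0 - int(target.y)
        frame[y0:y1, x0:x1] = patch[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]

        occ = spec.occluder
        if occ is not None and occ.start <= t < occ.stop:
            ow = max(1, round_half_up(w * occ.coverage))
            oh = max(1, round_half_up(h * occ.coverage))
            if occ.side == "right":
                rect = Box(box.x + box.w - ow, box.y, ow, box.h)
            elif occ.side == "left":
                rect = Box(box.x, box.y, ow, box.h)
            elif occ.side == "top":
                rect = Box(box.x, box.y, box.w, oh)
            elif occ.side == "bottom":
                rect = Box(box.x, box.y + box.h - oh, box.w, oh)
            else:
                raise ValueError(f"unknown occluder side {occ.side!r}")
            rx0, rx1, ry0, ry1 = rect.clipped(width, height)
            frame[ry0:ry1, rx0:rx1] = background[ry0:ry1, rx0:rx1]

        frame = np.clip(np.rint(frame * spec.illumination[t]), 0, 255).astype(np.uint8)
        frames.append(frame)
        boxes.append(box)
    return frames, boxes


def colour_bayes_error(spec: SceneSpec) -> float:
    """Bayes error of the fg/bg colour distributions under equal priors.

    Computed from the exact master-texture colour histograms the renderer
    uses (512-bin joint RGB): ``0.5 * sum(min(p_fg, p_bg))``.
    """
    fg_field, bg_field = _master_fields(spec)
    bg0, bg1 = spec.effective_bg_colours()

    def hist(field: np.ndarray, c0, c1) -> np.ndarray:
        img = np.clip(np.rint(_colourise(field, c0, c1)), 0, 255).astype(np.uint8)
        bins = colour_bin_map(img)
        counts = np.bincount(bins.ravel(), minlength=N_COLOUR_BINS).astype(np.float64)
        return counts / counts.sum()

    p_fg = hist(fg_field, spec.fg_colours[0], spec.fg_colours[1])
    p_bg = hist(bg_field, bg0, bg1)
    return float(0.5 * np.minimum(p_fg, p_bg).sum())


# -- path and profile helpers ------------------------------------------


def random_walk_path(
    n_frames: int,
    start: Tuple[float, float],
    max_step: float,
    bounds: Tuple[float, float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer random walk with per-frame displacement at most ``max_step``.

    ``bounds`` is ``(x_min, x_max, y_min, y_max)`` for the centre; steps that
    would leave the bounds are reflected.
    """
    per_axis = max(1, int(max_step / np.sqrt(2.0)))
    x_min, x_max, y_min, y_max = bounds
    path = np.empty((n_frames, 2))
    pos = np.array(start, dtype=np.float64)
    path[0] = pos
    for t in range(1, n_frames):
        step = rng.integers(-per_axis, per_axis + 1, size=2).astype(np.float64)
        nxt = pos + step
        if not x_min <= nxt[0] <= x_max:
            nxt[0] = pos[0] - step[0]
        if not y_min <= nxt[1] <= y_max:
            nxt[1] = pos[1] - step[1]
        pos = np.clip(nxt, [x_min, y_min], [x_max, y_max])
        path[t] = pos
    return path


def drift_scales(n_frames: int, rate: float) -> np.ndarray:
    """Geometric scale drift ``rate^t`` (e.g. ``rate=1.01`` for 1 %/frame)."""
    return rate ** np.arange(n_frames, dtype=np.float64)


def jump_scales(n_frames: int, jump_frame: int, factor: float) -> np.ndarray:
    """Unit scale with one abrupt jump to ``factor`` at ``jump_frame``."""
    scales = np.ones(n_frames)
    scales[jump_frame:] = factor
    return scales


def make_tracking_scene(
    kind: str,
    n_frames: int = 60,
    seed: int = 0,
    separation: float = 1.0,
    **overrides,
) -> SceneSpec:
    """Preset study scenes.

    * ``'static'`` — no motion, no scale change;
    * ``'walk_zoom'`` — random-walk motion (<= 5 px/frame) with 1 %/frame zoom;
    * ``'scale_jump'`` — static centre with a single 1.3x scale jump mid-way;
    * ``'occlusion'`` — static target partially occluded by background colours.
    """
    frame_size = overrides.pop("frame_size", (200, 150))
    target_size = overrides.pop("target_size", (48, 48))
    rng = np.random.default_rng(seed + 1)
    centre = (frame_size[0] / 2.0, frame_size[1] / 2.0)

    if kind == "static":
        spec = SceneSpec(
            frame_size=frame_size,
            n_frames=n_frames,
            target_size=target_size,
            separation=separation,
            seed=seed,
            **overrides,
        )
    elif kind == "walk_zoom":
        scales = drift_scales(n_frames, overrides.pop("zoom_rate", 1.01))
        max_w = target_size[0] * scales[-1]
        max_h = target_size[1] * scales[-1]
        bounds = (
            max_w / 2 + 2,
            frame_size[0] - max_w / 2 - 2,
            max_h / 2 + 2,
            frame_size[1] - max_h / 2 - 2,
        )
        centres = random_walk_path(n_frames, centre, 5.0, bounds, rng)
        spec = SceneSpec(
            frame_size=frame_size,
            n_frames=n_frames,
            target_size=target_size,
            centres=centres,
            scales=scales,
            separation=separation,
            seed=seed,
            **overrides,
        )
    elif kind == "scale_jump":
        jump_frame = overrides.pop("jump_frame", n_frames // 2)
        factor = overrides.pop("jump_factor", 1.3)
        spec = SceneSpec(
            frame_size=frame_size,
            n_frames=n_frames,
            target_size=target_size,
            scales=jump_scales(n_frames, jump_frame, factor),
            separation=separation,
            seed=seed,
            **overrides,
        )
    elif kind == "occlusion":
        occ = overrides.pop(
            "occluder", OccluderSpec(start=n_frames // 3, stop=n_frames, coverage=0.4)
        )
        spec = SceneSpec(
            frame_size=frame_size,
            n_frames=n_frames,
            target_size=target_size,
            occluder=occ,
            separation=separation,
            seed=seed,
            **overrides,
        )
    else:
        raise ValueError(f"unknown scene kind {kind!r}")
    return spec
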