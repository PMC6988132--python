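"""Axis-aligned bounding boxes, patch grids and overlap geometry.

Conventions used throughout the package:

* pixel coordinates are 0-based;
* a box ``(x, y, w, h)`` covers the half-open extent
  ``[x, x + w) x [y, y + h)``;
* boxes may extend past the frame border — pixel reads are clamped at the
  boundary, but overlap/loss computations always use the nominal geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple


def round_half_up(value: float) -> int:
    """Round to nearest integer with ties going up (deterministic, no banker's)."""
    return int(math.floor(value + 0.5))


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel coordinates.

    ``scale`` carries the box's scale relative to the first-frame box of a
    tracking run (dimensionless, 1.0 for a free-standing box).
    """

    x: float
    y: float
    w: float
    h: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")
        if not self.scale > 0:
            raise ValueError(f"box scale must be positive, got {self.scale}")

    # -- geometry ---------------------------------------------------------
    @property
    def cx(self) -> float:
        return self.x + self.w / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def int_rect(self) -> Tuple[int, int, int, int]:
        """Integer ``(x, y, w, h)`` rect used for pixel access (sides >= 1)."""
        return (
            round_half_up(self.x),
            round_half_up(self.y),
            max(1, round_half_up(self.w)),
            max(1, round_half_up(self.h)),
        )

    def clipped(self, width: int, height: int) -> Tuple[int, int, int, int]:
        """Clip the integer rect to a ``width x height`` frame.

        Returns ``(x0, x1, y0, y1)`` half-open bounds; the rect is empty when
        ``x0 >= x1`` or ``y0 >= y1``.
        """
        x, y, w, h = self.int_rect()
        x0 = max(0, x)
        y0 = max(0, y)
        x1 = min(width, x + w)
        y1 = min(height, y + h)
        return x0, x1, y0, y1

    def with_centre(self, cx: float, cy: float) -> "Box":
        return replace(self, x=cx - self.w / 2.0, y=cy - self.h / 2.0)

    def centre_distance(self, other: "Box") -> float:
        return math.hypot(self.cx - other.cx, self.cy - other.cy)

    def intersection_area(self, other: "Box") -> float:
        iw = min(self.x + self.w, other.x + other.w) - max(self.x, other.x)
        ih = min(self.y + self.h, other.y + other.h) - max(self.y, other.y)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih

    def iou(self, other: "Box") -> float:
        inter = self.intersection_area(other)
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0


def overlap_loss(a: Box, b: Box) -> float:
    """Structural loss between two boxes: ``1 - IoU``, in [0, 1]."""
    return 1.0 - a.iou(b)


@dataclass(frozen=True)
class PatchGrid:
    """Row-major decomposition of an integer rect into ``rows x cols`` patches.

    The patches tile the rect exactly: no overlap, no gap, and the union of the
    patch rects equals the rect even when the sides are not divisible.
    """

    rows: int
    cols: int
    rects: Tuple[Tuple[int, int, int, int], ...]

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols


def grid_cuts(extent: int, n: int) -> list[int]:
    """Cut points ``round(k * extent / n)`` for ``k = 0..n`` (ties up)."""
    return [round_half_up(k * extent / n) for k in range(n + 1)]


def decompose_grid(box: Box, rows: int = 7, cols: int = 7) -> PatchGrid:
    """Evenly decompose ``box`` into a ``rows x cols`` grid of patches.

    Raises ``ValueError`` when the box is too small to give every patch at
    least one pixel.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one row and one column")
    x, y, w, h = box.int_rect()
    if w < cols or h < rows:
        raise ValueError(
            f"box of integer size {w}x{h} too small for a {rows}x{cols} grid"
        )
    xs = grid_cuts(w, cols)
    ys = grid_cuts(h, rows)
    rects = tuple(
        (x + xs[c], y + ys[r], xs[c + 1] - xs[c], ys[r + 1] - ys[r])
        for r in range(rows)
        for c in range(cols)
    )
    return PatchGrid(rows=rows, cols=cols, rects=rects)
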