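"""Tracker configuration.

Defaults follow the framework's reference parameterisation: a 7x7 patch grid
(49 patches), incremental scale base lambda = 1.003 with n_r = 11 scales,
n_p = 11 KLT-derived scales, 5 tracked points per patch, classifier update
threshold eta = 0.3, segmentation update factor delta = 0.1, fine search
radius r_s = 5 px, and HSV + gradient features.  The remaining knobs are
implementation choices documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

VALID_FEATURES = ("hsv", "rgb", "hsv+g", "rgb+g")


@dataclass
class TrackerConfig:
    rows: int = 7
    cols: int = 7
    feature: str = "hsv+g"

    lam: float = 1.003  # base of the incremental scale set (slightly > 1)
    n_r: int = 11  # incremental scales (odd: symmetric exponents)
    n_p: int = 11  # KLT-derived scales
    n_pt: int = 5  # tracked points per patch
    use_klt_scales: bool = True  # False = incremental-only ablation mode

    eta: float = 0.3  # learning-phase confidence gate
    eta_gate: bool = True
    delta: float = 0.1  # segmentation / weight update factor

    r_s: int = 5  # level-2 half-extent (px)
    level1_stride: int = 2  # level-1 grid stride (px)
    min_box_side: int = 32  # frames pre-scaled so min box side reaches this

    # segmentation regions (fractions of box dims per side)
    margin_frac: float = 0.4
    ring_frac: float = 0.5

    # structured SVM
    C: float = 100.0
    budget: int = 100
    n_reprocess: int = 10
    n_optimize: int = 10
    svm_radii: int = 5  # polar learning-sample radii (up to r_w)
    svm_angles: int = 16

    # Lucas-Kanade
    lk_win: int = 21
    lk_levels: int = 3

    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in VALID_FEATURES:
            raise ValueError(
                f"feature must be one of {VALID_FEATURES}, got {self.feature!r}"
            )
        if self.rows < 1 or self.cols < 1:
            raise ValueError("patch grid must be at least 1x1")
        if self.n_r < 1 or self.n_r % 2 == 0:
            raise ValueError("n_r must be positive and odd")
        if self.n_p < 2:
            raise ValueError("n_p must be at least 2")
        if self.lam <= 1.0:
            raise ValueError("lam must be greater than 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if self.r_s < 1 or self.level1_stride < 1:
            raise ValueError("search radii/strides must be at least 1")

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    @property
    def colour_space(self) -> str:
        return self.feature.split("+")[0]

    @property
    def use_gradient(self) -> bool:
        return self.feature.endswith("+g")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "TrackerConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
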