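"""One-pass-evaluation tracking metrics: precision and success curves.

Precision at threshold d is the fraction of valid frames whose predicted
centre lies within d pixels (Euclidean, inclusive) of the ground-truth
centre; the headline score uses d = 20 px.  The success curve gives, for each
overlap threshold u in [0, 1], the fraction of valid frames with IoU strictly
above u; its area under the curve (mean over a dense uniform grid) is the
success score, and equals mean per-frame IoU in the dense-grid limit.

Ground-truth rows marked invalid (absent / out-of-view) are excluded from all
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .boxes import Box

PRECISION_THRESHOLDS = np.arange(0, 51, dtype=np.float64)
SUCCESS_THRESHOLDS = np.linspace(0.0, 1.0, 1001)


class MetricError(ValueError):
    """Raised when a metric is undefined (no valid frames)."""


@dataclass
class TrackRun:
    """Paired predicted / ground-truth boxes with a frame-validity mask."""

    predicted: Sequence[Box]
    ground_truth: Sequence[Optional[Box]]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.predicted) != len(self.ground_truth):
            raise ValueError("prediction and ground-truth lengths differ")
        auto = np.array([g is not None for g in self.ground_truth])
        if self.valid is None:
            self.valid = auto
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & auto
        if len(self.valid) != len(self.predicted):
            raise ValueError("validity mask length mismatch")

    def _require_valid(self) -> np.ndarray:
        idx = np.flatnonzero(self.valid)
        if idx.size == 0:
            raise MetricError("no valid frames: metric undefined")
        return idx

    def centre_errors(self) -> np.ndarray:
        idx = self._require_valid()
        return np.array(
            [self.predicted[i].centre_distance(self.ground_truth[i]) for i in idx]
        )

    def ious(self) -> np.ndarray:
        idx = self._require_valid()
        return np.array([self.predicted[i].iou(self.ground_truth[i]) for i in idx])


def precision_curve(run: TrackRun, thresholds: np.ndarray = PRECISION_THRESHOLDS) -> np.ndarray:
    errors = run.centre_errors()
    return np.array([(errors <= t).mean() for t in thresholds])


def precision_score(run: TrackRun, threshold_px: float = 20.0) -> float:
    """Fraction of valid frames with centre error <= ``threshold_px``."""
    return float((run.centre_errors() <= threshold_px).mean())


def success_curve(run: TrackRun, thresholds: np.ndarray = SUCCESS_THRESHOLDS) -> np.ndarray:
    ious = run.ious()
    return np.array([(ious > u).mean() for u in thresholds])


def success_auc(run: TrackRun, thresholds: np.ndarray = SUCCESS_THRESHOLDS) -> float:
    """Mean of the success curve over a uniform overlap-threshold grid.

    The u = 1 endpoint uses strict inequality, so a perfect run scores
    ``1 - 1/len(thresholds)`` short of exactly 1 on the default grid.
    """
    return float(success_curve(run, thresholds).mean())
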