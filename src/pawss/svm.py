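"""Online structured-output SVM with a support-vector budget (LaRank-style).

The learner scores (frame, box) pairs directly through a linear kernel on
weighted patch descriptors.  Each frame contributes a *support pattern*: the
winning box (anchor) plus candidate boxes around it with structural loss
``1 - IoU`` to the anchor.  Dual coefficients beta live per (pattern,
candidate); feasibility requires, for every pattern i,

    sum_y beta_i(y) = 0,   0 <= beta_i(anchor) <= C,   beta_i(y != anchor) <= 0.

Learning is sequential minimal optimisation over coefficient pairs:

* PROCESS-NEW on the incoming pattern pairs the anchor with the most violating
  candidate (minimum gradient);
* PROCESS-OLD revisits a random retained pattern, pairing the most increasable
  existing support vector with the globally most violating candidate;
* OPTIMIZE rebalances coefficients among a pattern's existing support vectors.

With a linear kernel the primal weight vector ``w = sum beta * x`` is
maintained explicitly, so scoring is a single matrix-vector product and the
gradient of any candidate is ``-loss - <w, x>``.

When the number of support vectors exceeds the budget, the negative support
vector whose removal least perturbs ``w`` is dropped and its coefficient is
transferred to its pattern's anchor, preserving the sum-to-zero constraint.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np


class SupportPattern:
    """A retained frame: candidate descriptors, losses and dual coefficients."""

    __slots__ = ("X", "loss", "anchor", "beta")

    def __init__(self, X: np.ndarray, anchor: int, loss: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        loss = np.asarray(loss, dtype=np.float64)
        if X.ndim != 2 or len(loss) != len(X):
            raise ValueError("descriptor matrix and loss vector sizes disagree")
        if not 0 <= anchor < len(X):
            raise ValueError("anchor index out of range")
        if loss[anchor] != 0.0:
            raise ValueError("anchor must have zero structural loss")
        self.X = X
        self.loss = loss
        self.anchor = int(anchor)
        self.beta = np.zeros(len(X))

    def support_indices(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0.0)


class StructuredSVM:
    """Budgeted online structured SVM with a linear kernel."""

    def __init__(
        self,
        n_features: int,
        C: float = 100.0,
        budget: Optional[int] = 100,
        n_optimize: int = 10,
        rng: Optional[np.random.Generator] = None,
    ):
        if n_features < 1:
            raise ValueError("n_features must be positive")
        if C <= 0:
            raise ValueError("C must be positive")
        self.n_features = n_features
        self.C = float(C)
        self.budget = budget
        self.n_optimize = n_optimize
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.w = np.zeros(n_features)
        self.patterns: List[SupportPattern] = []

    # -- scoring ----------------------------------------------------------
    def score(self, X: np.ndarray) -> np.ndarray:
        """Linear-kernel scores for a matrix of candidate descriptors."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"descriptor dimension {X.shape[1]} does not match model "
                f"dimension {self.n_features}"
            )
        return X @ self.w

    @property
    def n_support(self) -> int:
        return int(sum(len(p.support_indices()) for p in self.patterns))

    # -- SMO machinery ----------------------------------------------------
    def _cap(self, pat: SupportPattern, idx: int) -> float:
        return self.C if idx == pat.anchor else 0.0

    def _gradients(self, pat: SupportPattern, idx=None) -> np.ndarray:
        if idx is None:
            return -pat.loss - pat.X @ self.w
        return -pat.loss[idx] - pat.X[idx] @ self.w

    def _smo_step(self, pat: SupportPattern, ip: int, im: int) -> bool:
        if ip == im:
            return False
        diff = pat.X[ip] - pat.X[im]
        k = float(diff @ diff)
        if k < 1e-12:
            return False
        g_ip = float(self._gradients(pat, ip))
        g_im = float(self._gradients(pat, im))
        lam = (g_ip - g_im) / k
        lam = min(lam, self._cap(pat, ip) - pat.beta[ip])
        if lam <= 1e-14:
            return False
        pat.beta[ip] += lam
        pat.beta[im] -= lam
        self.w += lam * diff
        return True

    def _process_new(self, pat: SupportPattern) -> None:
        grads = self._gradients(pat)
        self._smo_step(pat, pat.anchor, int(np.argmin(grads)))

    def _active_patterns(self) -> List[SupportPattern]:
        return [p for p in self.patterns if len(p.support_indices())]

    def _pick_pattern(self) -> Optional[SupportPattern]:
        active = self._active_patterns()
        if not active:
            return None
        return active[int(self.rng.integers(len(active)))]

    def _process_old(self) -> None:
        pat = self._pick_pattern()
        if pat is None:
            return
        grads = self._gradients(pat)
        candidates_up = set(pat.support_indices().tolist()) | {pat.anchor}
        feasible = [
            i for i in candidates_up if pat.beta[i] < self._cap(pat, i) - 1e-12
        ]
        if not feasible:
            return
        ip = max(feasible, key=lambda i: grads[i])
        im = int(np.argmin(grads))
        self._smo_step(pat, ip, im)

    def _optimize_step(self) -> None:
        pat = self._pick_pattern()
        if pat is None:
            return
        support = set(pat.support_indices().tolist()) | {pat.anchor}
        grads = self._gradients(pat)
        feasible = [i for i in support if pat.beta[i] < self._cap(pat, i) - 1e-12]
        if not feasible:
            return
        ip = max(feasible, key=lambda i: grads[i])
        im = min(support, key=lambda i: grads[i])
        self._smo_step(pat, ip, im)

    # -- budget -----------------------------------------------------------
    def budget_maintenance(self) -> None:
        """Remove negative support vectors until the budget is respected.

        The removed vector is the one whose coefficient transfer to its
        pattern's anchor least perturbs the weight vector.
        """
        if self.budget is None:
            return
        while self.n_support > self.budget:
            best: Optional[Tuple[SupportPattern, int, float]] = None
            for pat in self.patterns:
                anchor_x = pat.X[pat.anchor]
                for j in np.flatnonzero(pat.beta < 0.0):
                    diff = anchor_x - pat.X[j]
                    cost = pat.beta[j] ** 2 * float(diff @ diff)
                    if best is None or cost < best[2]:
                        best = (pat, int(j), cost)
            if best is None:
                break
            pat, j, _ = best
            b = pat.beta[j]
            self.w += b * (pat.X[pat.anchor] - pat.X[j])
            pat.beta[pat.anchor] += b
            pat.beta[j] = 0.0
        self.patterns = self._active_patterns()

    # -- public learning --------------------------------------------------
    def learn(
        self,
        X: np.ndarray,
        anchor: int,
        loss: Sequence[float],
        n_reprocess: int = 10,
    ) -> None:
        """Absorb one new support pattern and rebalance retained ones."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features:
            raise ValueError("descriptor dimension does not match the model")
        pat = SupportPattern(X, anchor, np.asarray(loss, dtype=np.float64))
        self.patterns.append(pat)
        self._process_new(pat)
        self.budget_maintenance()
        for _ in range(n_reprocess):
            self._process_old()
            self.budget_maintenance()
            for _ in range(self.n_optimize):
                self._optimize_step()
        self.patterns = self._active_patterns()

    # -- diagnostics ------------------------------------------------------
    def dual_objective(self) -> float:
        """Dual objective: ``-sum(loss * beta) - 0.5 ||w||^2``."""
        loss_term = sum(float(p.loss @ p.beta) for p in self.patterns)
        return -loss_term - 0.5 * float(self.w @ self.w)

    def check_invariants(self, tol: float = 1e-8) -> None:
        """Assert dual feasibility and the budget bound; raises on violation."""
        for pat in self.patterns:
            total = float(pat.beta.sum())
            if abs(total) > tol:
                raise AssertionError(f"pattern beta sum {total} != 0")
            if not (-tol <= pat.beta[pat.anchor] <= self.C + tol):
                raise AssertionError(
                    f"anchor beta {pat.beta[pat.anchor]} outside [0, C]"
                )
            others = np.delete(pat.beta, pat.anchor)
            if others.size and others.max() > tol:
                raise AssertionError("non-anchor beta above zero")
        if self.budget is not None and self.n_support > self.budget:
            raise AssertionError(
                f"support vector count {self.n_support} exceeds budget {self.budget}"
            )

    def snapshot(self) -> dict:
        """JSON-friendly dump of support vectors for debugging (not stable API)."""
        return {
            "n_features": self.n_features,
            "C": self.C,
            "budget": self.budget,
            "patterns": [
                {
                    "anchor": p.anchor,
                    "support": [
                        {"index": int(i), "beta": float(p.beta[i])}
                        for i in p.support_indices()
                    ],
                }
                for p in self.patterns
            ],
        }
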