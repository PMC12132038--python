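"""Multivariate adaptive regression splines, minimal implementation.

Forward pass: greedily add reflected hinge pairs max(0, x - t) / max(0, t - x)
(knots at marginal quantiles) that most reduce the residual sum of squares of
a least-squares fit to the 0/1 response. Backward pass: prune terms by
generalised cross-validation, GCV = (SSE/n) / (1 - C(M)/n)^2 with effective
parameter count C(M) = M + penalty * (M - 1) / 2.

Predictions are the linear model on the selected basis, clipped to [0, 1] so
they can be treated as occurrence probabilities downstream.
"""

from __future__ import annotations

import numpy as np


class HingeBasisMars:
    """MARS-style additive hinge-basis model for a binary response."""

    def __init__(self, max_terms: int = 15, n_knots: int = 9, penalty: float = 3.0):
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.penalty = penalty
        self.basis_: list[tuple[int, float, int]] = []  # (feature, knot, sign)
        self.coef_: np.ndarray | None = None

    # -- basis evaluation ---------------------------------------------------

    @staticmethod
    def _hinge(x: np.ndarray, knot: float, sign: int) -> np.ndarray:
        return np.maximum(0.0, sign * (x - knot))

    def _design(self, X: np.ndarray, basis) -> np.ndarray:
        cols = [np.ones(len(X))]
        cols += [self._hinge(X[:, f], t, s) for f, t, s in basis]
        return np.column_stack(cols)

    @staticmethod
    def _sse(B: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        beta, *_ = np.linalg.lstsq(B, y, rcond=None)
        r = y - B @ beta
        return float(r @ r), beta

    def _gcv(self, sse: float, n: int, m_terms: int) -> float:
        c = m_terms + self.penalty * (m_terms - 1) / 2.0
        denom = (1.0 - c / n) ** 2
        return np.inf if denom <= 0 else (sse / n) / denom

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        knots = {
            j: np.unique(np.quantile(X[:, j], np.linspace(0.1, 0.9, self.n_knots)))
            for j in range(p)
        }
        basis: list[tuple[int, float, int]] = []
        best_sse, _ = self._sse(self._design(X, basis), y)
        while len(basis) < self.max_terms:
            best_add, best_add_sse = None, best_sse
            for j in range(p):
                for t in knots[j]:
                    pair = [(j, float(t), 1), (j, float(t), -1)]
                    if any(b in basis for b in pair):
                        continue
                    sse, _ = self._sse(self._design(X, basis + pair), y)
                    if sse < best_add_sse - 1e-12:
                        best_add, best_add_sse = pair, sse
            if best_add is None:
                break
            basis += best_add
            best_sse = best_add_sse

        # backward pruning by GCV over single-term deletions
        best_basis = list(basis)
        sse, _ = self._sse(self._design(X, best_basis), y)
        best_gcv = self._gcv(sse, n, 1 + len(best_basis))
        current = list(basis)
        while current:
            trial_best = None
            for b in current:
                trial = [x for x in current if x != b]
                sse, _ = self._sse(self._design(X, trial), y)
                g = self._gcv(sse, n, 1 + len(trial))
                if trial_best is None or g < trial_best[0]:
                    trial_best = (g, trial)
            current = trial_best[1]
            if trial_best[0] < best_gcv:
                best_gcv, best_basis = trial_best[0], list(current)

        self.basis_ = best_basis
        _, self.coef_ = self._sse(self._design(X, best_basis), y)
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted occurrence probability, clipped to [0, 1]."""
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        return np.clip(self._design(X, self.basis_) @ self.coef_, 0.0, 1.0)
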