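"""Baseline estimation by adaptive iteratively reweighted penalized least
squares (airPLS).

The core primitive is the Whittaker smoother: for a signal y and
non-negative weights w it returns the vector z minimising

    sum_i w_i (y_i - z_i)^2  +  lam * || D^(d) z ||^2

where D^(d) is the d-th order finite-difference operator on the index grid.
airPLS iterates the smoother, adaptively concentrating the weights on the
points that lie *below* the current fit (negative residuals): peaks, which
stick up above the baseline, are progressively excluded, so the fit
converges onto the signal's lower envelope -- the baseline.  Iteration t
sets w_i = 0 where the residual d_i = y_i - z_i >= 0 and
w_i = exp(t |d_i| / sum|d^-|) where d_i < 0, with the two endpoint weights
pinned to the maximum weight to keep the edges anchored.  The loop stops
when the negative-residual mass falls below ``conv_ratio`` of the total
signal mass or after ``max_iter`` iterations (a cap, not a fixed count).

The defaults (lam = 1e5, 15 iterations, second-order differences) are the
settings this pipeline uses for DPV traces on the 261-point grid; lam is
dimensionless relative to the index spacing, so users working on denser
grids should rescale it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import DegenerateSystemError, DomainError
from .signal_core import VoltammogramSet

__all__ = ["AirPLSParams", "whittaker_smooth", "airpls_baseline", "correct_set"]


@dataclass(frozen=True)
class AirPLSParams:
    lam: float = 1e5
    max_iter: int = 15
    diff_order: int = 2
    conv_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.lam >= 0):
            raise DomainError("lam must be >= 0")
        if self.max_iter < 1:
            raise DomainError("max_iter must be >= 1")
        if self.diff_order not in (1, 2, 3):
            raise DomainError("diff_order must be 1, 2 or 3")
        if not (0 < self.conv_ratio < 1):
            raise DomainError("conv_ratio must be in (0, 1)")


def _difference_matrix(n: int, order: int) -> sparse.csc_matrix:
    d = sparse.eye(n, format="csc")
    for _ in range(order):
        d = d[1:] - d[:-1]
    return d


def whittaker_smooth(y: np.ndarray, w: np.ndarray, lam: float,
                     diff_order: int = 2) -> np.ndarray:
    """Exact solution of the weighted penalized least-squares smoothing
    problem (sparse banded solve).

    ``lam = 0`` is accepted and returns the data unchanged (the penalty
    vanishes, so z = y wherever w > 0).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.ndim != 1 or w.shape != y.shape:
        raise DomainError("y and w must be 1-D vectors of equal length")
    if np.any(w < 0):
        raise DomainError("weights must be non-negative")
    if not np.any(w > 0):
        raise DegenerateSystemError("all weights are zero")
    if lam == 0:
        return y.copy()
    n = y.size
    d = _difference_matrix(n, diff_order)
    a = sparse.diags(w) + lam * (d.T @ d)
    return np.asarray(spsolve(a.tocsc(), w * y))


def airpls_baseline(y: np.ndarray,
                    params: AirPLSParams = AirPLSParams(),
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Fit the baseline of one trace; returns ``(baseline, corrected)``
    with ``corrected = y - baseline`` exactly."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise DomainError("y must be a 1-D vector")
    if not np.all(np.isfinite(y)):
        raise DomainError("y contains non-finite values")
    total = np.abs(y).sum()
    w = np.ones_like(y)
    z = y.copy()
    for t in range(1, params.max_iter + 1):
        z = whittaker_smooth(y, w, params.lam, params.diff_order)
        d = y - z
        neg = d < 0
        s_neg = float(np.abs(d[neg]).sum())
        if s_neg < params.conv_ratio * total or t == params.max_iter:
            break
        w = np.zeros_like(y)
        w[neg] = np.exp(t * np.abs(d[neg]) / s_neg)
        w_max = w.max() if w.max() > 0 else 1.0
        w[0] = w[-1] = w_max        # pin the endpoints
    return z, y - z


def correct_set(vset: VoltammogramSet,
                params: AirPLSParams = AirPLSParams()) -> VoltammogramSet:
    """Row-wise baseline correction of a whole set (grid and IDs kept)."""
    corrected = np.empty_like(vset.matrix)
    for i in range(vset.n_samples):
        try:
            _, corrected[i] = airpls_baseline(vset.matrix[i], params)
        except (DomainError, DegenerateSystemError) as exc:
            raise type(exc)(
                f"sample {vset.sample_ids[i]!r} (row {i}): {exc}"
            ) from exc
    return vset.with_matrix(corrected)
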