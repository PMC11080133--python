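"""Partial least squares regression (PLS2) by NIPALS, with cross-validation
and latent-variable selection.

NIPALS is used rather than SIMPLS because the downstream diagnostics need
both the X-score matrix T and the Y-score matrix U.  Each latent variable
maximises the covariance between the (deflated) response and predictor
blocks; the regression coefficient matrix on the scaled spaces is
B = W (P'W)^-1 Q', and predictions apply the stored X scaling, multiply by
B and invert the stored Y scaling.

Model complexity is chosen from the cross-validated error curve: the
selected number of latent variables is the smallest A whose pooled RMSECV
is within a tolerance (default 2%) of the curve minimum -- the parsimony
rule "stop adding factors once the error is no longer significantly
improved".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .errors import ConfigurationError, DegenerateSystemError, DomainError
from .filter_scale import (ScalingState, apply_scaling, fit_scaling,
                           inverse_scaling)

__all__ = [
    "PLSModel",
    "CVResult",
    "pls_fit",
    "pls_predict",
    "cross_validate",
    "select_n_lv",
    "model_to_json",
    "model_from_json",
]


@dataclass
class PLSModel:
    n_lv: int
    W: np.ndarray            # X weights, n_points x n_lv, unit columns
    T: np.ndarray            # X scores, n_samples x n_lv, mutually orthogonal
    P: np.ndarray            # X loadings, n_points x n_lv
    U: np.ndarray            # Y scores, n_samples x n_lv
    Q: np.ndarray            # Y loadings, n_analytes x n_lv
    B: np.ndarray            # regression coefficients (scaled spaces)
    x_scaling: ScalingState
    y_scaling: ScalingState
    n_iterations: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return self.W.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.Q.shape[0]


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def _coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray,
                  a: int) -> np.ndarray:
    """B for the first ``a`` latent variables: W_a (P_a' W_a)^-1 Q_a'."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


def pls_fit(X: np.ndarray, Y: np.ndarray, n_lv: int,
            x_mode: str = "center", y_mode: str = "center",
            tol: float = 1e-10, max_iter: int = 500) -> PLSModel:
    """Fit a PLS2 model with ``n_lv`` latent variables by NIPALS.

    ``x_mode``/``y_mode`` select the column scaling applied before the
    decomposition (``center``, ``autoscale`` or ``pareto``).  The inner
    iteration of each component stops when the score vector changes by less
    than ``tol`` relative or after ``max_iter`` passes (non-convergence is
    recorded as a warning, the component is kept).
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    if X.ndim != 2:
        raise DomainError("X must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise DomainError(
            f"X has {X.shape[0]} rows, Y has {Y.shape[0]}"
        )
    n, p = X.shape
    m = Y.shape[1]
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ConfigurationError(
            f"n_lv must be in [1, min(n_samples - 1, n_points)] = "
            f"[1, {min(n - 1, p)}], got {n_lv}"
        )
    if np.any(Y.std(axis=0) == 0):
        raise DomainError("Y contains a zero-variance column")

    x_state = fit_scaling(X, x_mode)
    y_state = fit_scaling(Y, y_mode)
    Xc = apply_scaling(X, x_state)
    Yc = apply_scaling(Y, y_state)

    W = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    U = np.zeros((n, n_lv))
    Q = np.zeros((m, n_lv))
    n_iterations: list[int] = []
    converged: list[bool] = []
    x_norm0 = np.linalg.norm(Xc)

    a = 0
    while a < n_lv:
        if (np.linalg.norm(Xc) < 1e-12 * max(x_norm0, 1.0)
                or np.linalg.norm(Yc) < 1e-12):
            warnings.warn(
                f"X or Y block exhausted after {a} latent variables; "
                f"model truncated from {n_lv}", stacklevel=2)
            break
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
        t = np.zeros(n)
        it, ok = 0, False
        for it in range(1, max_iter + 1):
            w = Xc.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise DegenerateSystemError(
                    "zero weight vector; X carries no covariance with Y"
                )
            w /= nw
            t_new = Xc @ w
            q = Yc.T @ t_new / (t_new @ t_new)
            u = Yc @ q / (q @ q)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                ok = True
                break
            t = t_new
        if not ok:
            warnings.warn(
                f"NIPALS component {a + 1} did not converge in {max_iter} "
                "iterations; component accepted", stacklevel=2)
        tt = t @ t
        pvec = Xc.T @ t / tt
        q = Yc.T @ t / tt
        Xc = Xc - np.outer(t, pvec)
        Yc = Yc - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], U[:, a], Q[:, a] = w, t, pvec, u, q
        n_iterations.append(it)
        converged.append(ok)
        a += 1

    W, T, P, U, Q = W[:, :a], T[:, :a], P[:, :a], U[:, :a], Q[:, :a]
    B = _coefficients(W, P, Q, a)
    return PLSModel(a, W, T, P, U, Q, B, x_state, y_state,
                    n_iterations, converged)


def pls_predict(model: PLSModel, X_new: np.ndarray,
                n_lv: int | None = None) -> np.ndarray:
    """Predict responses for new predictor rows (original Y units).

    ``n_lv`` (<= the model's) predicts with a truncated component set.
    """
    X_new = np.asarray(X_new, dtype=float)
    one = X_new.ndim == 1
    if one:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_points:
        raise DomainError(
            f"X_new has {X_new.shape[1]} columns, model was trained on "
            f"{model.n_points}"
        )
    if n_lv is None or n_lv == model.n_lv:
        B = model.B
    else:
        if not (1 <= n_lv <= model.n_lv):
            raise ConfigurationError(f"n_lv must be in [1, {model.n_lv}]")
        B = _coefficients(model.W, model.P, model.Q, n_lv)
    Yh = apply_scaling(X_new, model.x_scaling) @ B
    Yh = inverse_scaling(Yh, model.y_scaling)
    return Yh[0] if one else Yh


@dataclass
class CVResult:
    """Cross-validated error curves.

    ``rmsecv``/``press`` are (max_lv x n_analytes) on the original Y scale;
    ``predictions`` holds the out-of-fold predictions per candidate LV count
    (max_lv x n_samples x n_analytes).
    """

    rmsecv: np.ndarray
    press: np.ndarray
    predictions: np.ndarray
    scheme: str
    n: int
    chosen_n_lv: int | None = None

    @property
    def max_lv(self) -> int:
        return self.rmsecv.shape[0]


def _folds(n: int, scheme: Union[str, tuple[str, int]],
           seed: int) -> tuple[list[np.ndarray], str]:
    if scheme == "loo":
        return [np.array([i]) for i in range(n)], "leave-one-out"
    if isinstance(scheme, tuple) and scheme[0] == "kfold":
        k = int(scheme[1])
        if not (2 <= k <= n):
            raise ConfigurationError(f"kfold k must be in [2, {n}]")
        offset = int(np.random.default_rng(seed).integers(k))
        idx = np.arange(n)
        folds = [idx[(idx + offset) % k == f] for f in range(k)]
        return [f for f in folds if f.size], f"venetian-blinds {k}-fold (seed {seed})"
    raise ConfigurationError(f"unknown CV scheme {scheme!r}")


def cross_validate(X: np.ndarray, Y: np.ndarray, max_lv: int,
                   scheme: Union[str, tuple[str, int]] = "loo", seed: int = 0,
                   x_mode: str = "center", y_mode: str = "center") -> CVResult:
    """RMSECV per analyte for 1..max_lv latent variables.

    Scaling and model are refit on the retained samples of every fold; the
    held-out rows are predicted with each candidate component count.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, m = Y.shape[0], Y.shape[1]
    folds, descr = _folds(n, scheme, seed)
    min_train = min(n - f.size for f in folds)
    if max_lv > min(min_train - 1, X.shape[1]):
        raise ConfigurationError(
            f"max_lv = {max_lv} exceeds the capacity of the smallest "
            f"training fold ({min_train} rows)"
        )
    predictions = np.zeros((max_lv, n, m))
    for fold in folds:
        keep = np.setdiff1d(np.arange(n), fold)
        model = pls_fit(X[keep], Y[keep], max_lv, x_mode, y_mode)
        for a in range(1, model.n_lv + 1):
            predictions[a - 1, fold] = pls_predict(model, X[fold], a)
        for a in range(model.n_lv + 1, max_lv + 1):   # rank-truncated fold
            predictions[a - 1, fold] = predictions[model.n_lv - 1, fold]
    press = ((predictions - Y[None]) ** 2).sum(axis=1)
    rmsecv = np.sqrt(press / n)
    return CVResult(rmsecv, press, predictions, descr, n)


def select_n_lv(cv: CVResult, tol: float = 0.02) -> int:
    """Smallest component count whose pooled RMSECV is within ``tol``
    (relative) of the curve minimum.

    Pooling is the root mean square across analytes of the analyte-wise
    RMSECV.
    """
    if cv.max_lv < 1:
        raise DomainError("empty cross-validation curve")
    pooled = np.sqrt((cv.rmsecv ** 2).mean(axis=1))
    threshold = (1.0 + tol) * pooled.min()
    chosen = int(np.nonzero(pooled <= threshold)[0][0]) + 1
    cv.chosen_n_lv = chosen
    return chosen


# --- JSON serialisation -----------------------------------------------------

def _state_to_dict(s: ScalingState) -> dict:
    return {"mode": s.mode, "mean": s.mean.tolist(),
            "scale": s.scale.tolist(),
            "constant_mask": s.constant_mask.astype(bool).tolist()}


def _state_from_dict(d: dict) -> ScalingState:
    return ScalingState(d["mode"], np.asarray(d["mean"], dtype=float),
                        np.asarray(d["scale"], dtype=float),
                        np.asarray(d["constant_mask"], dtype=bool))


def model_to_json(model: PLSModel, path: str | Path | None = None) -> str:
    doc = {
        "n_lv": model.n_lv,
        "W": model.W.tolist(), "T": model.T.tolist(), "P": model.P.tolist(),
        "U": model.U.tolist(), "Q": model.Q.tolist(), "B": model.B.tolist(),
        "x_scaling": _state_to_dict(model.x_scaling),
        "y_scaling": _state_to_dict(model.y_scaling),
        "n_iterations": model.n_iterations,
        "converged": model.converged,
    }
    text = json.dumps(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def model_from_json(source: str | Path) -> PLSModel:
    try:
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
    except (OSError, ValueError):
        text = str(source)
    d = json.loads(text)
    arr = {k: np.asarray(d[k], dtype=float) for k in "WTPUQB"}
    return PLSModel(int(d["n_lv"]), arr["W"], arr["T"], arr["P"], arr["U"],
                    arr["Q"], arr["B"],
                    _state_from_dict(d["x_scaling"]),
                    _state_from_dict(d["y_scaling"]),
                    list(d["n_iterations"]),
                    [bool(c) for c in d["converged"]])
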