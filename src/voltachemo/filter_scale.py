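"""Savitzky-Golay filtering and column scaling ahead of PLS.

The SG filter fits a low-degree polynomial to a sliding window of the trace
by least squares and evaluates it (or its derivative) at the window centre,
which reduces to a fixed convolution in the interior.  Edge points are
handled by refitting the polynomial on the truncated asymmetric window, so
the output keeps the input length.  Derivatives are returned per volt (the
unit-spacing coefficients are rescaled by (1/step)^deriv).

Scaling modes follow chemometric convention: ``center`` subtracts the
column mean, ``autoscale`` additionally divides by the column standard
deviation (n-1 denominator), ``pareto`` divides by its square root --
damping, without equalising, the variance of high-intensity potentials.
The fitted :class:`ScalingState` supports the exact inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "SGParams",
    "ScalingState",
    "sg_coefficients",
    "apply_sg",
    "fit_scaling",
    "apply_scaling",
    "inverse_scaling",
]

_SCALING_MODES = ("center", "autoscale", "pareto")


@dataclass(frozen=True)
class SGParams:
    window: int = 15
    polyorder: int = 2
    deriv: int = 1

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError("window must be an odd count >= 3")
        if not (0 <= self.polyorder < self.window):
            raise ConfigurationError("polyorder must satisfy 0 <= polyorder < window")
        if not (0 <= self.deriv <= self.polyorder):
            raise ConfigurationError("deriv must satisfy 0 <= deriv <= polyorder")


def sg_coefficients(window: int, polyorder: int, deriv: int = 0) -> np.ndarray:
    """Least-squares convolution coefficients for the requested derivative
    at the window centre (unit grid spacing).

    The coefficient vector c satisfies: the deriv-th derivative of the
    polynomial least-squares fit through (x_j, y_j), x_j = j - window//2,
    evaluated at 0, equals c . y.
    """
    SGParams(window, polyorder, deriv)  # validate
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    design = np.vander(x, polyorder + 1, increasing=True)
    return factorial(deriv) * np.linalg.pinv(design)[deriv]


def _edge_value(seg: np.ndarray, centre: int, polyorder: int, deriv: int) -> float:
    """Polynomial LS fit on a truncated window, derivative at ``centre``."""
    x = np.arange(seg.size, dtype=float) - centre
    order = min(polyorder, seg.size - 1)
    coef = np.polynomial.polynomial.polyfit(x, seg, order)
    if deriv > order:
        return 0.0
    return float(factorial(deriv) * coef[deriv])


def apply_sg(matrix: np.ndarray, params: SGParams = SGParams(),
             step: float = 1.0) -> np.ndarray:
    """Row-wise SG filtering of a samples x points matrix (1-D input is
    treated as a single trace).

    ``step`` is the grid spacing in volts; a first derivative is then in
    current units per volt.
    """
    m = np.asarray(matrix, dtype=float)
    squeeze = m.ndim == 1
    if squeeze:
        m = m[None, :]
    if m.ndim != 2:
        raise DomainError("matrix must be 1-D or 2-D")
    n_points = m.shape[1]
    if n_points < params.window:
        raise DomainError(
            f"trace length {n_points} is shorter than the window {params.window}"
        )
    half = params.window // 2
    c = sg_coefficients(params.window, params.polyorder, params.deriv)
    out = np.empty_like(m)
    kernel = c[::-1]
    for i in range(m.shape[0]):
        out[i, half:n_points - half] = np.convolve(m[i], kernel, mode="valid")
        for j in range(half):
            out[i, j] = _edge_value(m[i, :j + half + 1], j,
                                    params.polyorder, params.deriv)
            k = n_points - 1 - j
            seg = m[i, k - half:]
            out[i, k] = _edge_value(seg, seg.size - 1 - j,
                                    params.polyorder, params.deriv)
    out *= (1.0 / step) ** params.deriv
    return out[0] if squeeze else out


@dataclass
class ScalingState:
    """Column-wise scaling fitted on a training matrix.

    ``scale`` is all ones for ``center``, the column SD for ``autoscale``
    and sqrt(SD) for ``pareto``; constant columns keep scale 1 and are
    flagged in ``constant_mask`` (they scale to exactly zero since they are
    centred first).
    """

    mode: str
    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray


def fit_scaling(matrix: np.ndarray, mode: str = "pareto") -> ScalingState:
    if mode not in _SCALING_MODES:
        raise ConfigurationError(
            f"mode must be one of {_SCALING_MODES}, got {mode!r}"
        )
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise DomainError("matrix must be 2-D")
    if m.shape[0] < 2 and mode != "center":
        raise DomainError(f"{mode} scaling needs at least 2 samples")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1) if m.shape[0] > 1 else np.zeros(m.shape[1])
    constant = sd == 0
    if mode == "center":
        scale = np.ones_like(mean)
    elif mode == "autoscale":
        scale = np.where(constant, 1.0, sd)
    else:  # pareto
        scale = np.where(constant, 1.0, np.sqrt(sd))
    return ScalingState(mode, mean, scale, constant)


def apply_scaling(matrix: np.ndarray, state: ScalingState) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape[-1] != state.mean.size:
        raise DomainError(
            f"matrix has {m.shape[-1]} columns, scaling state has {state.mean.size}"
        )
    return (m - state.mean) / state.scale


def inverse_scaling(matrix: np.ndarray, state: ScalingState) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape[-1] != state.mean.size:
        raise DomainError(
            f"matrix has {m.shape[-1]} columns, scaling state has {state.mean.size}"
        )
    return m * state.scale + state.mean
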