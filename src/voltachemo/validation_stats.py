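"""Model-quality statistics and outlier diagnostics for PLS calibration.

Covers the full validation suite of a multivariate calibration study:

* RMSE / REP% error summaries -- RMSE = sqrt(sum (y_pred - y_act)^2 / n)
  and its percentage relative to the mean nominal concentration of the
  same sample set;
* CV-ANOVA -- an F-test on cross-validated predictive residuals of the
  unit-variance response;
* the response-permutation test with R2/Q2 regression-line intercepts;
* leverage in the X- and Y-score spaces (diagonals of the projection
  matrices T(T'T)^-1 T' and U(U'U)^-1 U');
* Hotelling's T2 with its F-based critical threshold;
* standardized residuals with +-2 outlier flagging and normal-probability
  plotting coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateSystemError, DomainError
from .pls_core import PLSModel, cross_validate, pls_fit, pls_predict

__all__ = [
    "ErrorStats",
    "CvAnovaRow",
    "PermutationResult",
    "error_stats",
    "cv_anova",
    "permutation_test",
    "leverages",
    "hotelling_t2",
    "standardized_residuals",
    "normal_probability_coords",
    "r_squared",
    "q_squared",
]


@dataclass(frozen=True)
class ErrorStats:
    rmse: float          # mol/L
    rep_percent: float   # 100 * rmse / y_mean (NaN when y_mean == 0)
    r2: float            # of the predicted-vs-nominal OLS line
    n: int
    y_mean: float        # mol/L


def error_stats(y_pred: np.ndarray, y_act: np.ndarray) -> ErrorStats:
    """RMSE, relative error of prediction (%), and pred-vs-nominal r2."""
    yp = np.asarray(y_pred, dtype=float)
    ya = np.asarray(y_act, dtype=float)
    if yp.shape != ya.shape or yp.ndim != 1 or yp.size < 1:
        raise DomainError("y_pred and y_act must be equal-length 1-D vectors")
    n = yp.size
    rmse = float(np.sqrt(((yp - ya) ** 2).sum() / n))
    y_mean = float(ya.mean())
    rep = 100.0 * rmse / y_mean if y_mean != 0 else math.nan
    if n >= 2 and np.ptp(ya) > 0:
        if np.ptp(yp) == 0:
            r2 = 0.0
        else:
            r2 = float(stats.pearsonr(ya, yp).statistic ** 2)
    else:
        r2 = math.nan
    return ErrorStats(rmse, rep, r2, n, y_mean)


@dataclass(frozen=True)
class CvAnovaRow:
    """One response's CV-ANOVA decomposition.

    Invariants hold by construction: SS_total = SS_regression + SS_residual,
    DF likewise, MS = SS/DF, F = MS_regression / MS_residual.  The SD
    columns are sqrt(MS).
    """

    ss_total: float
    df_total: int
    ss_regression: float
    df_regression: int
    ss_residual: float
    df_residual: int

    @property
    def ms_total(self) -> float:
        return self.ss_total / self.df_total

    @property
    def ms_regression(self) -> float:
        return self.ss_regression / self.df_regression

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.df_residual

    @property
    def f(self) -> float:
        if self.ms_residual == 0:
            return math.inf
        return self.ms_regression / self.ms_residual

    @property
    def p(self) -> float:
        if math.isinf(self.f):
            return 0.0
        return float(stats.f.sf(self.f, self.df_regression, self.df_residual))

    @property
    def sd_total(self) -> float:
        return math.sqrt(self.ms_total)

    @property
    def sd_regression(self) -> float:
        return math.sqrt(max(self.ms_regression, 0.0))

    @property
    def sd_residual(self) -> float:
        return math.sqrt(self.ms_residual)

    @classmethod
    def from_sums(cls, ss_total: float, ss_residual: float,
                  df_total: int, df_regression: int) -> "CvAnovaRow":
        if df_total <= 0 or not (0 < df_regression < df_total):
            raise DomainError("require 0 < df_regression < df_total")
        return cls(ss_total, df_total, ss_total - ss_residual, df_regression,
                   ss_residual, df_total - df_regression)

    def as_dict(self) -> dict:
        return {
            "ss_total": self.ss_total, "df_total": self.df_total,
            "ss_regression": self.ss_regression,
            "df_regression": self.df_regression,
            "ss_residual": self.ss_residual, "df_residual": self.df_residual,
            "ms_regression": self.ms_regression,
            "ms_residual": self.ms_residual,
            "F": self.f, "p": self.p,
            "sd_regression": self.sd_regression,
            "sd_residual": self.sd_residual,
        }


def cv_anova(y_scaled: np.ndarray, cv_residuals: np.ndarray,
             df_regression: int | None = None) -> CvAnovaRow:
    """CV-ANOVA of one unit-variance response.

    ``y_scaled`` should be scaled so its centred sum of squares is n - 1;
    ``cv_residuals`` are the cross-validated predictive residuals on the
    same scale.  The degrees-of-freedom convention is configurable because
    no universal rule exists; the default assigns 5/6 of DF_total to the
    regression (the split the reference chemometric software prints for
    this design size: 24 total -> 20 regression / 4 residual).
    """
    y = np.asarray(y_scaled, dtype=float)
    r = np.asarray(cv_residuals, dtype=float)
    if y.ndim != 1 or r.shape != y.shape:
        raise DomainError("y_scaled and cv_residuals must be equal-length vectors")
    n = y.size
    if n < 3:
        raise DomainError("need at least 3 samples")
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_residual = float((r ** 2).sum())
    df_total = n - 1
    if df_regression is None:
        df_regression = round(df_total * 5 / 6)
    return CvAnovaRow.from_sums(ss_total, ss_residual, df_total, df_regression)


def r_squared(model: PLSModel, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of response variance explained on the given samples."""
    y = np.asarray(y, dtype=float)
    resid = pls_predict(model, X)[:, 0] - y
    ss_tot = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid ** 2).sum() / ss_tot)


def q_squared(X: np.ndarray, y: np.ndarray, n_lv: int,
              scheme="loo", seed: int = 0, x_mode: str = "center") -> float:
    """Cross-validated explained variance, 1 - PRESS/SS_total."""
    y = np.asarray(y, dtype=float)
    cv = cross_validate(X, y, n_lv, scheme, seed, x_mode)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return float(1.0 - cv.press[n_lv - 1, 0] / ss_tot)


@dataclass
class PermutationResult:
    """Response-permutation validation of a single-response PLS model.

    Each permutation refits the model against a shuffled response; R2 and
    Q2 are regressed on the absolute correlation of the permuted with the
    original response (the original model enters at correlation 1), and the
    regression-line intercepts at zero correlation summarise the null
    level.  A clearly negative Q2 intercept supports model validity.
    """

    n_perm: int
    correlations: np.ndarray   # includes the original point (1.0) first
    r2_values: np.ndarray
    q2_values: np.ndarray
    r2_intercept: float
    q2_intercept: float
    r2_original: float
    q2_original: float
    seed: int = 0


def permutation_test(X: np.ndarray, y: np.ndarray, n_lv: int,
                     n_perm: int = 40, seed: int = 0,
                     scheme="loo", x_mode: str = "center") -> PermutationResult:
    if n_perm < 10:
        raise DomainError("n_perm must be >= 10")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise DomainError("permutation test expects a single response vector")
    rng = np.random.default_rng(seed)

    def _fit_scores(y_b: np.ndarray) -> tuple[float, float]:
        model = pls_fit(X, y_b, n_lv, x_mode=x_mode)
        return (r_squared(model, X, y_b),
                q_squared(X, y_b, model.n_lv, scheme, seed, x_mode))

    r2_0, q2_0 = _fit_scores(y)
    corrs = [1.0]
    r2s = [r2_0]
    q2s = [q2_0]
    for _ in range(n_perm):
        yp = rng.permutation(y)
        corrs.append(abs(float(np.corrcoef(yp, y)[0, 1])))
        r2, q2 = _fit_scores(yp)
        r2s.append(r2)
        q2s.append(q2)
    corrs_a = np.asarray(corrs)
    r2_a, q2_a = np.asarray(r2s), np.asarray(q2s)
    r2_line = np.polynomial.polynomial.polyfit(corrs_a, r2_a, 1)
    q2_line = np.polynomial.polynomial.polyfit(corrs_a, q2_a, 1)
    return PermutationResult(n_perm, corrs_a, r2_a, q2_a,
                             float(r2_line[0]), float(q2_line[0]),
                             r2_0, q2_0, seed)


def _projection_diagonal(scores: np.ndarray) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    gram = s.T @ s
    try:
        m = np.linalg.solve(gram, s.T).T
    except np.linalg.LinAlgError as exc:
        raise DegenerateSystemError(f"singular score covariance: {exc}") from exc
    return (m * s).sum(axis=1)


def leverages(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample leverage in the X and Y score spaces (diagonals of
    T(T'T)^-1 T' and U(U'U)^-1 U')."""
    if model.n_lv < 1:
        raise DomainError("model has no latent variables")
    return _projection_diagonal(model.T), _projection_diagonal(model.U)


def hotelling_t2(model: PLSModel,
                 alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Hotelling T2 per sample and the F-based critical value at ``alpha``.

    T2_i = sum_a t_ia^2 / s_a^2 with s_a^2 the (n-1)-denominator variance of
    score column a; the critical value is
    A(N-1)(N+1) / (N(N-A)) * F_{1-alpha}(A, N-A).
    """
    T = model.T
    n, a = T.shape
    if n <= a:
        raise DomainError(f"need more samples ({n}) than components ({a})")
    s2 = T.var(axis=0, ddof=1)
    if np.any(s2 == 0):
        raise DegenerateSystemError("zero-variance score column")
    t2 = ((T - T.mean(axis=0)) ** 2 / s2).sum(axis=1)
    crit = (a * (n - 1) * (n + 1)) / (n * (n - a)) \
        * float(stats.f.ppf(1.0 - alpha, a, n - a))
    return t2, crit


def standardized_residuals(y_pred: np.ndarray, y_act: np.ndarray,
                           flag_at: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Raw residuals divided by the residual standard deviation (RSD), with
    outlier flags where |z| exceeds ``flag_at``.

    The residual is not re-centred and the RSD is the root mean square of
    the residuals, so an all-zero residual vector yields all-zero z and no
    flags.
    """
    yp = np.asarray(y_pred, dtype=float)
    ya = np.asarray(y_act, dtype=float)
    if yp.shape != ya.shape or yp.ndim != 1 or yp.size < 3:
        raise DomainError("need equal-length vectors of at least 3 residuals")
    resid = yp - ya
    rsd = float(np.sqrt((resid ** 2).mean()))
    if rsd == 0:
        z = np.zeros_like(resid)
    else:
        z = resid / rsd
    return z, np.abs(z) > flag_at


def normal_probability_coords(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(theoretical normal quantiles, sorted z) for a normal-probability
    plot, using Blom plotting positions (i - 3/8) / (n + 1/4)."""
    z = np.asarray(z, dtype=float)
    n = z.size
    ranks = np.arange(1, n + 1)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25)), np.sort(z)
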