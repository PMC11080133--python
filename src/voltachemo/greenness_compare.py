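"""Analytical Eco-Scale greenness scoring and two-method comparison tests.

The Eco-Scale starts from a base of 100 and subtracts penalty points for
reagent quantities/hazards, instrument energy demand, occupational hazards
and waste; 100 is the ideal green analysis, above 75 a "great green"
analysis, 50-75 acceptable, below 50 inadequate.  Penalty values are user
inputs: the bundled worksheets carry the items of the voltammetric method
this package models and of its reference HPLC comparator.

Method comparison uses the classical pooled-variance two-sample t test on
mean recoveries and the variance-ratio F test (larger over smaller
variance), judged against user-supplied tabulated critical values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "EcoItem",
    "EcoScaleSheet",
    "MethodSummary",
    "TTestResult",
    "FTestResult",
    "eco_scale",
    "pooled_t_test",
    "variance_ratio_test",
    "PROPOSED_DPV_ITEMS",
    "REFERENCE_HPLC_ITEMS",
]

_CATEGORIES = ("reagent", "energy", "occupational hazard", "waste")


@dataclass(frozen=True)
class EcoItem:
    label: str
    category: str
    penalty: float

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise DomainError(
                f"category must be one of {_CATEGORIES}, got {self.category!r}"
            )
        if self.penalty < 0:
            raise DomainError("penalty points must be >= 0")


#: Eco-Scale worksheet of the direct DPV method (Britton-Robinson buffer,
#: methanol co-solvent for the entacapone stock, mini-potentiostat).
PROPOSED_DPV_ITEMS: tuple[EcoItem, ...] = (
    EcoItem("Britton-Robinson buffer", "reagent", 1),
    EcoItem("Methanol", "reagent", 6),
    EcoItem("Water", "reagent", 0),
    EcoItem("Energy (<= 0.1 kWh per sample)", "energy", 0),
    EcoItem("Occupational hazard", "occupational hazard", 0),
    EcoItem("Waste", "waste", 3),
)

#: Eco-Scale worksheet of the reference HPLC comparator method.
REFERENCE_HPLC_ITEMS: tuple[EcoItem, ...] = (
    EcoItem("Water", "reagent", 0),
    EcoItem("Tetrahydrofuran", "reagent", 6),
    EcoItem("Trifluoroacetic acid", "reagent", 4),
    EcoItem("Acetonitrile", "reagent", 4),
    EcoItem("Energy (> 0.1 kWh per sample)", "energy", 1),
    EcoItem("Occupational hazard", "occupational hazard", 3),
    EcoItem("Waste", "waste", 5),
)


@dataclass(frozen=True)
class EcoScaleSheet:
    items: tuple[EcoItem, ...]
    total_penalty: float
    score: float
    classification: str


def _classify(score: float) -> str:
    if score == 100:
        return "ideal"
    if score > 75:
        return "great green"
    if score >= 50:
        return "acceptable"
    return "inadequate"


def eco_scale(items: Iterable[EcoItem]) -> EcoScaleSheet:
    """Score = 100 - total penalty points (floored at 0 with a warning)."""
    items = tuple(items)
    total = float(sum(it.penalty for it in items))
    score = 100.0 - total
    if score < 0:
        warnings.warn(
            f"total penalty {total} exceeds 100; score floored at 0",
            stacklevel=2)
        score = 0.0
    return EcoScaleSheet(items, total, score, _classify(score))


@dataclass(frozen=True)
class MethodSummary:
    """Summary statistics of one method's recoveries (%)."""

    mean: float
    sd: float
    n: int
    variance: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError("n must be >= 2")
        if self.sd < 0:
            raise DomainError("sd must be >= 0")

    @property
    def var(self) -> float:
        """Variance: the supplied value if given (printed tables often round
        sd and variance independently), else sd^2."""
        return self.sd ** 2 if self.variance is None else self.variance

    @classmethod
    def from_observations(cls, values: Sequence[float]) -> "MethodSummary":
        v = np.asarray(values, dtype=float)
        return cls(float(v.mean()), float(v.std(ddof=1)), int(v.size),
                   float(v.var(ddof=1)))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    critical: float | None
    verdict: str | None   # "no significant difference" / "significant difference"


@dataclass(frozen=True)
class FTestResult:
    f: float
    df: tuple[int, int]
    critical: float | None
    verdict: str | None


def _verdict(stat: float, critical: float | None) -> str | None:
    if critical is None:
        return None
    return ("no significant difference" if abs(stat) < critical
            else "significant difference")


def pooled_t_test(a: MethodSummary, b: MethodSummary,
                  critical: float | None = None) -> TTestResult:
    """Two-sample t on the means with pooled variance
    s_p^2 = ((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2).

    The pooled variance is always built from the SDs (summary tables often
    round sd and variance independently; the sd carries more digits of the
    underlying data)."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    t = (a.mean - b.mean) / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return TTestResult(t, df, critical, _verdict(t, critical))


def variance_ratio_test(a: MethodSummary, b: MethodSummary,
                        critical: float | None = None) -> FTestResult:
    """F = larger variance / smaller variance (always >= 1)."""
    if a.var <= 0 or b.var <= 0:
        raise DomainError("both variances must be > 0")
    if a.var >= b.var:
        f, df = a.var / b.var, (a.n - 1, b.n - 1)
    else:
        f, df = b.var / a.var, (b.n - 1, a.n - 1)
    return FTestResult(f, df, critical, _verdict(f, critical))
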