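"""Multilevel multifactor calibration design and univariate line fitting.

The calibration set follows a Brereton-style multilevel partial factorial:
for l concentration levels and up to l mixture factors it produces l^2 runs
in which every level of every factor occurs exactly l times and all factor
columns are mutually orthogonal (zero Pearson correlation).  Columns are
generated over the finite field GF(l) -- run r = (i, j) with i = r // l,
j = r % l gets factor k the level  j + k*i  (field arithmetic), which is
balanced and pairwise orthogonal for any distinct multipliers k.  Levels
are coded symmetrically around zero ({-2,-1,0,+1,+2} for five levels) and
mapped affinely onto each analyte's validated linear concentration range.

For the three-drug study this yields the 25-mixture, five-level design;
16 runs serve as the calibration set and 9 as the external validation set,
chosen by a seeded split constrained so that both subsets span every level
of every factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError
from .signal_core import ConcentrationTable, PotentialGrid, VoltammogramSet

__all__ = [
    "MixtureDesign",
    "UnivariateFit",
    "brereton_design",
    "map_levels_to_concentrations",
    "split_calibration_validation",
    "univariate_fit",
    "peak_currents",
]

_SUPPORTED_LEVELS = (3, 4, 5, 7)

# GF(4) multiplication over {0, 1, x, x+1} encoded as 0..3 (x^2 = x + 1);
# addition is XOR
_GF4_MUL = np.array([[0, 0, 0, 0],
                     [0, 1, 2, 3],
                     [0, 2, 3, 1],
                     [0, 3, 1, 2]])


def _gf_add(a, b, l):
    return np.bitwise_xor(a, b) if l == 4 else (a + b) % l


def _gf_mul(a, b, l):
    return _GF4_MUL[a, b] if l == 4 else (a * b) % l


@dataclass(frozen=True)
class MixtureDesign:
    """l^2-run design: ``level_codes`` holds the centred codes, one column
    per factor; each code appears exactly ``n_levels`` times per column and
    the columns are mutually uncorrelated."""

    n_levels: int
    n_factors: int
    level_codes: np.ndarray

    @property
    def n_runs(self) -> int:
        return self.level_codes.shape[0]

    @property
    def codes(self) -> np.ndarray:
        """The sorted set of level codes used by every factor."""
        return np.arange(self.n_levels) - (self.n_levels - 1) / 2.0


def brereton_design(n_levels: int = 5, n_factors: int = 3) -> MixtureDesign:
    """Generate the multilevel partial-factorial design (l^2 runs)."""
    if n_levels not in _SUPPORTED_LEVELS:
        raise ConfigurationError(
            f"n_levels must be one of {_SUPPORTED_LEVELS}, got {n_levels}"
        )
    if not (1 <= n_factors <= n_levels):
        raise ConfigurationError(
            f"n_factors must be between 1 and n_levels={n_levels}"
        )
    l = n_levels
    runs = np.arange(l * l)
    i, j = runs // l, runs % l
    codes = np.arange(l) - (l - 1) / 2.0
    cols = [codes[_gf_add(j, _gf_mul(k, i, l), l)] for k in range(n_factors)]
    return MixtureDesign(n_levels, n_factors, np.column_stack(cols))


def map_levels_to_concentrations(design: MixtureDesign,
                                 ranges: Mapping[str, tuple[float, float]],
                                 ) -> ConcentrationTable:
    """Affine map of level codes onto per-analyte concentration ranges:
    the lowest code becomes ``low`` mol/L, the highest ``high``, with equal
    spacing in between."""
    if len(ranges) != design.n_factors:
        raise ConfigurationError(
            f"{len(ranges)} ranges supplied for {design.n_factors} factors"
        )
    cmin, cmax = design.codes[0], design.codes[-1]
    columns = []
    for name, (low, high) in ranges.items():
        if not (low < high):
            raise ConfigurationError(f"{name}: range low must be below high")
        columns.append(low + (design.level_codes[:, len(columns)] - cmin)
                       / (cmax - cmin) * (high - low))
    ids = [f"mix{r + 1:02d}" for r in range(design.n_runs)]
    return ConcentrationTable(ids, list(ranges), np.column_stack(columns))


def split_calibration_validation(table: ConcentrationTable,
                                 n_cal: int = 16, n_val: int = 9,
                                 seed: int = 0,
                                 max_tries: int = 10000,
                                 ) -> tuple[list[str], list[str]]:
    """Seeded, balance-preserving split into calibration and validation IDs.

    Both subsets must contain every concentration level of every analyte;
    candidate random splits are drawn until one satisfies this (the same
    seed always reproduces the same split).
    """
    n = table.n_samples
    if n_cal + n_val > n:
        raise ConfigurationError(
            f"n_cal + n_val = {n_cal + n_val} exceeds the {n} available runs"
        )
    if n_cal < 1 or n_val < 0:
        raise ConfigurationError("n_cal must be >= 1 and n_val >= 0")
    levels = [np.unique(table.values[:, a]) for a in range(len(table.analytes))]
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        cal, val = perm[:n_cal], perm[n_cal:n_cal + n_val]
        ok = True
        for a, lv in enumerate(levels):
            if (not np.isin(lv, table.values[cal, a]).all()
                    or (n_val > 0
                        and not np.isin(lv, table.values[val, a]).all())):
                ok = False
                break
        if ok:
            cal_ids = [table.sample_ids[i] for i in sorted(cal)]
            val_ids = [table.sample_ids[i] for i in sorted(val)]
            return cal_ids, val_ids
    raise ConfigurationError(
        "no level-balanced split found; subset sizes may be too small to "
        "cover every level"
    )


@dataclass(frozen=True)
class UnivariateFit:
    """Ordinary least-squares calibration line (current vs concentration)."""

    slope: float        # current units per mol/L
    intercept: float    # current units
    r: float            # Pearson correlation coefficient


def univariate_fit(concs: np.ndarray, peak_currents: np.ndarray) -> UnivariateFit:
    """Fit one analyte's calibration line by OLS."""
    x = np.asarray(concs, dtype=float)
    y = np.asarray(peak_currents, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("concs and currents must be 1-D vectors of equal length")
    if x.size < 3:
        raise DomainError("at least 3 points are required")
    if np.ptp(x) == 0:
        raise DomainError("concentrations are all equal; line is undefined")
    res = stats.linregress(x, y)
    return UnivariateFit(float(res.slope), float(res.intercept), float(res.rvalue))


def peak_currents(vset: VoltammogramSet, ep: float,
                  window: float = 0.05) -> np.ndarray:
    """Apex current of every trace within ``ep +- window`` volts -- the
    univariate peak-height readout on (baseline-corrected) traces."""
    e = vset.grid.potentials()
    mask = np.abs(e - ep) <= window
    if not mask.any():
        raise DomainError(f"no grid points within {window} V of Ep = {ep} V")
    return vset.matrix[:, mask].max(axis=1)
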