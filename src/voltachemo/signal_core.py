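"""Data model for differential-pulse voltammograms and concentration tables.

A differential-pulse voltammogram (DPV) is a single current-versus-potential
trace recorded on a uniform potential grid.  The package works with three
containers:

``PotentialGrid``
    the shared, strictly increasing, uniformly spaced potential axis (V);
``Voltammogram``
    one trace (current vector) on a grid;
``VoltammogramSet``
    a sample x potential-point current matrix with shared grid and ordered
    sample IDs -- the unit every preprocessing and calibration stage
    operates on;
``ConcentrationTable``
    the paired sample x analyte matrix of nominal concentrations (mol/L).

Currents are stored in whatever unit the instrument produced, as long as it
is consistent across a data set; the data model never converts units.
Everything round-trips losslessly through plain CSV: the set header row
holds the potentials, each data row starts with the sample ID.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DomainError, FormatError

__all__ = [
    "PotentialGrid",
    "Voltammogram",
    "VoltammogramSet",
    "ConcentrationTable",
    "read_voltammogram_set",
    "write_voltammogram_set",
    "read_concentration_table",
    "write_concentration_table",
    "DEFAULT_GRID",
]

#: relative tolerance used when checking grid uniformity
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class PotentialGrid:
    """Uniform potential axis from ``start`` to ``stop`` (inclusive) in steps
    of ``step`` volts.

    The default axis, 0.00 to +1.30 V in 5 mV steps, carries 261 points.
    """

    start: float = 0.00
    stop: float = 1.30
    step: float = 0.005

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise DomainError(f"grid step must be positive, got {self.step}")
        if not (self.stop > self.start):
            raise DomainError(
                f"grid stop ({self.stop}) must exceed start ({self.start})"
            )
        n_frac = (self.stop - self.start) / self.step
        if abs(n_frac - round(n_frac)) > _GRID_RTOL * max(1.0, abs(n_frac)):
            raise DomainError(
                f"(stop - start)/step = {n_frac} is not an integer; "
                "the grid must end exactly on a step boundary"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def potentials(self) -> np.ndarray:
        """Potential values (V), strictly increasing, length ``n_points``."""
        return self.start + self.step * np.arange(self.n_points)

    def index_of(self, potential: float) -> int:
        """Index of the grid point nearest to ``potential``."""
        return int(np.argmin(np.abs(self.potentials() - potential)))

    @classmethod
    def from_potentials(cls, potentials: Sequence[float]) -> "PotentialGrid":
        """Reconstruct a grid from explicit potential values, validating
        uniform spacing.

        Raises
        ------
        FormatError
            naming the first offending column if spacing is non-uniform.
        """
        p = np.asarray(potentials, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise FormatError("a grid needs at least two potential values")
        diffs = np.diff(p)
        # the median spacing is robust to a single corrupt potential, so
        # the error points at the column that actually breaks the grid
        step = float(np.median(diffs))
        if step <= 0:
            raise FormatError("potentials must be strictly increasing")
        bad = np.nonzero(np.abs(diffs - step) > _GRID_RTOL * max(abs(step), 1e-12))[0]
        if bad.size:
            k = int(bad[0]) + 1
            raise FormatError(
                f"non-uniform potential grid: column {k + 1} (potential "
                f"{float(p[k])!r}) breaks the spacing of {step!r} V"
            )
        return cls(start=float(p[0]), stop=float(p[-1]), step=step)


def _check_current(current: np.ndarray, n_points: int) -> np.ndarray:
    c = np.asarray(current, dtype=float)
    if c.ndim != 1 or c.size != n_points:
        raise DomainError(
            f"current vector has length {c.size}, grid has {n_points} points"
        )
    if not np.all(np.isfinite(c)):
        raise DomainError("current vector contains non-finite values")
    return c


@dataclass(frozen=True)
class Voltammogram:
    """One current trace on a potential grid."""

    grid: PotentialGrid
    current: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "current", _check_current(self.current, self.grid.n_points)
        )

    def apex(self) -> tuple[float, float]:
        """(potential, current) of the global maximum of the trace."""
        i = int(np.argmax(self.current))
        return float(self.grid.potentials()[i]), float(self.current[i])


@dataclass
class VoltammogramSet:
    """A stack of voltammograms sharing one grid.

    ``matrix`` is n_samples x n_points; row order matches ``sample_ids``.
    """

    grid: PotentialGrid
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise DomainError("matrix must be 2-D (samples x potential points)")
        if m.shape[0] != len(self.sample_ids):
            raise DomainError(
                f"{m.shape[0]} matrix rows but {len(self.sample_ids)} sample IDs"
            )
        if m.shape[1] != self.grid.n_points:
            raise DomainError(
                f"matrix has {m.shape[1]} columns, grid has "
                f"{self.grid.n_points} points"
            )
        if m.size and not np.all(np.isfinite(m)):
            raise DomainError("matrix contains non-finite values")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.matrix = m

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, i: int) -> Voltammogram:
        return Voltammogram(self.grid, self.matrix[i].copy())

    def with_matrix(self, matrix: np.ndarray) -> "VoltammogramSet":
        """Same grid and IDs, new currents."""
        return VoltammogramSet(self.grid, list(self.sample_ids), matrix)

    def subset(self, ids: Sequence[str]) -> "VoltammogramSet":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return VoltammogramSet(self.grid, [self.sample_ids[i] for i in rows],
                               self.matrix[rows].copy())


@dataclass
class ConcentrationTable:
    """Nominal concentrations (mol/L): samples in rows, analytes in columns."""

    sample_ids: list[str]
    analytes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DomainError("values must be 2-D (samples x analytes)")
        if v.shape != (len(self.sample_ids), len(self.analytes)):
            raise DomainError(
                f"values shape {v.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.analytes)} analytes"
            )
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise DomainError("concentrations must be finite and non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.analytes = [str(a) for a in self.analytes]
        self.values = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, analyte: str) -> np.ndarray:
        return self.values[:, self.analytes.index(analyte)].copy()

    def subset(self, ids: Sequence[str]) -> "ConcentrationTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return ConcentrationTable([self.sample_ids[i] for i in rows],
                                  list(self.analytes), self.values[rows].copy())


DEFAULT_GRID = PotentialGrid()


def _format_potential(p: float) -> str:
    # headers carry 3 decimals (matches a 5 mV step); fall back to full
    # precision for denser grids
    s = f"{p:.3f}"
    return s if float(s) == p else repr(float(p))


def _format_value(v: float) -> str:
    # repr of a Python float is the shortest string that round-trips
    return repr(float(v))


def write_voltammogram_set(vset: VoltammogramSet, path: str | Path) -> None:
    """Write a set as CSV: header ``sample_id, E_1, ..., E_p``, one row per
    sample, full float precision (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id"] + [_format_potential(p)
                                    for p in vset.grid.potentials()])
        for sid, row in zip(vset.sample_ids, vset.matrix):
            w.writerow([sid] + [_format_value(v) for v in row])


def read_voltammogram_set(path: str | Path) -> VoltammogramSet:
    """Read a CSV written by :func:`write_voltammogram_set`.

    The grid is reconstructed from the header and checked for uniform
    spacing; the error message names the offending column if not.
    """
    path = Path(path)
    with path.open("r", newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 3:
        raise FormatError(f"{path}: header must contain at least two potentials")
    try:
        potentials = [float(x) for x in header[1:]]
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric potential in header: {exc}") from exc
    grid = PotentialGrid.from_potentials(potentials)
    ids: list[str] = []
    data: list[list[float]] = []
    for r, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row {r} has {len(row)} fields, header has {len(header)}"
            )
        ids.append(row[0])
        try:
            data.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: row {r}: {exc}") from exc
    matrix = (np.asarray(data, dtype=float)
              if data else np.empty((0, grid.n_points)))
    return VoltammogramSet(grid, ids, matrix)


def write_concentration_table(table: ConcentrationTable,
                              path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id"] + list(table.analytes))
        for sid, row in zip(table.sample_ids, table.values):
            w.writerow([sid] + [_format_value(v) for v in row])


def read_concentration_table(path: str | Path) -> ConcentrationTable:
    path = Path(path)
    with path.open("r", newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    analytes = header[1:]
    if not analytes:
        raise FormatError(f"{path}: no analyte columns")
    ids, data = [], []
    for r, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row {r} has {len(row)} fields, header has {len(header)}"
            )
        ids.append(row[0])
        try:
            data.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: row {r}: {exc}") from exc
    values = np.asarray(data, dtype=float) if data else np.empty((0, len(analytes)))
    return ConcentrationTable(ids, analytes, values)
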