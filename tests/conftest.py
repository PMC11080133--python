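"""Shared fixtures: the default mixture design, clean (artifact-free)
synthetic data, and one full default pipeline run reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import voltachemo as vc
from voltachemo.synthetic_dpv import _clean_matrix


@pytest.fixture(scope="session")
def design_table() -> vc.ConcentrationTable:
    """The 25-mixture five-level design mapped onto the three validated
    linear ranges."""
    return vc.map_levels_to_concentrations(
        vc.brereton_design(5, 3),
        {a.name: a.linear_range for a in vc.DEFAULT_ANALYTES})


@pytest.fixture(scope="session")
def max_apex(design_table) -> float:
    """Largest noiseless apex current of the design (artifact anchor)."""
    return float(_clean_matrix(design_table, vc.DEFAULT_ANALYTES,
                               vc.DEFAULT_GRID).max())


@pytest.fixture(scope="session")
def clean_simulation(design_table):
    """Artifact-free (exactly bilinear) voltammograms plus ground truth."""
    return vc.simulate(design_table, vc.DEFAULT_ANALYTES,
                       vc.ArtifactSpec.none())


@pytest.fixture(scope="session")
def default_run() -> vc.PipelineResult:
    """One full default pipeline run (seed 0), shared read-only."""
    return vc.run_pipeline(vc.PipelineConfig(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
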