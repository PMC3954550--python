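"""Shared fixtures: small, fast synthetic datasets used across test modules."""

import numpy as np
import pandas as pd
import pytest

from tfdyn import (
    FrapProtocol,
    ImagingRegime,
    MotionModel,
    NucleusGeometry,
    simulate_localizations,
)


@pytest.fixture(scope="session")
def agonist_model() -> MotionModel:
    """Reference agonist-bound receptor: ~55% diffusing, two bound states."""
    return MotionModel(
        fraction_free=0.551,
        fraction_short=0.2646,
        fraction_long=0.1844,
        d_free=1.31,
        d_bound=0.03,
        tau_short=0.7,
        tau_long=2.3,
    )


@pytest.fixture(scope="session")
def small_regime() -> ImagingRegime:
    """A light imaging regime for unit tests (seconds, not minutes)."""
    return ImagingRegime(series_per_cell=40, n_cells=6, rng_seed=11)


@pytest.fixture(scope="session")
def small_table(agonist_model, small_regime) -> pd.DataFrame:
    return simulate_localizations(agonist_model, small_regime)


@pytest.fixture(scope="session")
def tiny_frap_protocol() -> FrapProtocol:
    """Few particles, short recovery: enough for structural checks."""
    return FrapProtocol(
        n_prescans=10,
        recovery_duration=6.0,
        n_cells=2,
        n_particles=1500,
        sim_timestep=0.1,
        rng_seed=3,
    )


@pytest.fixture(scope="session")
def geometry() -> NucleusGeometry:
    return NucleusGeometry()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def pytest_collection_modifyitems(items):
    """Run the long acceptance recoveries after the fast unit suites."""
    items.sort(key=lambda it: it.fspath.basename == "test_acceptance.py")
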