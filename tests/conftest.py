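import matplotlib
matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aquakiwi import (
    PreprocessPlan,
    SimulationDesign,
    SpectralGrid,
    SpectraSet,
    run_plan,
    simulate_population,
    to_absorbance_set,
)


@pytest.fixture(scope="session")
def grid():
    return SpectralGrid()


@pytest.fixture(scope="session")
def small_population():
    """A compact simulated study (48 fruit x 4 configurations, seed 7)."""
    return simulate_population(SimulationDesign(n_fruit=48, seed=7))


@pytest.fixture(scope="session")
def small_snv2d(small_population):
    """SNV+2D spectra of the compact study."""
    absorb = to_absorbance_set(small_population.spectra, small_population.references)
    return run_plan(absorb, PreprocessPlan(steps=("snv", "savgol2d")))


@pytest.fixture
def toy_set(grid):
    """A 2-sample intensity set with distinct values for round-trip tests."""
    rng = np.random.default_rng(0)
    matrix = rng.uniform(0.4, 1.0, size=(2, len(grid)))
    table = pd.DataFrame({
        "fruit_id": ["F1", "F1"],
        "configuration": ["UU", "UP"],
        "ssc": [10.0, 10.0],
    })
    return SpectraSet(matrix=matrix, sample_table=table, grid=grid, kind="intensity")
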