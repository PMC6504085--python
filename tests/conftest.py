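"""Shared fixtures: session-scoped simulations reused across test modules."""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from cellsim.cell_model import CellType, ModelParams, run_cell_model
from cellsim.scenarios import (
    scenario_bulk_timecourse,
    scenario_confounded_growth,
    scenario_two_type_singlecell,
)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def small_trajectory():
    """Quick 12-hour run used by pathway/expression unit tests."""
    params = ModelParams(initial_num=12, hours=12.0, density=0.1, seed=5)
    types = [CellType(name="fast", cycle_mean=8.0, cycle_sd=1.0, proportion=1.0)]
    return run_cell_model(params, types)


@pytest.fixture(scope="session")
def isolated_type_a_run():
    """Fast-cycling cells (12 +/- 4 h) at negligible density: realized
    division intervals should recover the configured distribution."""
    params = ModelParams(initial_num=30, hours=56.0, density=0.001,
                         epsilon_adh=0.0, max_migration=0.5, seed=42)
    types = [CellType(name="A", cycle_mean=12.0, cycle_sd=4.0, proportion=1.0)]
    return run_cell_model(params, types)


@pytest.fixture(scope="session")
def isolated_type_b_run():
    """Slow-cycling cells (36 +/- 4 h) at negligible density."""
    params = ModelParams(initial_num=40, hours=126.0, density=0.001,
                         epsilon_adh=0.0, max_migration=0.5, seed=43)
    types = [CellType(name="B", cycle_mean=36.0, cycle_sd=4.0, proportion=1.0)]
    return run_cell_model(params, types)


@pytest.fixture(scope="session")
def bulk_scenario():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scenario_bulk_timecourse(seed=11)


@pytest.fixture(scope="session")
def singlecell_scenario():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scenario_two_type_singlecell(seed=11)


@pytest.fixture(scope="session")
def confounded_scenario():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scenario_confounded_growth(seed=11)
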