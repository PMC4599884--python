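import numpy as np
import pytest

from celldem import CellSpec, SimulationState, build_round_cell, default_parameters


@pytest.fixture(scope="session")
def table2():
    return default_parameters("table2")


@pytest.fixture(scope="session")
def small_cell(table2):
    """A coarse (resolution 3) reference cell, built once per session."""
    return build_round_cell(CellSpec(), table2, rng_seed=7, resolution=3.0)


@pytest.fixture()
def random_gas(table2):
    """50 randomly placed cytoplasm particles in a 5 um box."""
    state = SimulationState(table2, rng_seed=3)
    rng = np.random.default_rng(11)
    state.add_particles(rng.uniform(0.0, 5e-6, size=(50, 2)), "C", cell_id=0)
    return state
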