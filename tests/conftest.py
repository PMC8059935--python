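import numpy as np
import pytest
from hypothesis import settings

from hexseq import hexarray, simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_array():
    return hexarray.default_array(6, 8, seed=0)


@pytest.fixture(scope="session")
def grid12():
    return hexarray.default_array(12, 12, seed=1)


@pytest.fixture(scope="session")
def small_design():
    return simulate.SimulationDesign(
        n_rows=6, n_cols=8, cells_per_well=5, n_genes=120,
        cell_types=(
            simulate.CellTypeProgram("hepatocyte", 20),
            simulate.CellTypeProgram("MC38", 20),
            simulate.CellTypeProgram("MSC", 20),
            simulate.CellTypeProgram("myeloid", 20),
        ))


@pytest.fixture(scope="session")
def small_tissue(small_design):
    adata, truth, array = simulate.simulate_tissue(small_design, seed=7)
    return adata, truth, array


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
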