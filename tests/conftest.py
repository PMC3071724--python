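import numpy as np
import pytest

from scrollwave.cell import CellParameters, CellState


@pytest.fixture(scope="session")
def epi_params() -> CellParameters:
    return CellParameters.from_cell_type("epi")


@pytest.fixture(scope="session")
def initial_state() -> CellState:
    return CellState.initial()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
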