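import numpy as np
import pytest

from gexsens import (
    GridSpec,
    ModelParameters,
    SimulationResult,
    TABLE1_SPACE,
)


@pytest.fixture
def table1():
    return TABLE1_SPACE


@pytest.fixture
def small_grid():
    return GridSpec(5)


def make_result(protein_over_time, t_end=10.0, grid=None):
    """Build a synthetic SimulationResult from a (T, n) protein array.

    mRNA entries are zero-filled; the time grid is uniform on [0, t_end].
    """
    protein = np.asarray(protein_over_time, dtype=float)
    T, n = protein.shape
    grid = grid or GridSpec(n)
    states = np.concatenate([np.zeros((T, n)), protein], axis=1)
    times = np.linspace(0.0, t_end, T)
    params = ModelParameters(0, 0, 0, 0, 0, 0)
    return SimulationResult(times=times, states=states, params=params, grid=grid)
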