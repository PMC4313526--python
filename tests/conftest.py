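import numpy as np
import pytest

from mabkin import ExperimentDesign, load_measurements, load_params
from mabkin.estimation import DEFAULT_GLU0
from mabkin.model import IDX, STATE_NAMES
from mabkin.pso import SwarmConfig


@pytest.fixture(scope="session")
def bundled_table():
    return load_measurements("bundled")


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def pso_params():
    return load_params("pso")


@pytest.fixture(scope="session")
def bundled_initial(bundled_table):
    """13-state initial vector: t=0 measurements plus assumed glutamate."""
    init = np.zeros(len(STATE_NAMES))
    for v in bundled_table.variables:
        init[IDX[v]] = bundled_table.column(v)[0]
    init[IDX["GLU"]] = DEFAULT_GLU0
    return init


@pytest.fixture
def reduced_cfg():
    """Desk-scale swarm profile used by the fitting tests."""
    return SwarmConfig(n_particles=50, max_iter=100)


@pytest.fixture
def tiny_cfg():
    """Minimal profile for determinism/contract checks."""
    return SwarmConfig(n_particles=12, max_iter=15)
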