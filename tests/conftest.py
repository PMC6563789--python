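import pytest

from sptrf.io import CellClass
from sptrf.simulate import SimulationConfig, simulate_germline, simulate_study


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig()


@pytest.fixture(scope="session")
def germ(default_cfg):
    """Default germline simulation used by many read-only tests."""
    return simulate_germline(default_cfg, seed=3)


@pytest.fixture(scope="session")
def study():
    """Small full study with noiseless qPCR (exact copy-ratio oracle)."""
    cfg = SimulationConfig(qpcr_noise_sd=0.0, n_cells=2, clones_per_cell=30)
    return simulate_study(cfg, seed=5)


@pytest.fixture(scope="session")
def coelomocyte(study):
    return study.cells_of(1, CellClass.COELOMOCYTE)[0]


@pytest.fixture(scope="session")
def sperm(study):
    return study.cells_of(1, CellClass.SPERM)[0]
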