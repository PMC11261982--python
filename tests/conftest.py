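import warnings

import numpy as np
import pytest

from adtnorm import default_fixture, gating_fixture, run_normalization

warnings.filterwarnings("ignore", category=UserWarning)

SEED = 1234


@pytest.fixture(scope="session")
def default_sim():
    """(dataset, truth, config) — 3 batches x 4 markers x 2000 cells."""
    return default_fixture(seed=SEED, n_cells=2000)


@pytest.fixture(scope="session")
def default_norm(default_sim):
    ds, truth, config = default_sim
    return run_normalization(ds, config)


@pytest.fixture(scope="session")
def gating_sim():
    return gating_fixture(seed=SEED, n_cells=2000)


@pytest.fixture(scope="session")
def gating_norm(gating_sim):
    ds, truth, config = gating_sim
    return run_normalization(ds, config)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
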