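import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

from emdr.abm import ABMParams
from emdr.synth import TopologySpec, gen_stroma_topology


@pytest.fixture(scope="session")
def small_grid():
    """60x60 topology (~10% stroma, fragmented) for fast ABM tests."""
    return gen_stroma_topology(TopologySpec(0.10, n_seeds=15, side=60, seed=7))


@pytest.fixture(scope="session")
def fast_params():
    """Calibrated defaults with shortened phases for unit tests."""
    return ABMParams(steps_baseline=100, steps_therapy=250, n_reps=10, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
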