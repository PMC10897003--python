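import numpy as np
import pytest

from alnbrain.network import Connectome, GlobalParams, PopulationParams
from alnbrain.synthetic import synth_connectome, synth_partition
from alnbrain.transfer_tables import (NeuronParams, build_transfer_tables)

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def tables_small(neuron):
    """Coarse transfer tables: fast to build, adequate for dynamics tests."""
    return build_transfer_tables(
        neuron,
        mu_grid=np.arange(-4.0, 6.0 + 1e-9, 0.25),
        sigma_grid=np.arange(0.25, 3.5 + 1e-9, 0.25))


@pytest.fixture(scope="session")
def tables_default(neuron):
    """Default-resolution tables shared by the acceptance suite."""
    return build_transfer_tables(neuron)


@pytest.fixture(scope="session")
def connectome16():
    con, lengths = synth_connectome(16, seed=7, density=0.4)
    return con


@pytest.fixture(scope="session")
def partition16():
    return synth_partition(16, seed=7)


@pytest.fixture()
def single_node():
    return Connectome(C=np.zeros((1, 1)), D=np.zeros((1, 1)))


@pytest.fixture()
def short_glob():
    return GlobalParams(duration=6.0, transient=1.0)
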