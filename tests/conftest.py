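import numpy as np
import pytest

from cgresin.engine import EnsembleSpec, equilibrate_system
from cgresin.fixtures import make_fixture
from cgresin.forcefield import default_forcefield
from cgresin.molecules import Formulation, bisgma_template, tegdma_template
from cgresin.system import pack_box


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture(scope="session")
def teg():
    return tegdma_template()


@pytest.fixture(scope="session")
def bis():
    return bisgma_template()


@pytest.fixture(scope="session")
def mixed14(ff):
    """10 TEGDMA + 4 Bis-GMA with 2 initiators (120 beads)."""
    return make_fixture("mixed14", seed=3)


@pytest.fixture(scope="session")
def equilibrated_tegdma30(ff):
    """30 TEGDMA equilibrated at 298 K / 1 bar; shared by engine tests."""
    formulation = Formulation(w_bisgma=0.0, n_tegdma=30, n_bisgma=0)
    topo, state = pack_box(formulation, n_active=0, target_density_guess=0.7, seed=9)
    ens = EnsembleSpec(temperature=298.0, pressure=1.0, timestep_fs=20.0)
    state, _ = equilibrate_system(state, topo, ff, ens, 3000, seed=11)
    return topo, state


def rng(seed=0):
    return np.random.default_rng(seed)
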