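import numpy as np
import pytest

from protoncage.coords import CoordinateSeries
from protoncage.embed import EmbeddingSettings, embed_frames
from protoncage.pes import SurrogatePES
from protoncage.simulate import (LangevinSettings, SimulationProtocol,
                                 simulate_rc_langevin)
from protoncage.topology import make_default_topology


@pytest.fixture(scope="session")
def topo():
    return make_default_topology()


@pytest.fixture(scope="session")
def rc_short():
    """Small (4 ps analyzed) default-surface trajectory for unit tests."""
    protocol = SimulationProtocol(production_ps=3.0, equilibration_ps=1.0,
                                  n_replicas=2, replica_ps=1.0)
    return simulate_rc_langevin(SurrogatePES(), LangevinSettings(seed=11),
                                protocol).production_frames()


@pytest.fixture(scope="session")
def rc80():
    """Full default-protocol run (80 ps analyzed) used by the recovery tests."""
    return simulate_rc_langevin(SurrogatePES(), LangevinSettings(seed=0),
                                SimulationProtocol()).production_frames()


@pytest.fixture(scope="session")
def series80(rc80):
    return CoordinateSeries.from_rc(rc80)


@pytest.fixture(scope="session")
def traj80_jittered(rc80, topo):
    return embed_frames(rc80, topo, EmbeddingSettings(jitter=True, seed=0))
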