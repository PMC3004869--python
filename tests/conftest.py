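import numpy as np
import pytest

from helixtail.generate import (
    TwoStateGeneratorConfig,
    _backbone_topology,
    build_helix,
    simulate_two_state,
)
from helixtail.trajectory_io import SelectionSpec, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def helix_11():
    """Ideal alpha-helical 11-mer backbone coordinates."""
    return build_helix(11, "alpha")


@pytest.fixture(scope="session")
def topology_11():
    return _backbone_topology(11)


@pytest.fixture(scope="session")
def helix_trajectory(helix_11, topology_11):
    """Static 3-frame trajectory of the ideal helix."""
    return Trajectory(topology_11, np.repeat(helix_11[None], 3, axis=0))


@pytest.fixture(scope="session")
def jittered_helix_trajectory(helix_11, topology_11):
    """200 frames of the helix with 0.2 Å isotropic Gaussian jitter."""
    r = np.random.default_rng(7)
    coords = helix_11[None] + r.normal(scale=0.2, size=(200, *helix_11.shape))
    return Trajectory(topology_11, coords)


@pytest.fixture(scope="session")
def two_state_trajectory():
    """4000-frame native-like two-state run (p_folded 0.80, ground truth)."""
    config = TwoStateGeneratorConfig(seed=42)
    return simulate_two_state(config, 4000)


@pytest.fixture
def ca_core():
    return SelectionSpec(["CA"], (1, 7))
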