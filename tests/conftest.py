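import numpy as np
import pytest

from chromoswarm import (
    DistanceTargets,
    LossSpec,
    SwarmConfig,
    if_to_distance,
    make_fixture,
)


@pytest.fixture(scope="session")
def helix20():
    """Noiseless 20-bin helix fixture: (true_positions, if_matrix)."""
    return make_fixture("helix", 20, beta=1.0)


@pytest.fixture(scope="session")
def helix20_targets(helix20):
    _, ifm = helix20
    return if_to_distance(ifm, beta=1.0)


@pytest.fixture
def rmse_spec():
    return LossSpec(selector=0)


@pytest.fixture
def fast_config():
    """Desk-scale swarm budget used by the recovery tests."""
    return SwarmConfig(max_iterations=5000, seed=1)


def make_targets(expected, mask=None, beta=1.0):
    """Build DistanceTargets from a dense matrix of expected distances;
    default mask covers every off-diagonal pair."""
    expected = np.asarray(expected, dtype=float)
    if mask is None:
        mask = ~np.eye(expected.shape[0], dtype=bool)
    return DistanceTargets(d_expected=expected, mask=np.asarray(mask, bool), beta=beta)
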