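import numpy as np
import pytest

from abclock import SimConfig, simulate_lineage
from abclock.trajectory import fit_table


@pytest.fixture(scope="session")
def default_lineage():
    """One default-parameter lineage simulation shared across tests."""
    return simulate_lineage(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_fits(default_lineage):
    _, traj = default_lineage
    return fit_table(traj)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
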