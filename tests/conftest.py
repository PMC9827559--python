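import numpy as np
import pytest

import stressburst as sb
from stressburst.simkit import simulate_lineage


@pytest.fixture(scope="session")
def wt_cfg():
    return sb.packaged_scenario("WT_100uM")


@pytest.fixture(scope="session")
def oxyr_cfg():
    return sb.packaged_scenario("OxyR_100uM")


@pytest.fixture(scope="session")
def null_cfg():
    return sb.packaged_scenario("null_untreated")


@pytest.fixture(scope="session")
def wt_sim(wt_cfg):
    """A mid-sized burst-scenario simulation shared across tests."""
    return simulate_lineage(wt_cfg, n_cells=1500, duration=180.0, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
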