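import logging

import numpy as np
import pytest

from movieloc.synthio import CohortConfig, default_geometry, simulate_cohort

logging.getLogger("movieloc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six adults + four 3-year-olds, default study conditions, fixed seed."""
    cfg = CohortConfig(groups={"adult": 6, "3yo": 4})
    return simulate_cohort(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
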