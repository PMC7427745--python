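import numpy as np
import pytest

from wearcon.config import CohortConfig, with_degenerate_scales


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A one-subject-per-group cohort configuration."""
    return CohortConfig(group_sizes={"uncontrolled": 1, "controlled": 1,
                                     "non_asthmatic": 1}, seed=7)


@pytest.fixture(scope="session")
def degenerate_config(tiny_config):
    """Same cohort with every parameter distribution collapsed to its mean."""
    cfg = with_degenerate_scales(tiny_config)
    cfg.qc_fail_fraction = 0.0
    return cfg
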