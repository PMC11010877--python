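import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_table_cohort():
    """One fully processed default cohort (13/17 dogs), shared across tests."""
    from caninefc.studies import cohort_edge_table
    from caninefc.synthgen import default_config

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return cohort_edge_table(default_config(seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
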