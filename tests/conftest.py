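import numpy as np
import pytest
from hypothesis import settings

from cadfusion import default_config, load_published_tables, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def published():
    """Printed summary tables of the published 512-lesion reader study."""
    return load_published_tables()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-lesion synthetic cohort under the packaged default conditions."""
    return simulate_cohort(default_config(n_lesions=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
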