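import numpy as np
import pytest

from mmpkit import hydropathy, synthetic_data


@pytest.fixture(scope="session")
def scale():
    return hydropathy.cowan_whittaker()


@pytest.fixture(scope="session")
def fixture_cohort():
    """Small 3-group x 3-species cohort (deterministic)."""
    return synthetic_data.simulate_cohort(synthetic_data.fixture_cohort_spec(7))


@pytest.fixture(scope="session")
def default_cohort():
    """Full 13-group x 20-species cohort under the default study conditions."""
    return synthetic_data.simulate_cohort(synthetic_data.default_cohort_spec(11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
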