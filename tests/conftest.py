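import pytest
from hypothesis import settings

import hqdef as h

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default adult exposure scenario (70 kg, 2 L/day, year-round)."""
    return h.ExposureParams()


@pytest.fixture(scope="session")
def tables():
    return h.slovak_tables()


@pytest.fixture(scope="session")
def soft_hi(tables):
    return h.HealthIndicatorSet.from_dict(tables["indicators"]["soft"])


@pytest.fixture(scope="session")
def national_hi(tables):
    return h.HealthIndicatorSet.from_dict(tables["indicators"]["Slovak Republic"])


@pytest.fixture(scope="session")
def default_weights():
    return h.CauseWeights()
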