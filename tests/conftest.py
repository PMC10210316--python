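import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vvrkit import CohortConfig, generate_frame

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort (n = 537) with its provenance."""
    frame, info = generate_frame(CohortConfig(seed=1))
    return frame, info


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230524)
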