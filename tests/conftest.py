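import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """A 40-gene catalog shared by round-trip tests."""
    from organsnap import simulate_catalog

    return simulate_catalog(
        40,
        haplotype_distribution={1: 0.433, 2: 0.533, 3: 0.033, 4: 0.001},
        mean_length=900,
        seed=101,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
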