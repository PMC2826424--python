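import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20100223)


def random_quintets(rng, n, low=0.5, high=100.0):
    """Random positive quintets (not degenerate): arrays of shape (n, 5)."""
    return rng.uniform(low, high, size=(n, 5))
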