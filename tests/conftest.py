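import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_label_arrays(rng):
    """10,000 short random state sequences for oracle comparisons."""
    return [rng.integers(0, 3, size=int(n)).astype(np.int8)
            for n in rng.integers(5, 120, size=10_000)]
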