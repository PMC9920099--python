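import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack():
    """Five noisy variants of one 6-node binary network, stacked."""
    from netparafac import generate_dataset, stack_subjects

    ds = generate_dataset(K=6, S=5, m=0.2, density=0.2, rng_seed=7)
    return ds, stack_subjects(ds.subjects)
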