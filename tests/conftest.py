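import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, annotation-free run configuration for fast pipeline tests."""
    from psytact.pipeline import RunConfig
    from psytact.synthetic_data import CohortSpec

    return RunConfig(seed=11, cohort=CohortSpec(n_asd=4, n_td=4),
                     exclusion_annotations={})
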