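import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def tiny_cohort():
    """10+10 subjects, 12 regions — shared by structural tests."""
    from mbnet import CohortSpec, simulate_cohort

    spec = CohortSpec(
        n_group_a=10, n_group_b=10, n_regions=12, vertices_per_region=(15, 30), seed=101
    )
    return spec, simulate_cohort(spec)
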