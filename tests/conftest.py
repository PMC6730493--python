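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


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def panel2():
    from cytodx.synthetic_cohort import default_panels

    return default_panels()[1]


@pytest.fixture(scope="session")
def small_cohort(panel2):
    """A small transformed cohort shared across slower tests."""
    from cytodx.fcs_io import standard_transform
    from cytodx.synthetic_cohort import default_effects, generate_cohort

    samples, meta, truth = generate_cohort(
        panel2,
        default_effects(panel2),
        {"CVID": 6, "otherPAD": 6, "HC": 12},
        n_days=3,
        n_events_per_sample=2000,
        seed=42,
    )
    transformed = {sid: standard_transform(E) for sid, E in samples.items()}
    return transformed, meta, truth
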