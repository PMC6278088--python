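import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 1.81


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def validation_mixture():
    """Seeded five-component validation mixture with ground truth."""
    from nirsrls import make_oscillator_mixture, validation_mixture_config

    return make_oscillator_mixture(validation_mixture_config(seed=1))


@pytest.fixture(scope="session")
def block_expected_hr(validation_mixture):
    """Expected HR for the default block paradigm at the mixture's length."""
    from nirsrls.hrf import block_paradigm_train, expected_hr

    _, mixture, _ = validation_mixture
    return expected_hr(block_paradigm_train(), FS, mixture.size)
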