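import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pedpkd import cohort as cohort_mod
from pedpkd import synthetic as synth_mod

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def synth_cohort():
    """Default-size synthetic cohort (75 patients + 27 controls), seed 42."""
    return synth_mod.generate_cohort(seed=42)


@pytest.fixture(scope="session")
def derived_cohort(synth_cohort):
    cohort, truth, _ = synth_cohort
    derived, errors = cohort_mod.derive_all(cohort)
    assert errors == []
    return derived, truth
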