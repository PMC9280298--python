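import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegmediation import DEFAULT_SEED, TruthParams, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrated_truth() -> TruthParams:
    """Generator defaults calibrated to the trial's fitted coefficients."""
    return TruthParams()


@pytest.fixture(scope="session")
def default_bundle(calibrated_truth):
    """The default synthetic trial (25 subjects x 2 visits, spectra block)."""
    return generate_cohort(calibrated_truth, DEFAULT_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(DEFAULT_SEED)
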