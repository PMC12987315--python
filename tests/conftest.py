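import numpy as np
import pytest
from hypothesis import settings

from twomst.ml import SplitPlan
from twomst.pipeline import run_study
from twomst.synth import SyntheticSessionSpec, default_cohort, simulate_session

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_session():
    """One synthetic paired session under the default study conditions."""
    return simulate_session(SyntheticSessionSpec(), seed=42)


@pytest.fixture(scope="session")
def clean_session():
    """A defect-free session: no noise, jitter, compression, drift or lag."""
    spec = SyntheticSessionSpec(
        compression=0.0,
        crosstalk_y=0.0,
        crosstalk_z=0.0,
        noise_sd=0.0,
        drift_rate=0.0,
        jitter_sd_s=0.0,
        duplicate_prob=0.0,
        lag_s=0.0,
        marker_noise_m=0.0,
    )
    return simulate_session(spec, seed=42)


@pytest.fixture(scope="session")
def cohort20():
    """The 20-subject evaluation cohort (compression and noise on)."""
    return default_cohort(20, seed=7)


@pytest.fixture(scope="session")
def study20(cohort20):
    """Full AA-vs-ML study on the 20-subject cohort."""
    return run_study(cohort20, plan=SplitPlan(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
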