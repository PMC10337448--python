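import numpy as np
import pytest

from schedquit.schedule_engine import SmokerProfile
from schedquit.synthetic_trial import TrialConfig, generate_trial


@pytest.fixture
def profile_23():
    """23 cpd smoker awake 07:00-23:00."""
    return SmokerProfile(baseline_cpd=23, wake_time=7 * 60, bed_time=23 * 60)


@pytest.fixture
def profile_20():
    return SmokerProfile(baseline_cpd=20, wake_time=7 * 60, bed_time=23 * 60)


@pytest.fixture(scope="session")
def default_trial():
    """One defaults-configured trial dataset, shared across read-only tests."""
    return generate_trial(TrialConfig(), seed=20260904).participants


def make_config(**overrides) -> TrialConfig:
    cfg = TrialConfig(**overrides)
    return cfg


def random_profile(rng: np.random.Generator) -> SmokerProfile:
    """A plausible random smoker profile (cpd >= 10 to avoid the warning)."""
    cpd = int(rng.integers(10, 61))
    wake = int(rng.integers(0, 12 * 60))
    waking = int(rng.integers(8 * 60, 18 * 60))
    bed = min(wake + waking, 1440)
    return SmokerProfile(baseline_cpd=cpd, wake_time=wake, bed_time=bed)
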