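import numpy as np
import pytest

from sensewin import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_cohort():
    """40 subjects, strong age-5-7 effect, fixed seed."""
    cfg = SimConfig(n_subjects=40, effect_size=1.5, noise_sd=1.0, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def null_cohort():
    """No exposure effect at all: the response is pure noise."""
    cfg = SimConfig(n_subjects=40, effect_size=0.0, type_effect=0.0, noise_sd=1.0, seed=11)
    return simulate_cohort(cfg)
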