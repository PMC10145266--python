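import numpy as np
import pytest

from tacropk import SimConfig, simulate_population


@pytest.fixture(scope="session")
def paper_like_cohort():
    """A 14-subject cohort under the default (study-condition) generator."""
    cfg = SimConfig(n_subjects=14, seed=7)
    truths, profiles = simulate_population(cfg)
    return cfg, truths, profiles


@pytest.fixture(scope="session")
def large_cohort():
    """A cohort large enough that class geometric means sit well within 2%
    of their targets (sampling SE per class is ~0.5%)."""
    cfg = SimConfig(n_subjects=20_000, seed=11)
    truths, profiles = simulate_population(cfg)
    return cfg, truths, profiles


@pytest.fixture
def rng():
    return np.random.default_rng(20230411)
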