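import numpy as np
import pytest

from onsetstrat import ScenarioConfig, sample_onset_mixture, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort under the default dominant-haplotype scenario."""
    cfg = ScenarioConfig(n_cases=300, n_controls=1500, master_seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def onset_sample():
    """Full-cohort-sized draw from the fitted two-component onset mixture."""
    return sample_onset_mixture(4523, weights=(0.384, 0.616), seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
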