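import numpy as np
import pytest

from breathcad.spectra import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticCohortConfig:
    """A fast cohort: few samples, 400 points, same band structure as default."""
    return SyntheticCohortConfig(n_egc=6, n_agc=8, n_healthy=6, n_points=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
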