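import numpy as np
import pytest

from pgxdili.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded case-control cohort shared across module tests."""
    cfg = SimulationConfig(
        n_cases=60, n_controls=150, n_population=400, n_null_variants=30, seed=20240301
    )
    g, pheno, truth = simulate_cohort(cfg)
    return cfg, g, pheno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
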