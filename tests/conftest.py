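import numpy as np
import pytest

from conndist.simulate import SimConfig, simulate_cohort

SMALL_PARTITION = (5, 5, 5, 5, 4, 3, 3)  # 30 regions over 7 networks


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a strong planted 15-edge component (negative association)."""
    config = SimConfig(
        n_subjects=120,
        n_regions=30,
        partition_sizes=SMALL_PARTITION,
        effect_edges=15,
        effect_rho=-0.5,
        seed=42,
    )
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted structure anywhere (pure noise)."""
    config = SimConfig(
        n_subjects=80,
        n_regions=30,
        partition_sizes=SMALL_PARTITION,
        effect_edges=0,
        effect_rho=0.0,
        path_a=0.0,
        path_b=0.0,
        path_c_prime=0.0,
        seed=7,
    )
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
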