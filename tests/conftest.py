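import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from dnvscreen.simulate import CohortSimConfig, simulate_cohort, simulate_trio_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """60-family cohort (~8,400 dnSNVs), shared across read-only tests."""
    return simulate_cohort(CohortSimConfig(n_families=60, seed=7))


@pytest.fixture(scope="session")
def fullscale_cohort():
    """Cohort at the reference size: 1,917 families, ~267k dnSNVs."""
    return simulate_cohort(CohortSimConfig(seed=11))


@pytest.fixture(scope="session")
def quad_fixture(tmp_path_factory):
    """Quad VCF/PED fixture with one planted site of every class."""
    result = simulate_trio_genotypes(
        {
            "true_denovo": 20,
            "inherited": 15,
            "low_gq": 6,
            "low_dp": 5,
            "high_af": 4,
            "high_maf": 3,
            "excluded": 4,
            "recurrent": 3,
            "missing_gt": 2,
        },
        n_families=8,
        seed=42,
    )
    paths = result.write(tmp_path_factory.mktemp("quads"))
    return result, paths
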