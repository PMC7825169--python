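import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ampdiv.simulate import SimulationConfig, simulate_community

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """Small but structured community: 3 lineages, 3 regions, 8 samples."""
    return SimulationConfig(seed=7, n_lineages=3, genotypes_per_lineage=(4, 8),
                            lakes_per_region=(2, 1, 1),
                            depth_range=(150, 600))


@pytest.fixture(scope="session")
def small_community(small_cfg):
    return simulate_community(small_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240916)
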