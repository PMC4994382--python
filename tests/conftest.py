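import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prevmap import SyntheticConfig, simulate_survey
from prevmap.adjacency import grid_adjacency

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_survey():
    """A compact synthetic survey shared across read-only tests."""
    cfg = SyntheticConfig(n_regions=2, districts_per_region=4,
                          clusters_per_district_mean=5.0,
                          cluster_size_mean=8.0, seed=20240915)
    ds, truth = simulate_survey(cfg)
    return cfg, ds, truth


@pytest.fixture
def grid6():
    """Queen adjacency of a 6x6 district lattice."""
    return grid_adjacency(np.arange(36).reshape(6, 6))
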