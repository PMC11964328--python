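import numpy as np
import pytest

from edgentropy import (SyntheticConfig, build_entropy_table,
                        default_subnetwork_map, simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced three-group cohort with a planted subnetwork effect."""
    cfg = SyntheticConfig(
        n_regions=30, n_time=120, group_sizes=(16, 12, 16), seed=42,
        effect_map={"MDDSI": {"dorsal_attention": -2.5,
                              "default_mode": 2.0}})
    subjects, manifest, truth = simulate_cohort(cfg)
    return cfg, subjects, manifest, truth


@pytest.fixture(scope="session")
def small_entropy_table(small_cohort):
    cfg, subjects, manifest, _ = small_cohort
    subnets = default_subnetwork_map(cfg.n_regions)
    return build_entropy_table(subjects, manifest, subnets, k=10,
                               n_restarts=5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
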