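import numpy as np
import pytest

import xqtlmap as xm


@pytest.fixture(scope="session")
def toy_map() -> xm.GeneticMap:
    """20-cM single chromosome at a uniform 2 cM/Mb."""
    return xm.GeneticMap.linear({"chr1": 20.0})


@pytest.fixture(scope="session")
def small_config() -> xm.SimConfig:
    return xm.SimConfig(
        seed=42, n_replicates=4, pool_size_range=(80, 80), mean_coverage=50,
        survival_target=0.2, duplicate_control_replicates=(),
        chrom_lengths_cm={"chr1": 20.0}, snps_per_cm=25, dirichlet_alpha=None)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """A neutral 4-replicate experiment shared across read-only tests."""
    pools, truth, panel = xm.simulate_experiment(small_config)
    return pools, truth, panel, small_config.genetic_map()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
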