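import numpy as np
import pytest

from pcaplace import (
    PlacementConfig,
    SimConfig,
    pca_reference,
    simulate_panel,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A 3-population panel small enough for per-test placements."""
    return SimConfig(n_pops=3, n_per_pop=30, L=600, Fst=0.1, seed=11, outgroup_Fst=0.2)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_space(small_panel):
    panel, _ = small_panel
    return pca_reference(panel, K=4)


@pytest.fixture(scope="session")
def small_study(small_panel, small_cfg):
    _, truth = small_panel
    return simulate_study(truth, small_cfg, assignments=[0, 1, 2] * 4, seed=77)


@pytest.fixture()
def placement_cfg() -> PlacementConfig:
    return PlacementConfig(K=4, K_prime=20, min_loci=100, knn_k=10, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
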