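import numpy as np
import pytest
from hypothesis import settings

from ennrl import ENNConfig, generate_synthetic_ppi, split_golden_standard
from ennrl.network import network_from_edges

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def path_graph():
    """3-node path a-b-c."""
    return network_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def path_plus_isolate():
    """Path of 3 nodes plus one isolated node."""
    return network_from_edges(["a", "b", "c", "d"], [("a", "b"), ("b", "c")])


@pytest.fixture
def single_edge_pair():
    return network_from_edges(["a", "b"], [("a", "b")])


@pytest.fixture
def synthetic_net():
    """Mid-size duplication-divergence network used across modules."""
    return generate_synthetic_ppi(120, 0.4, 0.1, seed=11)


@pytest.fixture
def synthetic_split(synthetic_net):
    return split_golden_standard(synthetic_net, 0.3, seed=5)


def random_adjacency(m: int, p: float, seed: int) -> np.ndarray:
    """Symmetric binary adjacency with zero diagonal (test helper)."""
    rng = np.random.default_rng(seed)
    a = (rng.random((m, m)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T


def fast_enn_config(**overrides) -> ENNConfig:
    """Config that converges quickly on desk-size networks."""
    base = dict(
        learning_rate=0.02,
        max_epochs=2000,
        patience=50,
        loss_tolerance=1e-8,
        seed=0,
    )
    base.update(overrides)
    return ENNConfig(**base)
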