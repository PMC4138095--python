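import networkx as nx
import pytest

from pathcrosstalk import PpiNetwork, SimulationConfig, simulate_study


@pytest.fixture
def triangle_net():
    return PpiNetwork(graph=nx.Graph([("v1", "v2"), ("v2", "v3"), ("v1", "v3")]))


def path_network(n: int) -> PpiNetwork:
    return PpiNetwork(graph=nx.path_graph([f"v{i}" for i in range(1, n + 1)]))


def small_config(seed: int = 0, **kw) -> SimulationConfig:
    """Down-scaled study for fast unit tests."""
    defaults = dict(
        n_genes=300,
        n_pathways=5,
        pathway_size_range=(8, 12),
        n_risk_pathways=3,
        candidates_per_pathway=5,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(seed=11))
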