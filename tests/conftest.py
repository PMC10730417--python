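import numpy as np
import pytest

from fcnet import synthetic
from fcnet.connectivity import BinaryGraph


@pytest.fixture(scope="session")
def toy_graphs() -> dict[str, synthetic.ToyGraph]:
    return synthetic.generate_toy_graphs()


@pytest.fixture(scope="session")
def small_fixture_graphs(toy_graphs):
    """Adjacency matrices of at most 12 nodes for oracle comparisons."""
    import networkx as nx

    graphs = {
        name: tg.adjacency
        for name, tg in toy_graphs.items()
        if tg.adjacency.shape[0] <= 12
    }
    graphs["er_12"] = nx.to_numpy_array(
        nx.gnp_random_graph(12, 0.35, seed=7), dtype=int
    )
    graphs["er_10_sparse"] = nx.to_numpy_array(
        nx.gnp_random_graph(10, 0.25, seed=11), dtype=int
    )
    return graphs


@pytest.fixture
def rng():
    return np.random.default_rng(20230929)


def as_graph(adj) -> BinaryGraph:
    return BinaryGraph(np.asarray(adj))
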