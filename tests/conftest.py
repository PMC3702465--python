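import networkx as nx
import pytest

from netprio import GeneNetwork, GeneSet, SyntheticScenario


@pytest.fixture
def path_net() -> GeneNetwork:
    """a - b - c path."""
    g = nx.Graph([("a", "b"), ("b", "c")])
    return GeneNetwork(g)


@pytest.fixture
def star_net() -> GeneNetwork:
    g = nx.star_graph(4)
    g = nx.relabel_nodes(g, {0: "h", 1: "l1", 2: "l2", 3: "l3", 4: "l4"})
    return GeneNetwork(g)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """Compact scenario keeping unit tests fast."""
    return SyntheticScenario(
        seed=11,
        n_genes=120,
        module_size=15,
        known_size=8,
        goset_size=20,
        goset_purity=0.6,
        n_datasets=2,
        genes_per_dataset=80,
        samples_per_dataset=12,
        n_terms=12,
        n_planted_terms=3,
    )


@pytest.fixture(scope="session")
def small_data(small_scenario):
    return small_scenario.generate()


def random_network(rng, n, p) -> GeneNetwork:
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    if g.number_of_edges() == 0:
        g.add_edge("n000", "n001")
    return GeneNetwork(g)


def make_seed_set(*genes) -> GeneSet:
    return GeneSet("seeds", genes)
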