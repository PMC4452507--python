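import networkx as nx
import numpy as np
import pytest

from gsmf.features import BipartiteInteractions
from gsmf.network import GeneNetwork


@pytest.fixture
def path_network():
    """a - b - c path graph."""
    return GeneNetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def er_network():
    """Erdos-Renyi graph G(30, 0.2), nodes n0..n29."""
    g = nx.gnp_random_graph(30, 0.2, seed=7)
    return GeneNetwork.from_edges(
        (f"n{a}", f"n{b}") for a, b in g.edges
    )


@pytest.fixture
def small_bipartite():
    """5 drugs x 8 genes random binary map, seeded."""
    rng = np.random.default_rng(11)
    drugs = [f"d{i}" for i in range(5)]
    genes = [f"g{j}" for j in range(8)]
    pairs = [
        (d, g) for d in drugs for g in genes if rng.random() < 0.4
    ]
    # drug d4 left without interactors on purpose
    pairs = [(d, g) for d, g in pairs if d != "d4"]
    return BipartiteInteractions.from_pairs(pairs, row_ids=drugs, col_ids=genes)


def bfs_all_pairs(network: GeneNetwork):
    """Independent exhaustive BFS oracle: dict of dicts of hop counts."""
    adj = {n: set() for n in network.graph.nodes}
    for a, b in network.graph.edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for src in adj:
        dist = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        out[src] = dist
    return out
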