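import numpy as np
import pytest

from cnmnet.network import Bipartite, Layer, MultilayerNetwork, Multiplex, NodeRef
from cnmnet.rwr import RWRConfig


@pytest.fixture
def two_node_net() -> MultilayerNetwork:
    """Single multiplex, single undirected edge A-B."""
    layer = Layer.from_edges("l", [("A", "B", 1.0)])
    return MultilayerNetwork((Multiplex("genes", (layer,)),))


@pytest.fixture
def hetero_toy() -> MultilayerNetwork:
    """Two multiplexes (genes: 2 layers, metabolites: 1 layer) joined by one
    undirected bipartite; small enough to hand-check."""
    g1 = Layer.from_edges("ppi", [("a", "b", 1.0), ("b", "c", 1.0)])
    g2 = Layer.from_edges("coexpr", [("a", "c", 0.5)], weighted=True)
    m1 = Layer.from_edges("pathway", [("x", "y", 1.0)])
    bip = Bipartite.from_edges("gm", "genes", "metabolites", [("a", "x", 1.0)])
    return MultilayerNetwork(
        (Multiplex("genes", (g1, g2)), Multiplex("metabolites", (m1,))), (bip,)
    )


def random_multilayer(rng: np.random.Generator) -> MultilayerNetwork:
    """Random 2-3 multiplex toy with mixed directed/undirected layers and
    bipartites; <= ~200 supra-states."""
    n_mp = int(rng.integers(2, 4))
    multiplexes = []
    for k in range(n_mp):
        n_nodes = int(rng.integers(4, 12))
        nodes = [f"m{k}n{i}" for i in range(n_nodes)]
        n_layers = int(rng.integers(1, 4))
        layers = []
        for a in range(n_layers):
            directed = bool(rng.random() < 0.3)
            weighted = bool(rng.random() < 0.5)
            edges = []
            for i in range(n_nodes):
                for j in range(n_nodes):
                    if i == j or (not directed and i > j):
                        continue
                    if rng.random() < 0.35:
                        w = float(rng.uniform(0.2, 2.0)) if weighted else 1.0
                        edges.append((nodes[i], nodes[j], w))
            layers.append(
                Layer.from_edges(f"L{a}", edges, directed=directed, weighted=weighted)
            )
        multiplexes.append(Multiplex(f"mp{k}", tuple(layers), frozenset(nodes)))
    bipartites = []
    for k in range(n_mp - 1):
        src = sorted(multiplexes[k].node_universe)
        tgt = sorted(multiplexes[k + 1].node_universe)
        directed = bool(rng.random() < 0.3)
        edges = []
        for a in src:
            for b in tgt:
                if rng.random() < 0.25:
                    edges.append((a, b, 1.0))
        if not edges:
            edges = [(src[0], tgt[0], 1.0)]
        bipartites.append(
            Bipartite.from_edges(
                f"bip{k}", f"mp{k}", f"mp{k + 1}", edges, directed=directed
            )
        )
    return MultilayerNetwork(tuple(multiplexes), tuple(bipartites))


@pytest.fixture
def rwr_config() -> RWRConfig:
    return RWRConfig(restart=0.7)


def seed_in(net: MultilayerNetwork, multiplex: str = None) -> NodeRef:
    mp = net.multiplexes[0] if multiplex is None else net.get_multiplex(multiplex)
    return NodeRef(mp.name, sorted(mp.node_universe)[0])
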