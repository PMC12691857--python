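"""Random walk with restart: transition construction, solvers, ranking."""

import numpy as np
import pandas as pd
import pytest

from cnmnet.network import Bipartite, Layer, MultilayerNetwork, Multiplex, NodeRef
from cnmnet.rwr import (
    RandomWalkRestart,
    RWRConfig,
    SeedSet,
    build_transition,
    exact_scores,
    rank_top,
    rwr_scores,
)

from conftest import random_multilayer


def _single_layer_net(edges, nodes=None, directed=False, weighted=False):
    layer = Layer.from_edges("l", edges, directed=directed, weighted=weighted)
    extra = frozenset(nodes or ()) - layer.node_ids
    return MultilayerNetwork((Multiplex("m", (layer,), extra),))


class TestBuildTransition:
    def test_single_layer_reduces_to_column_normalized_adjacency(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0), ("c", "d", 1.0)]
        net = _single_layer_net(edges)
        trans = build_transition(net)
        nodes = trans.index.nodes["m"]
        adj = np.zeros((4, 4))
        pos = {n: i for i, n in enumerate(nodes)}
        for x, y, _ in edges:
            adj[pos[x], pos[y]] = adj[pos[y], pos[x]] = 1.0
        expected = adj / adj.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(trans.matrix.toarray(), expected, atol=1e-15)
        assert not trans.dangling.any()

    def test_isolated_node_is_fully_dangling(self):
        net = _single_layer_net([("a", "b", 1.0)], nodes={"z"})
        trans = build_transition(net)
        z_col = list(trans.index.nodes["m"]).index("z")
        assert trans.dangling[z_col] == pytest.approx(1.0)
        assert trans.matrix[:, z_col].sum() == 0.0

    def test_directed_edges_walked_one_way(self):
        net = _single_layer_net([("a", "b", 1.0)], directed=True)
        trans = build_transition(net)
        nodes = list(trans.index.nodes["m"])
        a, b = nodes.index("a"), nodes.index("b")
        mat = trans.matrix.toarray()
        assert mat[b, a] == 1.0
        assert mat[a, b] == 0.0
        assert trans.dangling[b] == pytest.approx(1.0)

    def test_three_node_toy_with_bipartite_hand_enumeration(self):
        # genes: a-b edge; metabolites: x alone; bipartite a-x (undirected).
        g = Layer.from_edges("g", [("a", "b", 1.0)])
        m = Layer.from_edges("m", [], weighted=False)
        bip = Bipartite.from_edges("bip", "G", "M", [("a", "x", 1.0)])
        net = MultilayerNetwork(
            (Multiplex("G", (g,)), Multiplex("M", (m,), frozenset({"x"}))), (bip,)
        )
        trans = build_transition(net)
        idx = trans.index
        gpos = {n: i for i, n in enumerate(idx.nodes["G"])}
        mat = trans.matrix.toarray()
        col_a = idx.state("G", 0, gpos["a"])
        col_b = idx.state("G", 0, gpos["b"])
        col_x = idx.state("M", 0, 0)
        # from a: stay (1/2) -> b; jump to M (1/2) -> x
        assert mat[idx.state("G", 0, gpos["b"]), col_a] == pytest.approx(0.5)
        assert mat[col_x, col_a] == pytest.approx(0.5)
        # from b: no bipartite neighbors -> stay with prob 1 -> a
        assert mat[idx.state("G", 0, gpos["a"]), col_b] == pytest.approx(1.0)
        # from x: no intra-layer edges; jump back to a with prob 1/2, dangle 1/2
        assert mat[col_a, col_x] == pytest.approx(0.5)
        assert trans.dangling[col_x] == pytest.approx(0.5)

    def test_columns_are_stochastic_with_dangling(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = random_multilayer(rng)
            trans = build_transition(net)
            colsum = np.asarray(trans.matrix.sum(axis=0)).ravel() + trans.dangling
            np.testing.assert_allclose(colsum, 1.0, atol=1e-12)


class TestSolvers:
    def test_restart_limit_returns_restart_vector(self, two_node_net):
        config = RWRConfig(restart=1 - 1e-12)
        solver = RandomWalkRestart(two_node_net, config)
        s = solver.scores([NodeRef("genes", "A")])
        v = solver.restart_vector([NodeRef("genes", "A")])
        np.testing.assert_allclose(s.supra, v, atol=1e-9)

    def test_uniform_seed_on_cycle_gives_uniform_scores(self):
        edges = [(f"n{i}", f"n{(i + 1) % 8}", 1.0) for i in range(8)]
        net = _single_layer_net(edges)
        seeds = [NodeRef("m", f"n{i}") for i in range(8)]
        s = rwr_scores(net, seeds, RWRConfig())
        np.testing.assert_allclose(s.aggregate().values, 1 / 8, atol=1e-9)

    def test_two_node_closed_form(self, two_node_net):
        # s_A = 0.3 s_B + 0.7, s_B = 0.3 s_A  =>  s_A = 0.7/0.91
        s = rwr_scores(two_node_net, [NodeRef("genes", "A")], RWRConfig(restart=0.7))
        agg = s.aggregate()
        assert agg[("genes", "A")] == pytest.approx(0.7 / 0.91, abs=1e-9)
        assert agg[("genes", "B")] == pytest.approx(0.21 / 0.91, abs=1e-9)

    def test_single_node_network_gets_all_mass(self):
        net = _single_layer_net([], nodes={"only"})
        s = exact_scores(net, [NodeRef("m", "only")], RWRConfig())
        assert s.aggregate()[("m", "only")] == pytest.approx(1.0)

    def test_iterative_matches_exact_on_random_toys(self):
        rng = np.random.default_rng(42)
        config = RWRConfig(restart=0.7, tolerance=1e-12)
        for _ in range(20):
            net = random_multilayer(rng)
            solver = RandomWalkRestart(net, config)
            mp = net.multiplexes[int(rng.integers(len(net.multiplexes)))]
            seed = NodeRef(mp.name, sorted(mp.node_universe)[0])
            it = solver.scores([seed]).aggregate()
            ex = solver.exact([seed]).aggregate()
            assert np.abs(it.values - ex.values).max() < 1e-8
            assert it.sum() == pytest.approx(1.0, abs=1e-8)

    def test_conservation_with_dangling_states(self):
        net = _single_layer_net([("a", "b", 1.0)], nodes={"z"}, directed=True)
        s = rwr_scores(net, [NodeRef("m", "a")], RWRConfig())
        assert s.total == pytest.approx(1.0, abs=1e-8)

    def test_seed_locality(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 12
            edges = [(f"n{i}", f"n{(i + 1) % n}", 1.0) for i in range(n)]
            edges += [("n0", f"n{i}", 1.0) for i in range(2, 5)]
            net = _single_layer_net(edges)
            seed_node = f"n{int(rng.integers(n))}"
            s = rwr_scores(net, [NodeRef("m", seed_node)], RWRConfig())
            scores = s.node_scores("m")
            assert scores[seed_node] > scores.median()

    def test_deterministic_bit_identical(self, hetero_toy):
        s1 = rwr_scores(hetero_toy, [NodeRef("genes", "a")], RWRConfig())
        s2 = rwr_scores(hetero_toy, [NodeRef("genes", "a")], RWRConfig())
        assert (s1.supra == s2.supra).all()

    def test_pagerank_reduction_against_independent_solver(self):
        # personalized PageRank on a single undirected layer, solved densely
        # and independently of the package's operator construction
        rng = np.random.default_rng(3)
        n = 15
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j], 1.0)
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.3
        ]
        net = _single_layer_net(edges, nodes=nodes)
        r = 0.7
        seed = NodeRef("m", "n0")
        s = rwr_scores(net, [seed], RWRConfig(restart=r, tolerance=1e-14)).node_scores("m")

        adj = np.zeros((n, n))
        for a, b, _ in edges:
            i, j = int(a[1:]), int(b[1:])
            adj[i, j] = adj[j, i] = 1.0
        deg = adj.sum(axis=0)
        P = np.divide(adj, deg[None, :], out=np.zeros_like(adj), where=deg[None, :] > 0)
        v = np.zeros(n)
        v[0] = 1.0
        dangle = (deg == 0).astype(float)
        A = np.eye(n) - (1 - r) * (P + np.outer(v, dangle))
        ref = np.linalg.solve(A, r * v)
        ordered = np.array([s[f"n{i}"] for i in range(n)])
        assert np.abs(ordered - ref).max() < 1e-10

    def test_missing_seed_raises_naming_node(self, two_node_net):
        with pytest.raises(KeyError, match="nope"):
            rwr_scores(two_node_net, [NodeRef("genes", "nope")])

    def test_nonconvergence_raises_with_residual(self, two_node_net):
        config = RWRConfig(restart=0.7, tolerance=1e-300, max_iterations=3)
        with pytest.raises(Exception, match="did not converge"):
            RandomWalkRestart(two_node_net, config).scores([NodeRef("genes", "A")])


class TestSeedSet:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            SeedSet([])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            SeedSet([(NodeRef("m", "a"), -1.0)])

    def test_weighted_seeds_shift_restart_mass(self, two_node_net):
        solver = RandomWalkRestart(two_node_net, RWRConfig())
        v = solver.restart_vector(
            SeedSet([(NodeRef("genes", "A"), 3.0), (NodeRef("genes", "B"), 1.0)])
        )
        nodes = list(solver.transition.index.nodes["genes"])
        assert v[nodes.index("A")] == pytest.approx(0.75)
        assert v[nodes.index("B")] == pytest.approx(0.25)


class TestRankTop:
    def _scores(self, net, mapping):
        solver = RandomWalkRestart(net, RWRConfig())
        sv = solver.scores([NodeRef("m", next(iter(mapping)))])
        # overwrite supra with a crafted distribution for ranking checks
        idx = solver.transition.index
        sv.supra = np.zeros_like(sv.supra)
        for node, val in mapping.items():
            sv.supra[idx.state("m", 0, list(idx.nodes["m"]).index(node))] = val
        return sv

    def test_tie_broken_lexically(self):
        net = _single_layer_net([("A", "B", 1.0), ("B", "C", 1.0)])
        sv = self._scores(net, {"A": 0.3, "B": 0.3, "C": 0.2})
        top = rank_top(sv, "m", 2)
        assert list(top["node"]) == ["A", "B"]

    def test_exclusion(self):
        net = _single_layer_net([("A", "B", 1.0), ("B", "C", 1.0)])
        sv = self._scores(net, {"A": 0.3, "B": 0.3, "C": 0.2})
        top = rank_top(sv, "m", 3, exclude={NodeRef("m", "A")})
        assert list(top["node"]) == ["B", "C"]

    def test_overlong_request_returns_all(self):
        net = _single_layer_net([("A", "B", 1.0)])
        sv = self._scores(net, {"A": 0.6, "B": 0.4})
        top = rank_top(sv, "m", 20)
        assert len(top) == 2

    def test_unknown_multiplex_rejected(self, two_node_net):
        sv = rwr_scores(two_node_net, [NodeRef("genes", "A")])
        with pytest.raises(KeyError):
            rank_top(sv, "ghost", 5)
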