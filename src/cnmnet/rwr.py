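"""Random walk with restart on a multiplex-heterogeneous network.

The walker lives on supra-states (multiplex, layer, node).  At every step it
restarts from the seed set with probability ``r`` (default 0.7); otherwise it
either stays in its multiplex — picking one of the multiplex's layers
uniformly and following an out-edge proportionally to edge weight — or jumps
through a bipartite to another multiplex, landing on a bipartite neighbor in
a uniformly chosen layer.  The choice between staying and each reachable
multiplex is uniform; jump mass toward multiplexes where the current node has
no bipartite neighbor is reallocated to staying so columns stay stochastic.
States with nowhere to go (dangling) redirect their mass to the restart
vector, the standard PageRank correction.

Scores are stationary probabilities, aggregated per node by summing over
layers; they sum to one and measure proximity to the seeds.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .network import MultilayerNetwork, NodeRef

logger = logging.getLogger(__name__)

__all__ = [
    "RWRConfig",
    "SeedSet",
    "ScoreVector",
    "SupraIndex",
    "SupraTransition",
    "RandomWalkRestart",
    "ConvergenceError",
    "build_transition",
    "rwr_scores",
    "exact_scores",
    "rank_top",
]


class ConvergenceError(RuntimeError):
    """Iterative solver failed to reach tolerance; carries the last residual."""

    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"random walk did not converge in {iterations} iterations "
            f"(last L1 residual {residual:.3e})"
        )
        self.residual = residual
        self.iterations = iterations


@dataclass(frozen=True)
class RWRConfig:
    """Random-walk parameters.

    ``restart`` is the global restart probability r.  ``multiplex_restart_weights``
    (tau) weights the restart mass across multiplexes; the default is uniform
    over the multiplexes that actually contain seeds (renormalized).  Layer
    choice and inter-multiplex jumps are uniform.
    """

    restart: float = 0.7
    multiplex_restart_weights: dict[str, float] | None = None
    tolerance: float = 1e-10
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart < 1.0:
            raise ValueError("restart probability must lie in (0, 1)")
        if self.multiplex_restart_weights is not None:
            vals = list(self.multiplex_restart_weights.values())
            if any(w < 0 for w in vals) or sum(vals) <= 0:
                raise ValueError("multiplex restart weights must be non-negative, not all zero")


class SeedSet:
    """Non-empty set of seed nodes with optional non-negative weights."""

    def __init__(self, seeds: Iterable[NodeRef | tuple]):
        items: list[tuple[NodeRef, float]] = []
        for entry in seeds:
            if isinstance(entry, NodeRef):
                items.append((entry, 1.0))
            elif len(entry) == 2 and isinstance(entry[1], (int, float)):
                items.append((NodeRef(*entry[0]), float(entry[1])))
            else:
                items.append((NodeRef(*entry), 1.0))
        if not items:
            raise ValueError("seed set is empty")
        if any(w < 0 for _, w in items):
            raise ValueError("seed weights must be non-negative")
        if sum(w for _, w in items) <= 0:
            raise ValueError("seed weights sum to zero")
        self.items: tuple[tuple[NodeRef, float], ...] = tuple(items)

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class SupraIndex:
    """Bijection between supra-states (multiplex, layer, node) and flat ints."""

    multiplex_names: tuple[str, ...]
    nodes: dict[str, tuple[str, ...]]  # multiplex -> sorted node ids
    n_layers: dict[str, int]
    offsets: dict[str, int]
    n_states: int
    pos: dict[str, dict[str, int]]  # multiplex -> node id -> index

    @classmethod
    def from_network(cls, net: MultilayerNetwork) -> "SupraIndex":
        nodes = {m.name: tuple(sorted(m.node_universe)) for m in net.multiplexes}
        n_layers = {m.name: len(m.layers) for m in net.multiplexes}
        offsets: dict[str, int] = {}
        total = 0
        for m in net.multiplexes:
            offsets[m.name] = total
            total += len(nodes[m.name]) * n_layers[m.name]
        pos = {k: {n: i for i, n in enumerate(v)} for k, v in nodes.items()}
        return cls(
            tuple(m.name for m in net.multiplexes), nodes, n_layers, offsets, total, pos
        )

    def node_pos(self, multiplex: str) -> dict[str, int]:
        return self.pos[multiplex]

    def state(self, multiplex: str, layer_idx: int, node_idx: int) -> int:
        return self.offsets[multiplex] + layer_idx * len(self.nodes[multiplex]) + node_idx


@dataclass(frozen=True)
class SupraTransition:
    """Column-stochastic supra operator plus per-column dangling mass."""

    index: SupraIndex
    matrix: sparse.csr_matrix  # matrix[row, col]: mass flowing col -> row
    dangling: np.ndarray  # per-column mass redirected to the restart vector


def build_transition(net: MultilayerNetwork, config: RWRConfig | None = None) -> SupraTransition:
    """Build the supra transition operator for a validated network.

    From state (k, alpha, i): pick uniformly among {stay in k} and the
    multiplexes where node i has at least one bipartite neighbor (respecting
    bipartite direction).  Staying picks one of k's layers uniformly and moves
    along an out-edge of i proportionally to weight (mass for layers where i
    has no out-edge is dangling).  Jumping to l moves to a bipartite neighbor
    proportionally to bipartite weight, landing in a uniformly chosen layer
    of l.
    """
    del config  # probabilities are structural under the uniform factorization
    idx = SupraIndex.from_network(net)
    pos = {m.name: idx.node_pos(m.name) for m in net.multiplexes}

    # per (multiplex, layer): node -> [(neighbor index, weight)]
    out_nbrs: dict[str, list[dict[int, list[tuple[int, float]]]]] = {}
    for mp in net.multiplexes:
        p = pos[mp.name]
        layers = []
        for layer in mp.layers:
            nbrs: dict[int, list[tuple[int, float]]] = {}
            for a, b, w in layer.edges:
                ia, ib = p[a], p[b]
                nbrs.setdefault(ia, []).append((ib, w))
                if not layer.directed:
                    nbrs.setdefault(ib, []).append((ia, w))
            layers.append(nbrs)
        out_nbrs[mp.name] = layers

    # per multiplex: node index -> {other multiplex: [(neighbor index, weight)]}
    bip_nbrs: dict[str, dict[int, dict[str, list[tuple[int, float]]]]] = {
        m.name: {} for m in net.multiplexes
    }

    def _add_bip(src_mp: str, src: str, tgt_mp: str, tgt: str, w: float) -> None:
        i = pos[src_mp][src]
        j = pos[tgt_mp][tgt]
        bip_nbrs[src_mp].setdefault(i, {}).setdefault(tgt_mp, []).append((j, w))

    for bip in net.bipartites:
        for a, b, w in bip.edges:
            _add_bip(bip.source_multiplex, a, bip.target_multiplex, b, w)
            if not bip.directed:
                _add_bip(bip.target_multiplex, b, bip.source_multiplex, a, w)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for mp in net.multiplexes:
        k = mp.name
        n_k = len(idx.nodes[k])
        L_k = idx.n_layers[k]
        for i in range(n_k):
            reachable = [
                l for l, nb in bip_nbrs[k].get(i, {}).items() if nb
            ]
            p_each = 1.0 / (1.0 + len(reachable))
            jump_cols = [idx.state(k, alpha, i) for alpha in range(L_k)]
            # staying: identical distribution from every source layer alpha
            stay_entries: list[tuple[int, float]] = []
            for beta in range(L_k):
                nbrs = out_nbrs[k][beta].get(i)
                if not nbrs:
                    continue  # dangling share, implicit in 1 - colsum
                total_w = sum(w for _, w in nbrs)
                for j, w in nbrs:
                    stay_entries.append(
                        (idx.state(k, beta, j), p_each / L_k * w / total_w)
                    )
            for l in reachable:
                nbrs = bip_nbrs[k][i][l]
                total_w = sum(w for _, w in nbrs)
                L_l = idx.n_layers[l]
                for j, w in nbrs:
                    share = p_each * w / total_w / L_l
                    for beta_l in range(L_l):
                        stay_entries.append((idx.state(l, beta_l, j), share))
            for col in jump_cols:
                for row, val in stay_entries:
                    rows.append(row)
                    cols.append(col)
                    vals.append(val)

    mat = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(idx.n_states, idx.n_states)
    )
    colsum = np.asarray(mat.sum(axis=0)).ravel()
    dangling = np.clip(1.0 - colsum, 0.0, 1.0)
    dangling[dangling < 1e-15] = 0.0
    return SupraTransition(idx, mat, dangling)


@dataclass
class ScoreVector:
    """RWR stationary probabilities: supra-scores plus per-node aggregation."""

    index: SupraIndex
    supra: np.ndarray

    def aggregate(self) -> pd.Series:
        """Per-node score (sum over layers), indexed by (multiplex, node)."""
        parts = []
        for k in self.index.multiplex_names:
            n_k = len(self.index.nodes[k])
            L_k = self.index.n_layers[k]
            off = self.index.offsets[k]
            block = self.supra[off : off + n_k * L_k].reshape(L_k, n_k).sum(axis=0)
            parts.append(
                pd.Series(
                    block,
                    index=pd.MultiIndex.from_product(
                        [[k], self.index.nodes[k]], names=["multiplex", "node"]
                    ),
                )
            )
        return pd.concat(parts).rename("score")

    def node_score_array(self, multiplex: str) -> np.ndarray:
        """Per-node scores of one multiplex, aligned with
        ``index.nodes[multiplex]`` (sorted node ids).  No pandas overhead;
        used by the resampling scans."""
        n_k = len(self.index.nodes[multiplex])
        L_k = self.index.n_layers[multiplex]
        off = self.index.offsets[multiplex]
        return self.supra[off : off + n_k * L_k].reshape(L_k, n_k).sum(axis=0)

    def node_scores(self, multiplex: str) -> pd.Series:
        """Per-node scores of one multiplex, indexed by node id."""
        return pd.Series(
            self.node_score_array(multiplex),
            index=list(self.index.nodes[multiplex]),
            name="score",
        )

    @property
    def total(self) -> float:
        return float(self.supra.sum())


def _restart_vector(
    trans: SupraTransition, net: MultilayerNetwork, seeds: SeedSet, config: RWRConfig
) -> np.ndarray:
    idx = trans.index
    by_mp: dict[str, list[tuple[int, float]]] = {}
    for ref, w in seeds:
        if ref.multiplex not in idx.nodes:
            raise KeyError(f"seed multiplex {ref.multiplex!r} not in network")
        p = idx.node_pos(ref.multiplex)
        if ref.node not in p:
            raise KeyError(f"seed node {ref.node!r} not found in multiplex {ref.multiplex!r}")
        by_mp.setdefault(ref.multiplex, []).append((p[ref.node], w))

    if config.multiplex_restart_weights is not None:
        tau = {
            k: config.multiplex_restart_weights.get(k, 0.0) for k in by_mp
        }
    else:
        tau = {k: 1.0 for k in by_mp}
    total_tau = sum(tau.values())
    if total_tau <= 0:
        raise ValueError("restart weights give zero mass to every seeded multiplex")

    v = np.zeros(idx.n_states)
    for k, entries in by_mp.items():
        mass_k = tau[k] / total_tau
        w_total = sum(w for _, w in entries)
        if w_total <= 0:
            raise ValueError(f"seed weights in multiplex {k!r} sum to zero")
        L_k = idx.n_layers[k]
        for node_idx, w in entries:
            for alpha in range(L_k):
                v[idx.state(k, alpha, node_idx)] += mass_k * (w / w_total) / L_k
    return v


class RandomWalkRestart:
    """Reusable solver bound to one network: build the supra operator once,
    then score many seed sets (iteratively or by exact linear solve)."""

    def __init__(self, net: MultilayerNetwork, config: RWRConfig | None = None):
        self.net = net
        self.config = config or RWRConfig()
        self.transition = build_transition(net, self.config)

    def restart_vector(self, seeds: SeedSet | Iterable) -> np.ndarray:
        seeds = seeds if isinstance(seeds, SeedSet) else SeedSet(seeds)
        return _restart_vector(self.transition, self.net, seeds, self.config)

    def scores(self, seeds: SeedSet | Iterable) -> ScoreVector:
        """Power iteration s <- (1-r)(M s + (d.s) v) + r v to L1 tolerance."""
        v = self.restart_vector(seeds)
        r = self.config.restart
        M = self.transition.matrix
        d = self.transition.dangling
        s = v.copy()
        residual = np.inf
        for _ in range(self.config.max_iterations):
            s_new = (1.0 - r) * (M @ s + d.dot(s) * v) + r * v
            residual = float(np.abs(s_new - s).sum())
            s = s_new
            if residual < self.config.tolerance:
                return ScoreVector(self.transition.index, s)
        raise ConvergenceError(residual, self.config.max_iterations)

    def exact(self, seeds: SeedSet | Iterable) -> ScoreVector:
        """Dense linear solve of s = (1-r)(M + v d^T) s + r v (small networks)."""
        idx = self.transition.index
        if idx.n_states > 5000:
            raise ValueError("exact solver is for small instances (<= ~5000 supra-states)")
        v = self.restart_vector(seeds)
        r = self.config.restart
        M_hat = self.transition.matrix.toarray() + np.outer(v, self.transition.dangling)
        A = np.eye(idx.n_states) - (1.0 - r) * M_hat
        s = np.linalg.solve(A, r * v)
        assert abs(s.sum() - 1.0) < 1e-8, "exact solve lost probability mass"
        return ScoreVector(idx, s)


def rwr_scores(
    net: MultilayerNetwork, seeds: SeedSet | Iterable, config: RWRConfig | None = None
) -> ScoreVector:
    """One-shot iterative RWR (builds the transition operator internally)."""
    return RandomWalkRestart(net, config).scores(seeds)


def exact_scores(
    net: MultilayerNetwork, seeds: SeedSet | Iterable, config: RWRConfig | None = None
) -> ScoreVector:
    """One-shot exact RWR by dense linear solve; verification oracle for the
    iterative solver on small instances."""
    return RandomWalkRestart(net, config).exact(seeds)


def rank_top(
    scores: ScoreVector,
    multiplex: str,
    top_n: int,
    exclude: Iterable[NodeRef] = (),
) -> pd.DataFrame:
    """Top-scoring nodes of one multiplex.

    Deterministic ordering: score descending, ties broken by node id
    ascending.  Excluded nodes (typically the seeds) are dropped before
    ranking.  Asking for more rows than available returns all, with a warning.
    """
    if multiplex not in scores.index.multiplex_names:
        raise KeyError(f"no multiplex {multiplex!r} in scores")
    drop = {NodeRef(*e).node for e in exclude if NodeRef(*e).multiplex == multiplex}
    ser = scores.node_scores(multiplex)
    ser = ser[~ser.index.isin(drop)]
    df = ser.reset_index()
    df.columns = ["node", "score"]
    df = df.sort_values(["score", "node"], ascending=[False, True], kind="mergesort")
    if top_n > len(df):
        logger.warning(
            "requested top %d of multiplex %s but only %d nodes available",
            top_n, multiplex, len(df),
        )
    out = df.head(top_n).reset_index(drop=True)
    out.index = out.index + 1
    out.index.name = "rank"
    return out
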