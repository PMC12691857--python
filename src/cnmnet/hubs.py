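"""Resampling null for nonspecific hubs.

Network propagation is biased toward topologically central nodes: generic
metabolites (water, ATP, cations) and highly connected genes surface in the
top of almost any seed's ranking.  This module implements the random-seeding
null that detects them: run RWR from many randomly drawn single-gene seeds,
count how often each node lands in the top-10/50/100 of its category, and
call nodes hubs when they occur in the top-50 in strictly more than 5% of
iterations.  Hubs are then removed from the network (genes and metabolites
only) before seed-specific queries.

A paired full-vs-subset scan (same seed sequence with and without chosen
layers, e.g. the experimental co-expression layers) quantifies how much those
layers drive hub structure.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MultilayerNetwork, NodeRef, drop_layers
from .rwr import ConvergenceError, RandomWalkRestart, RWRConfig

logger = logging.getLogger(__name__)

__all__ = [
    "HubScanConfig",
    "HubReport",
    "FullSubsetComparison",
    "random_seed_scan",
    "detect_hubs",
    "full_vs_subset_scan",
]


@dataclass(frozen=True)
class HubScanConfig:
    """Parameters of the random-seed hub scan.

    ``seed_pool`` is the population the random seeds are drawn from (with
    replacement), typically every protein-coding gene node.  ``hub_top_k``
    and ``hub_fraction`` define the hub rule: occurrence in the top
    ``hub_top_k`` of a category in strictly more than ``hub_fraction`` of the
    (converged) iterations.  ``hub_multiplexes`` limits hub *calling* to some
    categories (genes and metabolites by default behaviour when left None:
    all categories present in the report are eligible; the pipeline passes
    the gene and metabolite multiplex names explicitly).
    """

    seed_pool: tuple[NodeRef, ...]
    n_iterations: int = 1000
    top_k_levels: tuple[int, ...] = (10, 50, 100)
    hub_top_k: int = 50
    hub_fraction: float = 0.05
    rng_seed: int = 0
    hub_multiplexes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.hub_top_k not in self.top_k_levels:
            raise ValueError("hub_top_k must be one of top_k_levels")
        if not 0.0 < self.hub_fraction < 1.0:
            raise ValueError("hub_fraction must lie in (0, 1)")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be non-negative")
        object.__setattr__(
            self, "seed_pool", tuple(NodeRef(*s) for s in self.seed_pool)
        )


@dataclass
class HubReport:
    """Occurrence counts per (multiplex, node, top-k level) over a scan."""

    counts: pd.DataFrame  # columns: multiplex, node, top_k, count
    n_iterations: int
    n_effective: int  # converged iterations (the denominators)
    failed_iterations: tuple[int, ...] = ()
    config: HubScanConfig | None = None

    def counts_at(self, top_k: int) -> pd.DataFrame:
        return self.counts[self.counts["top_k"] == top_k].reset_index(drop=True)

    def count_of(self, multiplex: str, node: str, top_k: int) -> int:
        sel = self.counts[
            (self.counts["multiplex"] == multiplex)
            & (self.counts["node"] == node)
            & (self.counts["top_k"] == top_k)
        ]
        return int(sel["count"].iloc[0]) if len(sel) else 0


def random_seed_scan(
    net: MultilayerNetwork,
    config: HubScanConfig,
    rwr_config: RWRConfig | None = None,
    solver: RandomWalkRestart | None = None,
) -> HubReport:
    """Run RWR from ``n_iterations`` random single-node seeds and count
    top-k occurrences per category.

    Seeds are drawn uniformly with replacement from ``config.seed_pool``
    using a generator seeded with ``config.rng_seed`` (the scan is fully
    deterministic).  Each iteration's seed is excluded from its own ranking.
    Iterations whose walk fails to converge are recorded and excluded from
    the occurrence denominators.
    """
    if not config.seed_pool:
        raise ValueError("seed pool is empty")
    if solver is None:
        solver = RandomWalkRestart(net, rwr_config)
    idx = solver.transition.index
    for ref in config.seed_pool:
        if ref.multiplex not in idx.pos or ref.node not in idx.pos[ref.multiplex]:
            raise KeyError(f"seed pool node {ref} not in network")
    rng = np.random.default_rng(config.rng_seed)
    draws = rng.integers(0, len(config.seed_pool), size=config.n_iterations)

    levels = sorted(config.top_k_levels)
    k_max = levels[-1]
    node_arrays = {k: np.asarray(idx.nodes[k]) for k in idx.multiplex_names}
    counters: dict[str, dict[int, np.ndarray]] = {
        mp: {k: np.zeros(len(node_arrays[mp]), dtype=np.int64) for k in levels}
        for mp in idx.multiplex_names
    }
    failed: list[int] = []
    for it in range(config.n_iterations):
        seed = config.seed_pool[int(draws[it])]
        try:
            sv = solver.scores([seed])
        except ConvergenceError:
            logger.warning("iteration %d (seed %s) did not converge; excluded", it, seed)
            failed.append(it)
            continue
        for mp in idx.multiplex_names:
            arr = sv.node_score_array(mp).copy()
            if mp == seed.multiplex:
                pos = idx.node_pos(mp).get(seed.node)
                if pos is not None:
                    arr[pos] = -np.inf  # seed excluded from its own ranking
            # stable argsort on descending score; node ids are already sorted,
            # so ties break by ascending node id
            order = np.argsort(-arr, kind="stable")
            order = order[np.isfinite(arr[order])]
            for k in levels:
                counters[mp][k][order[:k]] += 1

    rows = []
    for mp in idx.multiplex_names:
        for k in levels:
            cnt = counters[mp][k]
            nz = np.flatnonzero(cnt)
            for i in nz:
                rows.append(
                    {"multiplex": mp, "node": node_arrays[mp][i], "top_k": k,
                     "count": int(cnt[i])}
                )
    counts = pd.DataFrame(rows, columns=["multiplex", "node", "top_k", "count"])
    return HubReport(
        counts=counts,
        n_iterations=config.n_iterations,
        n_effective=config.n_iterations - len(failed),
        failed_iterations=tuple(failed),
        config=config,
    )


def detect_hubs(report: HubReport, config: HubScanConfig | None = None) -> set[NodeRef]:
    """Nodes occurring in the top-``hub_top_k`` of their category in strictly
    more than ``hub_fraction`` of converged iterations.

    The strict inequality means a node at exactly the 5% boundary is *not* a
    hub.  Calling is limited to ``config.hub_multiplexes`` when set (the hub
    removal rule applies to genes and metabolites, not phenotypes).
    """
    config = config or report.config
    if config is None:
        raise ValueError("no HubScanConfig available")
    if report.n_effective == 0:
        return set()
    cutoff = config.hub_fraction * report.n_effective
    sel = report.counts[report.counts["top_k"] == config.hub_top_k]
    if config.hub_multiplexes is not None:
        sel = sel[sel["multiplex"].isin(config.hub_multiplexes)]
    sel = sel[sel["count"] > cutoff]
    return {NodeRef(r.multiplex, r.node) for r in sel.itertuples()}


@dataclass
class FullSubsetComparison:
    """Paired scans on the full network and a layer-dropped subset."""

    full: HubReport
    subset: HubReport
    paired: pd.DataFrame  # multiplex, node, top_k, count_full, count_subset
    correlations: pd.DataFrame  # multiplex, top_k, pearson_r, n_nodes


def full_vs_subset_scan(
    net: MultilayerNetwork,
    dropped_layers: Sequence[str | tuple[str, str]],
    config: HubScanConfig,
    rwr_config: RWRConfig | None = None,
) -> FullSubsetComparison:
    """Run the random-seed scan on the full network and on the network minus
    ``dropped_layers`` with the *same* seed sequence, and pair the counts.

    The paired table underlies the full-vs-subset occurrence scatter; the
    Pearson correlation of paired counts is reported per category and top-k
    level.  Dropped layers keep their nodes in the universe (as isolated
    nodes), so the seed pool stays valid.
    """
    subset_net = drop_layers(net, dropped_layers, keep_nodes=True) if dropped_layers else net
    full_report = random_seed_scan(net, config, rwr_config)
    subset_report = random_seed_scan(subset_net, config, rwr_config)

    merged = pd.merge(
        full_report.counts.rename(columns={"count": "count_full"}),
        subset_report.counts.rename(columns={"count": "count_subset"}),
        on=["multiplex", "node", "top_k"],
        how="outer",
    ).fillna(0)
    merged["count_full"] = merged["count_full"].astype(int)
    merged["count_subset"] = merged["count_subset"].astype(int)
    merged = merged.sort_values(["multiplex", "top_k", "node"]).reset_index(drop=True)

    rows = []
    for (mp, k), grp in merged.groupby(["multiplex", "top_k"], sort=True):
        x = grp["count_full"].values.astype(float)
        y = grp["count_subset"].values.astype(float)
        if len(grp) < 2 or x.std() == 0 or y.std() == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"multiplex": mp, "top_k": k, "pearson_r": r, "n_nodes": len(grp)})
    correlations = pd.DataFrame(rows, columns=["multiplex", "top_k", "pearson_r", "n_nodes"])
    return FullSubsetComparison(full_report, subset_report, merged, correlations)
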