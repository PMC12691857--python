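"""Joint-seed disease queries and overlap reporting.

A query seeds the walk jointly with a disease gene (e.g. Mtm1) and a
phenotype term (e.g. HP:0003202, skeletal muscle atrophy) and returns the
top-scoring gene and metabolite nodes.  Running several queries — one per
phenotype of interest — and partitioning the union of their top lists into
shared-by-all / partially shared / query-specific nodes reproduces the
shared/specific analysis shape used to prioritize candidate metabolites.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd

from .network import MultilayerNetwork, NodeRef
from .rwr import RandomWalkRestart, RWRConfig, rank_top

__all__ = ["QueryResult", "OverlapTable", "joint_seed_query", "overlap_table"]


@dataclass
class QueryResult:
    """Top-scoring genes and metabolites for one seed set."""

    label: str
    genes: pd.DataFrame  # rank-indexed, columns: node, score
    metabolites: pd.DataFrame

    def top_nodes(self, category: str) -> list[str]:
        frame = getattr(self, category)
        return list(frame["node"])


def joint_seed_query(
    net: MultilayerNetwork,
    gene_seed: NodeRef | str | None = None,
    phenotype_seed: NodeRef | str | None = None,
    top_n: int = 20,
    rwr_config: RWRConfig | None = None,
    *,
    gene_multiplex: str = "genes",
    metabolite_multiplex: str = "metabolites",
    phenotype_multiplex: str = "phenotypes",
    label: str | None = None,
    solver: RandomWalkRestart | None = None,
) -> QueryResult:
    """Single RWR with a gene and/or a phenotype as joint seeds.

    Restart mass splits uniformly across the seeded multiplexes (so with both
    seeds, the gene and phenotype multiplexes each carry half of the restart
    mass).  Seeds are excluded from their own rankings.  A missing seed node
    raises ``KeyError`` naming it.
    """
    seeds: list[NodeRef] = []
    if gene_seed is not None:
        ref = gene_seed if isinstance(gene_seed, NodeRef) else NodeRef(gene_multiplex, gene_seed)
        seeds.append(ref)
    if phenotype_seed is not None:
        ref = (
            phenotype_seed
            if isinstance(phenotype_seed, NodeRef)
            else NodeRef(phenotype_multiplex, phenotype_seed)
        )
        seeds.append(ref)
    if not seeds:
        raise ValueError("at least one seed (gene or phenotype) is required")
    for ref in seeds:
        if not net.has_node(ref):
            raise KeyError(f"seed node {ref.node!r} not found in multiplex {ref.multiplex!r}")

    if solver is None:
        solver = RandomWalkRestart(net, rwr_config)
    scores = solver.scores(seeds)
    genes = rank_top(scores, gene_multiplex, top_n, exclude=seeds)
    metabolites = rank_top(scores, metabolite_multiplex, top_n, exclude=seeds)
    if label is None:
        label = "+".join(s.node for s in seeds)
    return QueryResult(label=label, genes=genes, metabolites=metabolites)


@dataclass
class OverlapTable:
    """Partition of the union of top lists across queries.

    ``table`` has one row per (category, node): the sorted query labels that
    rank it, and a status among ``shared_all`` (every query), ``shared_some``
    (at least two but not all), and ``specific`` (exactly one).
    """

    table: pd.DataFrame  # category, node, labels, n_queries, status
    query_labels: tuple[str, ...]

    def nodes(self, category: str, status: str) -> list[str]:
        sel = self.table[(self.table["category"] == category) & (self.table["status"] == status)]
        return list(sel["node"])

    def specific_to(self, category: str, label: str) -> list[str]:
        sel = self.table[
            (self.table["category"] == category)
            & (self.table["status"] == "specific")
            & (self.table["labels"] == label)
        ]
        return list(sel["node"])


def overlap_table(
    results: Sequence[QueryResult], categories: Sequence[str] = ("genes", "metabolites")
) -> OverlapTable:
    """Partition top-list members into shared-by-all / partially shared /
    query-specific, per category.  Requires at least two queries; ordering is
    deterministic (category, then node id)."""
    if len(results) < 2:
        raise ValueError("need at least two query results to overlap")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("query labels must be unique")
    rows = []
    for category in categories:
        membership: dict[str, set[str]] = {}
        for res in results:
            for node in res.top_nodes(category):
                membership.setdefault(node, set()).add(res.label)
        for node in sorted(membership):
            hits = membership[node]
            if len(hits) == len(results):
                status = "shared_all"
            elif len(hits) > 1:
                status = "shared_some"
            else:
                status = "specific"
            rows.append(
                {
                    "category": category,
                    "node": node,
                    "labels": ",".join(sorted(hits)),
                    "n_queries": len(hits),
                    "status": status,
                }
            )
    table = pd.DataFrame(rows, columns=["category", "node", "labels", "n_queries", "status"])
    return OverlapTable(table=table, query_labels=tuple(labels))
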