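"""Synthetic data generators with ground truth.

Everything the pipeline consumes can be simulated here: bulk RNA-seq-like
count matrices with planted co-expression modules and group-averaged
phenotypic traits (four experimental groups: wild-type, disease model, and
their treated counterparts), metabolite abundance profiles with planted
co-abundance blocks, and multiplex-heterogeneous networks mirroring the
composition of the real one (five gene layers, two metabolite layers, a
directed reaction monoplex, a phenotype DAG, isolated tissue nodes, eight
bipartites) with planted hub nodes.

All generators are pure functions of their spec: the same ``rng_seed``
reproduces the same data bit for bit, and ground truth (module labels,
latent factors, hub lists) is always returned alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import Bipartite, Layer, MultilayerNetwork, Multiplex, NodeRef

__all__ = [
    "ModuleSpec",
    "TraitSpec",
    "ExpressionSimSpec",
    "SimulatedExpression",
    "simulate_expression_with_traits",
    "LayerSimSpec",
    "MultiplexSimSpec",
    "BipartiteSimSpec",
    "HubSpec",
    "NetworkSimSpec",
    "simulate_multilayer",
    "simulate_metabolite_profiles",
    "table_shaped_network_spec",
    "DEFAULT_GROUPS",
]

DEFAULT_GROUPS = ("WT", "disease", "WT_treated", "disease_treated")


# ---------------------------------------------------------------------------
# Expression + traits


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module: a latent factor shared by
    ``n_features`` features with the given effect size and feature-level
    noise standard deviation (log scale).  ``group_shifts`` adds a
    group-dependent mean to the latent factor (disease vs rescue structure)."""

    n_features: int = 50
    effect: float = 1.0
    noise_sd: float = 0.3
    group_shifts: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class TraitSpec:
    """One phenotypic trait, built as a rho-correlated transform of its
    linked module's latent factor, then averaged within experimental group
    (each animal carries its group mean, emulating group-level phenotyping).
    ``module`` indexes into the spec's module list; None gives pure noise."""

    name: str
    module: int | None = None
    rho: float = 0.6
    group_offsets: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")


def _default_modules() -> tuple[ModuleSpec, ...]:
    # module 0 tracks healthy muscle (high in WT / rescued); module 1 tracks
    # disease severity on a weaker, non-mirrored axis (distinct biological
    # processes are only mildly collinear); module 2 responds to treatment
    # irrespective of genotype (as tamoxifen does in the real cohorts)
    healthy = {"WT": 1.0, "disease": -1.0, "WT_treated": 1.0, "disease_treated": 0.3}
    severity = {"WT": -0.5, "disease": 1.0, "WT_treated": -0.5, "disease_treated": 0.2}
    treatment = {"WT": -0.7, "disease": -0.7, "WT_treated": 0.7, "disease_treated": 0.7}
    return (
        ModuleSpec(group_shifts=healthy),
        ModuleSpec(group_shifts=severity),
        ModuleSpec(group_shifts=treatment),
    )


def _default_traits() -> tuple[TraitSpec, ...]:
    # the seven phenotypic metrics collected for the CNM cohorts
    return (
        TraitSpec("body_mass", module=0, rho=0.5),
        TraitSpec("normalized_ta_mass", module=0, rho=0.6),
        TraitSpec("relative_maximal_force", module=0, rho=0.6),
        TraitSpec("hanging_time", module=0, rho=0.5),
        TraitSpec("pct_central_nuclei", module=1, rho=0.6),
        TraitSpec("pct_abnormal_mitochondria", module=1, rho=0.5),
        TraitSpec("pct_small_fibers", module=1, rho=0.5),
    )


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Study-shaped expression simulation: 4 groups x 6 mice, 3 planted
    modules of 50 features (noise sd 0.3) plus 250 background features (the
    stable majority a real transcriptome provides, which anchors the
    median-of-ratios size factors), and 7 group-averaged traits."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {g: 6 for g in DEFAULT_GROUPS}
    )
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    n_background: int = 250
    library_size_range: tuple[float, float] = (0.7, 1.4)
    dispersion: float = 0.05
    baseline_log_mean_range: tuple[float, float] = (np.log(100.0), np.log(1000.0))
    traits: tuple[TraitSpec, ...] = field(default_factory=_default_traits)
    rng_seed: int = 0


@dataclass
class SimulatedExpression:
    """Counts + traits + ground truth from one expression simulation."""

    counts: pd.DataFrame  # features x samples, non-negative integers
    traits: pd.DataFrame  # samples x traits (group-constant values)
    truth: pd.Series  # feature -> planted label ("module_k" / "background")
    factors: pd.DataFrame  # modules x samples latent factors (with shifts)
    groups: pd.Series  # sample -> group
    achieved_trait_correlation: pd.Series  # trait -> cor(group-avg trait, factor)


def simulate_expression_with_traits(spec: ExpressionSimSpec) -> SimulatedExpression:
    """Simulate negative-binomial counts with planted modules and
    group-averaged traits.

    Per module m, a latent factor f_m is drawn standard normal per sample and
    shifted by the module's group means; each module feature's log mean is
    baseline + effect * f_m + noise.  Counts are negative binomial with the
    spec's dispersion and sample-specific library-size factors.  Traits are
    rho-correlated transforms of their linked factor, then replaced by their
    group averages; the achieved correlation between the averaged trait and
    the factor is reported (a warning is raised when group averaging makes
    the target rho unreachable).
    """
    rng = np.random.default_rng(spec.rng_seed)
    samples: list[str] = []
    groups: list[str] = []
    for g, n in spec.n_per_group.items():
        for i in range(n):
            samples.append(f"{g}_{i + 1}")
            groups.append(g)
    n_samples = len(samples)
    group_ser = pd.Series(groups, index=samples, name="group")

    factors = np.zeros((len(spec.modules), n_samples))
    feature_ids: list[str] = []
    truth: list[str] = []
    log_mu_rows: list[np.ndarray] = []
    for m, mod in enumerate(spec.modules):
        f = rng.standard_normal(n_samples)
        if mod.group_shifts:
            f = f + np.array([mod.group_shifts.get(g, 0.0) for g in groups])
        factors[m] = f
        base = rng.uniform(*spec.baseline_log_mean_range, size=mod.n_features)
        signs = np.ones(mod.n_features)  # unsigned network: same-sign loadings
        for j in range(mod.n_features):
            feature_ids.append(f"gene_m{m + 1}_{j + 1}")
            truth.append(f"module_{m + 1}")
            noise = rng.normal(0.0, mod.noise_sd, size=n_samples)
            log_mu_rows.append(base[j] + signs[j] * mod.effect * f + noise)
    for j in range(spec.n_background):
        feature_ids.append(f"gene_bg_{j + 1}")
        truth.append("background")
        base = rng.uniform(*spec.baseline_log_mean_range)
        log_mu_rows.append(base + rng.normal(0.0, 1.0, size=n_samples))

    lib = rng.uniform(*spec.library_size_range, size=n_samples)
    mu = np.exp(np.vstack(log_mu_rows)) * lib[None, :]
    if spec.dispersion > 0:
        n_nb = 1.0 / spec.dispersion
        p_nb = n_nb / (n_nb + mu)
        counts = rng.negative_binomial(n_nb, p_nb)
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=feature_ids, columns=samples)

    trait_cols = {}
    achieved = {}
    for ts in spec.traits:
        # traits linked to a module absent from this spec fall back to noise
        linked = ts.module if ts.module is not None and ts.module < len(spec.modules) else None
        ts = replace(ts, module=linked)
        if ts.module is None:
            raw = rng.standard_normal(n_samples)
        else:
            f = factors[ts.module]
            fz = (f - f.mean()) / (f.std() if f.std() > 0 else 1.0)
            raw = ts.rho * fz + np.sqrt(1.0 - ts.rho**2) * rng.standard_normal(n_samples)
        if ts.group_offsets:
            raw = raw + np.array([ts.group_offsets.get(g, 0.0) for g in groups])
        ser = pd.Series(raw, index=samples)
        averaged = ser.groupby(group_ser).transform("mean")
        trait_cols[ts.name] = averaged
        if ts.module is not None:
            f = factors[ts.module]
            if averaged.std() == 0 or np.std(f) == 0:
                ach = float("nan")
            else:
                ach = float(np.corrcoef(averaged.values, f)[0, 1])
            achieved[ts.name] = ach
            if not np.isnan(ach) and (np.sign(ach) != np.sign(ts.rho) or abs(ach) < abs(ts.rho) / 2):
                warnings.warn(
                    f"trait {ts.name!r}: group averaging yields correlation "
                    f"{ach:.2f} against target {ts.rho:.2f}",
                    stacklevel=2,
                )
        else:
            achieved[ts.name] = float("nan")
    traits_df = pd.DataFrame(trait_cols, index=samples)

    return SimulatedExpression(
        counts=counts_df,
        traits=traits_df,
        truth=pd.Series(truth, index=feature_ids, name="truth"),
        factors=pd.DataFrame(
            factors, index=[f"module_{m + 1}" for m in range(len(spec.modules))],
            columns=samples,
        ),
        groups=group_ser,
        achieved_trait_correlation=pd.Series(achieved, name="achieved_r"),
    )


# ---------------------------------------------------------------------------
# Metabolite profiles


def simulate_metabolite_profiles(
    n_metabolites: int = 60,
    n_samples: int = 16,
    blocks: tuple[ModuleSpec, ...] = (ModuleSpec(n_features=15, noise_sd=0.3),),
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal metabolite abundance matrix with planted co-abundance blocks.

    Returns (abundances, truth).  Block features share a latent factor on the
    log scale; the remaining metabolites are independent noise.  The output is
    suitable for building a co-expression layer at soft power 5 with TOM
    threshold 0.05 (the metabolomic preset).
    """
    rng = np.random.default_rng(rng_seed)
    n_block = sum(b.n_features for b in blocks)
    if n_block > n_metabolites:
        raise ValueError("blocks exceed n_metabolites")
    samples = [f"s{i + 1}" for i in range(n_samples)]
    ids: list[str] = []
    truth: list[str] = []
    rows: list[np.ndarray] = []
    for b, block in enumerate(blocks):
        f = rng.standard_normal(n_samples)
        base = rng.uniform(np.log(10.0), np.log(1000.0), size=block.n_features)
        for j in range(block.n_features):
            ids.append(f"met_b{b + 1}_{j + 1}")
            truth.append(f"block_{b + 1}")
            rows.append(base[j] + block.effect * f + rng.normal(0, block.noise_sd, n_samples))
    for j in range(n_metabolites - n_block):
        ids.append(f"met_bg_{j + 1}")
        truth.append("background")
        base = rng.uniform(np.log(10.0), np.log(1000.0))
        rows.append(base + rng.normal(0, 1.0, n_samples))
    abund = pd.DataFrame(np.exp(np.vstack(rows)), index=ids, columns=samples)
    return abund, pd.Series(truth, index=ids, name="truth")


# ---------------------------------------------------------------------------
# Multilayer networks


@dataclass(frozen=True)
class LayerSimSpec:
    """One simulated layer: Erdos-Renyi at the given density ("er"), a
    preferential-attachment graph with the same expected edge count ("pa",
    giving the heavy-tailed degrees of real interactomes), a random DAG with
    edges pointing from later to earlier nodes ("dag", emulating a
    child-to-parent ontology), or edgeless ("empty")."""

    name: str
    density: float = 0.05
    weighted: bool = False
    directed: bool = False
    kind: str = "er"  # er | pa | dag | empty

    def __post_init__(self) -> None:
        if self.kind not in ("er", "pa", "dag", "empty"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("er", "pa") and not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")


@dataclass(frozen=True)
class MultiplexSimSpec:
    name: str
    n_nodes: int
    layers: tuple[LayerSimSpec, ...]
    prefix: str = ""


@dataclass(frozen=True)
class BipartiteSimSpec:
    source: str
    target: str
    density: float = 0.02
    weighted: bool = False
    directed: bool = False
    name: str | None = None


@dataclass(frozen=True)
class HubSpec:
    """A planted hub: one node wired to ``fraction`` of its multiplex's other
    nodes in every layer."""

    multiplex: str
    fraction: float = 0.5
    node: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("hub fraction must lie in (0, 1]")


@dataclass(frozen=True)
class NetworkSimSpec:
    multiplexes: tuple[MultiplexSimSpec, ...]
    bipartites: tuple[BipartiteSimSpec, ...] = ()
    hubs: tuple[HubSpec, ...] = ()
    rng_seed: int = 0


def _node_ids(mp: MultiplexSimSpec) -> list[str]:
    prefix = mp.prefix or (mp.name[:1] + "_")
    width = max(3, len(str(mp.n_nodes)))
    return [f"{prefix}{i:0{width}d}" for i in range(mp.n_nodes)]


def _er_edges(nodes: list[str], density: float, directed: bool, weighted: bool, rng):
    n = len(nodes)
    edges = []
    if directed:
        mask = rng.random((n, n)) < density
        np.fill_diagonal(mask, False)
        pairs = np.argwhere(mask)
    else:
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < density
        pairs = np.stack([iu[keep], ju[keep]], axis=1)
    for i, j in pairs:
        w = float(rng.uniform(0.1, 1.0)) if weighted else 1.0
        edges.append((nodes[i], nodes[j], w))
    return edges


def _pa_edges(nodes: list[str], density: float, weighted: bool, rng):
    # Barabasi-Albert attachment matched to the ER edge count at `density`;
    # node labels are shuffled so hubs are not always the low-index nodes
    import networkx as nx

    n = len(nodes)
    m = max(1, round(density * (n - 1) / 2))
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(0, 2**31 - 1)))
    perm = rng.permutation(n)
    edges = []
    for i, j in g.edges():
        w = float(rng.uniform(0.1, 1.0)) if weighted else 1.0
        edges.append((nodes[perm[i]], nodes[perm[j]], w))
    return edges


def _dag_edges(nodes: list[str], density: float, rng):
    # random DAG over the node ordering: each pair (i < j) independently gives
    # a child->parent edge j -> i at the specified density
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < density
    return [(nodes[j], nodes[i], 1.0) for i, j in zip(iu[keep], ju[keep])]


def simulate_multilayer(spec: NetworkSimSpec) -> tuple[MultilayerNetwork, list[NodeRef]]:
    """Simulate a multiplex-heterogeneous network with planted hubs.

    Returns the validated network and the list of planted hub nodes.  Hubs
    are wired (on top of the random edges) to ``fraction`` of the other nodes
    of their multiplex in every non-empty-kind layer; for directed layers
    both directions are added so the hub is reachable and leaveable.
    """
    rng = np.random.default_rng(spec.rng_seed)
    hub_refs: list[NodeRef] = []
    hubs_by_mp: dict[str, list[HubSpec]] = {}
    for hub in spec.hubs:
        hubs_by_mp.setdefault(hub.multiplex, []).append(hub)

    multiplexes = []
    for mp_spec in spec.multiplexes:
        nodes = _node_ids(mp_spec)
        hub_nodes: dict[str, float] = {}
        for hub in hubs_by_mp.get(mp_spec.name, []):
            hub_node = hub.node or nodes[0]
            if hub_node not in nodes:
                raise ValueError(f"hub node {hub_node!r} not in multiplex {mp_spec.name!r}")
            hub_nodes[hub_node] = hub.fraction
            ref = NodeRef(mp_spec.name, hub_node)
            if ref not in hub_refs:
                hub_refs.append(ref)

        layers = []
        for lay in mp_spec.layers:
            if lay.kind == "er":
                edges = _er_edges(nodes, lay.density, lay.directed, lay.weighted, rng)
            elif lay.kind == "pa":
                edges = _pa_edges(nodes, lay.density, lay.weighted, rng)
            elif lay.kind == "dag":
                edges = _dag_edges(nodes, lay.density, rng)
            else:
                edges = []
            if lay.kind != "empty":
                for hub_node, fraction in hub_nodes.items():
                    others = [x for x in nodes if x != hub_node]
                    n_wire = int(np.ceil(fraction * len(others)))
                    targets = rng.choice(len(others), size=n_wire, replace=False)
                    for t in targets:
                        edges.append((hub_node, others[t], 1.0))
                        if lay.directed or lay.kind == "dag":
                            edges.append((others[t], hub_node, 1.0))
            directed = lay.directed or lay.kind == "dag"
            if lay.weighted:
                layers.append(
                    Layer.from_edges(lay.name, edges, directed=directed, weighted=True)
                )
            else:
                layers.append(
                    Layer.from_edges(lay.name, edges, directed=directed, weighted=False)
                )
        covered: set[str] = set()
        for layer in layers:
            covered |= layer.node_ids
        multiplexes.append(
            Multiplex(mp_spec.name, tuple(layers), frozenset(nodes) - covered)
        )

    nodes_by_mp = {m.name: sorted(m.node_universe) for m in multiplexes}
    bipartites = []
    for bp in spec.bipartites:
        src_nodes = nodes_by_mp[bp.source]
        tgt_nodes = nodes_by_mp[bp.target]
        mask = rng.random((len(src_nodes), len(tgt_nodes))) < bp.density
        edges = [
            (
                src_nodes[i],
                tgt_nodes[j],
                float(rng.uniform(0.1, 1.0)) if bp.weighted else 1.0,
            )
            for i, j in np.argwhere(mask)
        ]
        bipartites.append(
            Bipartite.from_edges(
                bp.name or f"{bp.source}-{bp.target}",
                bp.source,
                bp.target,
                edges,
                directed=bp.directed,
                weighted=bp.weighted,
            )
        )
    return MultilayerNetwork(tuple(multiplexes), tuple(bipartites)), hub_refs


def table_shaped_network_spec(
    rng_seed: int = 0,
    *,
    n_genes: int = 120,
    n_metabolites: int = 60,
    n_reactions: int = 80,
    n_phenotypes: int = 60,
    n_tissues: int = 10,
    hubs: tuple[HubSpec, ...] = (),
) -> NetworkSimSpec:
    """A reduced-scale spec mirroring the real network's composition: a
    5-layer gene multiplex (PPI, complex and pathway co-membership, gene and
    protein co-expression), a 2-layer metabolite multiplex, a directed
    reaction monoplex, a phenotype DAG, isolated tissue nodes, and the eight
    bipartites connecting them."""
    genes = MultiplexSimSpec(
        "genes",
        n_genes,
        (
            LayerSimSpec("ppi", 0.02, kind="pa"),
            LayerSimSpec("complex_comembership", 0.02),
            LayerSimSpec("pathway_comembership", 0.03, kind="pa"),
            LayerSimSpec("gene_coexpression", 0.05, weighted=True),
            LayerSimSpec("protein_coexpression", 0.05, weighted=True),
        ),
        prefix="g",
    )
    metabolites = MultiplexSimSpec(
        "metabolites",
        n_metabolites,
        (
            LayerSimSpec("pathway_comembership", 0.03),
            LayerSimSpec("metabolite_coexpression", 0.08, weighted=True),
        ),
        prefix="m",
    )
    reactions = MultiplexSimSpec(
        "reactions", n_reactions, (LayerSimSpec("subsystems", 0.05, directed=True),),
        prefix="r",
    )
    phenotypes = MultiplexSimSpec(
        "phenotypes", n_phenotypes, (LayerSimSpec("ontology", 0.04, kind="dag"),),
        prefix="hp",
    )
    tissues = MultiplexSimSpec(
        "tissues", n_tissues, (LayerSimSpec("tissues", kind="empty"),), prefix="t"
    )
    bipartites = (
        BipartiteSimSpec("genes", "metabolites", 0.02),
        BipartiteSimSpec("genes", "reactions", 0.02),
        BipartiteSimSpec("metabolites", "reactions", 0.02, directed=True),
        BipartiteSimSpec("reactions", "metabolites", 0.02, directed=True),
        BipartiteSimSpec("genes", "tissues", 0.05, weighted=True),
        BipartiteSimSpec("genes", "phenotypes", 0.02),
        BipartiteSimSpec("metabolites", "tissues", 0.03),
        BipartiteSimSpec("phenotypes", "tissues", 0.03),
    )
    return NetworkSimSpec(
        multiplexes=(genes, metabolites, reactions, phenotypes, tissues),
        bipartites=bipartites,
        hubs=hubs,
        rng_seed=rng_seed,
    )
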