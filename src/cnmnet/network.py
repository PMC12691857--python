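"""Multiplex-heterogeneous multilayer network model.

A :class:`MultilayerNetwork` is a collection of multiplexes (each a stack of
layers over one node type: genes, metabolites, reactions, phenotype terms,
tissues) joined by bipartite edge sets linking pairs of multiplexes.  This is
the object the random walk with restart (:mod:`cnmnet.rwr`) operates on.

Edge lists are plain 2- or 3-column TSV files; a manifest (YAML) describes how
layers and bipartites assemble into the full network.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "NodeRef",
    "Layer",
    "Multiplex",
    "Bipartite",
    "MultilayerNetwork",
    "LayerParseError",
    "ValidationError",
    "ConfigError",
    "read_layer_edges",
    "write_layer_edges",
    "assemble_network",
    "load_manifest",
    "write_network",
    "density",
    "summarize",
    "remove_nodes",
    "drop_layers",
]


class LayerParseError(ValueError):
    """Malformed edge-list file."""


class ValidationError(ValueError):
    """Network object violating a structural invariant."""


class ConfigError(ValueError):
    """Invalid manifest or configuration."""


class NodeRef(NamedTuple):
    """A node addressed by its multiplex and identifier."""

    multiplex: str
    node: str


def _canonicalize_edges(
    edges: Iterable[tuple[str, str, float]], directed: bool
) -> tuple[list[tuple[str, str, float]], int, int]:
    """Canonicalize an edge multiset.

    Undirected edges are stored with lexically sorted endpoints; duplicates
    collapse keeping the maximum weight; self-loops are dropped.  Returns the
    canonical edge list plus the number of collapsed duplicates and dropped
    self-loops.
    """
    best: dict[tuple[str, str], float] = {}
    n_dup = 0
    n_loops = 0
    for a, b, w in edges:
        a = a.strip()
        b = b.strip()
        if not a or not b:
            raise ValidationError("empty node identifier in edge list")
        if w <= 0:
            raise ValidationError(f"non-positive edge weight {w!r} on ({a}, {b})")
        if a == b:
            n_loops += 1
            continue
        key = (a, b) if directed or a <= b else (b, a)
        if key in best:
            n_dup += 1
            best[key] = max(best[key], w)
        else:
            best[key] = w
    return [(a, b, w) for (a, b), w in best.items()], n_dup, n_loops


@dataclass(frozen=True)
class Layer:
    """One edge set over a multiplex's node type.

    Unweighted layers carry weight 1.0 on every edge.  Edges are canonical:
    no self-loops, no duplicate pairs, and lexically ordered endpoints when
    undirected.
    """

    name: str
    directed: bool
    weighted: bool
    edges: tuple[tuple[str, str, float], ...]

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple[str, str, float]],
        *,
        directed: bool = False,
        weighted: bool = False,
    ) -> "Layer":
        canon, n_dup, n_loops = _canonicalize_edges(edges, directed)
        if not weighted and any(w != 1.0 for _, _, w in canon):
            raise ValidationError(f"layer {name!r} declared unweighted but carries non-unit weights")
        if n_dup:
            logger.info("layer %s: collapsed %d duplicate edges (kept max weight)", name, n_dup)
        if n_loops:
            logger.info("layer %s: dropped %d self-loops", name, n_loops)
        canon.sort()
        return cls(name, directed, weighted, tuple(canon))

    @property
    def node_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class Multiplex:
    """One or more layers over a single node type.

    ``extra_nodes`` holds members of the node universe that appear in no layer
    edge (isolated nodes, e.g. tissue nodes or bipartite-only endpoints).
    """

    name: str
    layers: tuple[Layer, ...]
    extra_nodes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError(f"multiplex {self.name!r} has no layers")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValidationError(f"multiplex {self.name!r} has duplicate layer names")

    @property
    def node_universe(self) -> frozenset[str]:
        out: set[str] = set(self.extra_nodes)
        for layer in self.layers:
            out |= layer.node_ids
        return frozenset(out)

    def get_layer(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(f"no layer {name!r} in multiplex {self.name!r}")


@dataclass(frozen=True)
class Bipartite:
    """Edges linking two multiplexes (source side to target side)."""

    name: str
    source_multiplex: str
    target_multiplex: str
    directed: bool
    weighted: bool
    edges: tuple[tuple[str, str, float], ...]

    @classmethod
    def from_edges(
        cls,
        name: str,
        source_multiplex: str,
        target_multiplex: str,
        edges: Iterable[tuple[str, str, float]],
        *,
        directed: bool = False,
        weighted: bool = False,
    ) -> "Bipartite":
        # Sides are distinct node spaces: never reorder endpoints, only dedupe.
        canon, n_dup, _ = _canonicalize_edges(edges, directed=True)
        if not weighted and any(w != 1.0 for _, _, w in canon):
            raise ValidationError(
                f"bipartite {name!r} declared unweighted but carries non-unit weights"
            )
        if n_dup:
            logger.info("bipartite %s: collapsed %d duplicate edges", name, n_dup)
        canon.sort()
        return cls(name, source_multiplex, target_multiplex, directed, weighted, tuple(canon))

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class MultilayerNetwork:
    """The full multiplex-heterogeneous network."""

    multiplexes: tuple[Multiplex, ...]
    bipartites: tuple[Bipartite, ...] = ()

    def __post_init__(self) -> None:
        names = [m.name for m in self.multiplexes]
        if len(set(names)) != len(names):
            raise ValidationError("multiplex names are not unique")
        for bip in self.bipartites:
            for end in (bip.source_multiplex, bip.target_multiplex):
                if end not in names:
                    raise ConfigError(
                        f"bipartite {bip.name!r} references unknown multiplex {end!r}"
                    )

    @property
    def multiplex_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.multiplexes)

    def get_multiplex(self, name: str) -> Multiplex:
        for m in self.multiplexes:
            if m.name == name:
                return m
        raise KeyError(f"no multiplex {name!r}")

    def has_node(self, ref: NodeRef) -> bool:
        try:
            return ref.node in self.get_multiplex(ref.multiplex).node_universe
        except KeyError:
            return False


# ---------------------------------------------------------------------------
# Edge-list I/O


def _parse_edge_file(path: Path, weighted: bool) -> list[tuple[str, str, float]]:
    edges: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if weighted:
                if len(parts) != 3:
                    raise LayerParseError(
                        f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                    )
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise LayerParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            else:
                if len(parts) != 2:
                    raise LayerParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                    )
                w = 1.0
            if w <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive weight {w}")
            edges.append((parts[0], parts[1], w))
    return edges


def read_layer_edges(
    path: str | Path,
    *,
    directed: bool = False,
    weighted: bool = False,
    name: str | None = None,
) -> Layer:
    """Read a 2- or 3-column TSV edge list into a canonical :class:`Layer`.

    Lines starting with ``#`` are ignored.  A weight column is required iff
    ``weighted``; unweighted edges get weight 1.0.
    """
    path = Path(path)
    edges = _parse_edge_file(path, weighted)
    return Layer.from_edges(name or path.stem, edges, directed=directed, weighted=weighted)


def read_bipartite_edges(
    path: str | Path,
    source_multiplex: str,
    target_multiplex: str,
    *,
    directed: bool = False,
    weighted: bool = False,
    name: str | None = None,
) -> Bipartite:
    """Read a bipartite edge list (source id, target id[, weight])."""
    path = Path(path)
    edges = _parse_edge_file(path, weighted)
    return Bipartite.from_edges(
        name or path.stem,
        source_multiplex,
        target_multiplex,
        edges,
        directed=directed,
        weighted=weighted,
    )


def write_layer_edges(layer: Layer | Bipartite, path: str | Path) -> None:
    """Write edges back to TSV (3 columns if weighted, else 2)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, w in layer.edges:
            if layer.weighted:
                fh.write(f"{a}\t{b}\t{w!r}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Manifest assembly


def load_manifest(manifest: str | Path | Mapping) -> dict:
    """Load a manifest mapping from a YAML path, or pass a mapping through."""
    if isinstance(manifest, (str, Path)):
        path = Path(manifest)
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"manifest {path} is not a mapping")
        data.setdefault("paths", {})
        data["paths"].setdefault("base", str(path.parent))
        return data
    return dict(manifest)


def assemble_network(manifest: str | Path | Mapping) -> MultilayerNetwork:
    """Assemble a validated :class:`MultilayerNetwork` from a manifest.

    Manifest schema (YAML)::

        paths: {base: <dir>}          # optional; defaults to the manifest dir
        multiplexes:
          genes:
            layers:
              - {name: ppi, path: genes/ppi.tsv, directed: false, weighted: false}
        bipartites:
          - {name: gene-metab, source: genes, target: metabolites,
             path: bip/gm.tsv, directed: false, weighted: false}
        rwr: {restart: 0.7}           # consumed by cnmnet.rwr, not here

    Bipartite endpoints missing from their multiplex's layers are added to the
    node universe as isolated nodes (with a logged warning).
    """
    cfg = load_manifest(manifest)
    base = Path(cfg.get("paths", {}).get("base", "."))
    if "multiplexes" not in cfg or not cfg["multiplexes"]:
        raise ConfigError("manifest has no 'multiplexes' block")

    multiplexes: list[Multiplex] = []
    for mp_name, mp_cfg in cfg["multiplexes"].items():
        layer_cfgs = mp_cfg.get("layers") or []
        if not layer_cfgs:
            raise ConfigError(f"multiplex {mp_name!r} lists no layers")
        layers = tuple(
            read_layer_edges(
                base / lc["path"],
                directed=bool(lc.get("directed", False)),
                weighted=bool(lc.get("weighted", False)),
                name=lc.get("name"),
            )
            for lc in layer_cfgs
        )
        extra = frozenset(mp_cfg.get("nodes") or ())
        multiplexes.append(Multiplex(mp_name, layers, extra))

    mp_names = {m.name for m in multiplexes}
    bipartites: list[Bipartite] = []
    for bc in cfg.get("bipartites") or []:
        src, tgt = bc["source"], bc["target"]
        if src not in mp_names or tgt not in mp_names:
            raise ConfigError(
                f"bipartite {bc.get('name', bc['path'])!r} references unknown multiplex "
                f"{src if src not in mp_names else tgt!r}"
            )
        bipartites.append(
            read_bipartite_edges(
                base / bc["path"],
                src,
                tgt,
                directed=bool(bc.get("directed", False)),
                weighted=bool(bc.get("weighted", False)),
                name=bc.get("name"),
            )
        )

    # Promote bipartite-only endpoints to isolated universe members.
    by_name = {m.name: m for m in multiplexes}
    for bip in bipartites:
        for side, mp_name in (
            (0, bip.source_multiplex),
            (1, bip.target_multiplex),
        ):
            mp = by_name[mp_name]
            missing = {e[side] for e in bip.edges} - mp.node_universe
            if missing:
                logger.warning(
                    "bipartite %s: %d endpoint(s) absent from multiplex %s layers; "
                    "added as isolated nodes",
                    bip.name,
                    len(missing),
                    mp_name,
                )
                by_name[mp_name] = replace(mp, extra_nodes=mp.extra_nodes | missing)

    return MultilayerNetwork(
        tuple(by_name[m.name] for m in multiplexes), tuple(bipartites)
    )


def write_network(
    net: MultilayerNetwork, outdir: str | Path, rwr_params: Mapping | None = None
) -> Path:
    """Write every layer and bipartite as TSV plus a ``manifest.yaml`` that
    :func:`assemble_network` reads back.  Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"multiplexes": {}, "bipartites": []}
    for mp in net.multiplexes:
        layer_entries = []
        for layer in mp.layers:
            rel = f"{mp.name}/{layer.name}.tsv"
            write_layer_edges(layer, outdir / rel)
            layer_entries.append(
                {"name": layer.name, "path": rel,
                 "directed": layer.directed, "weighted": layer.weighted}
            )
        entry: dict = {"layers": layer_entries}
        covered: set[str] = set()
        for layer in mp.layers:
            covered |= layer.node_ids
        isolated = sorted(mp.node_universe - covered)
        if isolated:
            entry["nodes"] = isolated
        manifest["multiplexes"][mp.name] = entry
    for bip in net.bipartites:
        rel = f"bipartites/{bip.name}.tsv"
        write_layer_edges(bip, outdir / rel)
        manifest["bipartites"].append(
            {"name": bip.name, "source": bip.source_multiplex,
             "target": bip.target_multiplex, "path": rel,
             "directed": bip.directed, "weighted": bip.weighted}
        )
    if rwr_params:
        manifest["rwr"] = dict(rwr_params)
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


# ---------------------------------------------------------------------------
# Summaries


def density(n_nodes: int, n_edges: int) -> float:
    """Graph density: actual edges over potential edges, m / (n(n-1)/2).

    The same convention is applied to directed and undirected edge sets, which
    is how the published summary tables this mirrors are computed.
    """
    if n_nodes < 2:
        return float("nan")
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


def summarize(net: MultilayerNetwork) -> pd.DataFrame:
    """One row per layer and per bipartite: node/edge counts, density, flags.

    Densities are rounded to 3 decimals for reporting.  Bipartite densities
    are left blank (NaN): the printed node count is the sum of both sides and
    the side split is unknown, so no defensible denominator exists.
    """
    rows = []
    for mp in net.multiplexes:
        for layer in mp.layers:
            n = len(layer.node_ids) if layer.n_edges else len(mp.node_universe)
            rows.append(
                {
                    "network": mp.name,
                    "layer": layer.name,
                    "n_nodes": n,
                    "n_edges": layer.n_edges,
                    "density": round(density(n, layer.n_edges), 3) if n >= 2 else float("nan"),
                    "weighted": layer.weighted,
                    "directed": layer.directed,
                }
            )
    for bip in net.bipartites:
        src_nodes = {e[0] for e in bip.edges}
        tgt_nodes = {e[1] for e in bip.edges}
        rows.append(
            {
                "network": f"{bip.source_multiplex}—{bip.target_multiplex}",
                "layer": bip.name,
                "n_nodes": len(src_nodes) + len(tgt_nodes),
                "n_edges": bip.n_edges,
                "density": float("nan"),
                "weighted": bip.weighted,
                "directed": bip.directed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surgery


def remove_nodes(net: MultilayerNetwork, targets: Iterable[NodeRef]) -> MultilayerNetwork:
    """Delete nodes and all their incident edges from every layer and bipartite.

    Unknown targets are logged and ignored (removal is idempotent).  Nodes
    left isolated by the deletion remain members of their node universe.
    """
    by_mp: dict[str, set[str]] = {}
    for ref in targets:
        ref = NodeRef(*ref)
        if not net.has_node(ref):
            logger.warning("remove_nodes: %s not present; skipped", ref)
            continue
        by_mp.setdefault(ref.multiplex, set()).add(ref.node)

    new_mps = []
    for mp in net.multiplexes:
        drop = by_mp.get(mp.name, set())
        if not drop:
            new_mps.append(mp)
            continue
        keep_universe = mp.node_universe - drop
        new_layers = tuple(
            Layer(
                l.name,
                l.directed,
                l.weighted,
                tuple(e for e in l.edges if e[0] not in drop and e[1] not in drop),
            )
            for l in mp.layers
        )
        covered: set[str] = set()
        for l in new_layers:
            covered |= l.node_ids
        new_mps.append(Multiplex(mp.name, new_layers, frozenset(keep_universe - covered)))

    new_bips = []
    for bip in net.bipartites:
        src_drop = by_mp.get(bip.source_multiplex, set())
        tgt_drop = by_mp.get(bip.target_multiplex, set())
        new_bips.append(
            replace(
                bip,
                edges=tuple(
                    e for e in bip.edges if e[0] not in src_drop and e[1] not in tgt_drop
                ),
            )
        )
    return MultilayerNetwork(tuple(new_mps), tuple(new_bips))


def drop_layers(
    net: MultilayerNetwork,
    layer_refs: Iterable[str | tuple[str, str]],
    *,
    keep_nodes: bool = True,
) -> MultilayerNetwork:
    """Remove whole layers, e.g. the experimental co-expression layers.

    ``layer_refs`` items are ``(multiplex, layer)`` pairs or ``"multiplex:layer"``
    strings.  With ``keep_nodes`` the original node universe is preserved (nodes
    only covered by a dropped layer become isolated).  A multiplex may not be
    left with zero layers.
    """
    parsed: set[tuple[str, str]] = set()
    for ref in layer_refs:
        if isinstance(ref, str):
            if ":" not in ref:
                raise ConfigError(f"layer reference {ref!r} is not 'multiplex:layer'")
            mp_name, layer_name = ref.split(":", 1)
        else:
            mp_name, layer_name = ref
        parsed.add((mp_name, layer_name))

    known = {(mp.name, l.name) for mp in net.multiplexes for l in mp.layers}
    unknown = parsed - known
    if unknown:
        raise ConfigError(f"unknown layer(s): {sorted(unknown)}")

    new_mps = []
    for mp in net.multiplexes:
        kept = tuple(l for l in mp.layers if (mp.name, l.name) not in parsed)
        if kept is mp.layers or len(kept) == len(mp.layers):
            new_mps.append(mp)
            continue
        if not kept:
            raise ConfigError(f"dropping leaves multiplex {mp.name!r} with zero layers")
        extra = mp.extra_nodes
        if keep_nodes:
            covered: set[str] = set()
            for l in kept:
                covered |= l.node_ids
            extra = frozenset(mp.node_universe - covered)
        new_mps.append(Multiplex(mp.name, kept, extra))
    return MultilayerNetwork(tuple(new_mps), net.bipartites)
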