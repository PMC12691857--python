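"""Config-driven orchestration of the full analysis.

A run config (YAML or dict) lists stages in dependency order; each stage
writes its outputs under ``<output_dir>/<stage>/`` before the next starts,
and the run manifest (JSON) records every parameter — including defaulted
ones — plus output checksums and wall times, so a run can be reproduced
bit-identically from the manifest alone.

Stages: ``simulate_expression`` -> ``coexpression`` -> ``simulate_network``
-> ``summarize`` -> ``hubscan`` -> ``explore``.  Later stages read the
earlier stages' outputs from the same run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable, Mapping

import pandas as pd
import yaml

from . import coexpression as cx
from . import explore as xp
from . import hubs as hb
from . import simulate as sim
from .network import (
    ConfigError,
    MultilayerNetwork,
    NodeRef,
    assemble_network,
    remove_nodes,
    summarize,
    write_network,
)
from .rwr import RWRConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_run_config", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_dir(stage_dir: Path) -> dict[str, str]:
    return {
        str(p.relative_to(stage_dir)): _sha256(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file()
    }


def load_run_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if "output_dir" not in cfg:
        raise ConfigError("run config needs 'output_dir'")
    cfg.setdefault("rng_seed", 0)
    cfg.setdefault("stages", [])
    return cfg


# ---------------------------------------------------------------------------
# Stage implementations.  Each takes (outdir, params, seed, ctx) and returns
# the fully resolved parameters it ran with (defaults included).


def _stage_simulate_expression(outdir: Path, params: dict, seed: int, ctx: dict) -> dict:
    spec = sim.ExpressionSimSpec(rng_seed=params.get("rng_seed", seed))
    if "n_per_group" in params:
        spec = dataclasses.replace(spec, n_per_group=dict(params["n_per_group"]))
    data = sim.simulate_expression_with_traits(spec)
    data.counts.to_csv(outdir / "counts.tsv", sep="\t")
    data.traits.to_csv(outdir / "traits.tsv", sep="\t")
    data.truth.to_csv(outdir / "truth.tsv", sep="\t")
    data.factors.to_csv(outdir / "factors.tsv", sep="\t")
    ctx["expression"] = data
    return {"rng_seed": spec.rng_seed, "n_per_group": spec.n_per_group,
            "n_modules": len(spec.modules), "n_background": spec.n_background}


def _stage_coexpression(outdir: Path, params: dict, seed: int, ctx: dict) -> dict:
    if "expression" in ctx:
        counts, traits = ctx["expression"].counts, ctx["expression"].traits
    else:
        counts = pd.read_csv(params["counts"], sep="\t", index_col=0)
        traits = pd.read_csv(params["traits"], sep="\t", index_col=0)
    model = cx.WGCNA(
        counts,
        traits,
        power=params.get("power", 12),
        min_module_size=params.get("min_module_size", 30),
        merge_threshold=params.get("merge_threshold", 0.25),
        alpha=params.get("alpha", 0.05),
    )
    res = model.fit()
    res.to_dir(outdir)
    (outdir / "summary.txt").write_text(res.summary() + "\n", encoding="utf-8")
    layer = res.export_layer(params.get("export_threshold", 0.15), name="coexpression")
    from .network import write_layer_edges

    write_layer_edges(layer, outdir / "coexpression_layer.tsv")
    ctx["wgcna"] = res
    return {"power": model.power, "min_module_size": model.min_module_size,
            "merge_threshold": model.merge_threshold, "alpha": model.alpha,
            "export_threshold": params.get("export_threshold", 0.15)}


def _stage_simulate_network(outdir: Path, params: dict, seed: int, ctx: dict) -> dict:
    hub_fraction = params.get("hub_fraction", 0.5)
    hubs = (sim.HubSpec("genes", hub_fraction),) if params.get("plant_hub", True) else ()
    spec = sim.table_shaped_network_spec(
        rng_seed=params.get("rng_seed", seed),
        n_genes=params.get("n_genes", 120),
        n_metabolites=params.get("n_metabolites", 60),
        n_reactions=params.get("n_reactions", 80),
        n_phenotypes=params.get("n_phenotypes", 60),
        n_tissues=params.get("n_tissues", 10),
        hubs=hubs,
    )
    net, hub_refs = sim.simulate_multilayer(spec)
    write_network(net, outdir / "network", rwr_params={"restart": 0.7})
    pd.DataFrame(hub_refs, columns=["multiplex", "node"]).to_csv(
        outdir / "planted_hubs.tsv", sep="\t", index=False
    )
    ctx["network"] = net
    ctx["planted_hubs"] = hub_refs
    return {"rng_seed": spec.rng_seed, "n_genes": params.get("n_genes", 120),
            "hub_fraction": hub_fraction, "plant_hub": params.get("plant_hub", True)}


def _require_network(ctx: dict, params: dict) -> MultilayerNetwork:
    if "network" in ctx:
        return ctx["network"]
    if "manifest" in params:
        return assemble_network(params["manifest"])
    raise StageError("no network available: run simulate_network first or pass 'manifest'")


def _stage_summarize(outdir: Path, params: dict, seed: int, ctx: dict) -> dict:
    net = _require_network(ctx, params)
    summarize(net).to_csv(outdir / "network_summary.tsv", sep="\t", index=False)
    return {}


def _stage_hubscan(outdir: Path, params: dict, seed: int, ctx: dict) -> dict:
    net = _require_network(ctx, params)
    pool_mp = params.get("pool_multiplex", "genes")
    pool = tuple(
        NodeRef(pool_mp, n) for n in sorted(net.get_multiplex(pool_mp).node_universe)
    )
    config = hb.HubScanConfig(
        seed_pool=pool,
        n_iterations=params.get("n_iterations", 200),
        top_k_levels=tuple(params.get("top_k_levels", (10, 50, 100))),
        hub_top_k=params.get("hub_top_k", 50),
        hub_fraction=params.get("hub_fraction", 0.05),
        rng_seed=params.get("rng_seed", seed),
        hub_multiplexes=tuple(params.get("hub_multiplexes", ("genes", "metabolites"))),
    )
    rwr_config = RWRConfig(restart=params.get("restart", 0.7))
    dropped = params.get("drop_layers")
    if dropped:
        comp = hb.full_vs_subset_scan(net, list(dropped), config, rwr_config)
        report = comp.full
        comp.paired.to_csv(outdir / "full_vs_subset.tsv", sep="\t", index=False)
        comp.correlations.to_csv(outdir / "full_vs_subset_correlation.tsv", sep="\t",
                                 index=False)
    else:
        report = hb.random_seed_scan(net, config, rwr_config)
    report.counts.to_csv(outdir / "occurrences.tsv", sep="\t", index=False)
    hub_set = hb.detect_hubs(report, config)
    pd.DataFrame(sorted(hub_set), columns=["multiplex", "node"]).to_csv(
        outdir / "hubs.tsv", sep="\t", index=False
    )
    pruned = remove_nodes(net, hub_set)
    write_network(pruned, outdir / "pruned_network", rwr_params={"restart": 0.7})
    ctx["pruned_network"] = pruned
    ctx["hubs"] = hub_set
    return {"n_iterations": config.n_iterations, "rng_seed": config.rng_seed,
            "top_k_levels": list(config.top_k_levels), "hub_top_k": config.hub_top_k,
            "hub_fraction": config.hub_fraction, "restart": rwr_config.restart,
            "drop_layers": list(dropped) if dropped else [],
            "n_hubs_detected": len(hub_set)}


def _stage_explore(outdir: Path, params: dict, seed: int, ctx: dict) -> dict:
    net = ctx.get("pruned_network") or _require_network(ctx, params)
    gene_mp = params.get("gene_multiplex", "genes")
    pheno_mp = params.get("phenotype_multiplex", "phenotypes")
    gene_seed = params.get("gene_seed") or sorted(net.get_multiplex(gene_mp).node_universe)[0]
    pheno_seeds = params.get("phenotype_seeds")
    if not pheno_seeds:
        pheno_seeds = sorted(net.get_multiplex(pheno_mp).node_universe)[:3]
    rwr_config = RWRConfig(restart=params.get("restart", 0.7))
    from .rwr import RandomWalkRestart

    solver = RandomWalkRestart(net, rwr_config)
    results = []
    for ph in pheno_seeds:
        res = xp.joint_seed_query(
            net,
            gene_seed=NodeRef(gene_mp, gene_seed),
            phenotype_seed=NodeRef(pheno_mp, ph),
            top_n=params.get("top_n", 20),
            gene_multiplex=gene_mp,
            phenotype_multiplex=pheno_mp,
            metabolite_multiplex=params.get("metabolite_multiplex", "metabolites"),
            solver=solver,
        )
        res.genes.to_csv(outdir / f"query_{ph}_genes.tsv", sep="\t")
        res.metabolites.to_csv(outdir / f"query_{ph}_metabolites.tsv", sep="\t")
        results.append(res)
    if len(results) >= 2:
        xp.overlap_table(results).table.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    return {"gene_seed": gene_seed, "phenotype_seeds": list(pheno_seeds),
            "top_n": params.get("top_n", 20), "restart": rwr_config.restart}


_STAGES: dict[str, Callable[[Path, dict, int, dict], dict]] = {
    "simulate_expression": _stage_simulate_expression,
    "coexpression": _stage_coexpression,
    "simulate_network": _stage_simulate_network,
    "summarize": _stage_summarize,
    "hubscan": _stage_hubscan,
    "explore": _stage_explore,
}


def run_pipeline(config: str | Path | Mapping) -> dict:
    """Execute the configured stages in order and write a run manifest.

    Returns the manifest dict (also written to ``<output_dir>/run_manifest.json``):
    per stage, the resolved parameters, the output files with sha256
    checksums, and the wall time.  A stage failure raises :class:`StageError`
    naming the stage; outputs of completed stages are retained.
    """
    cfg = load_run_config(config)
    outroot = Path(cfg["output_dir"])
    outroot.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["rng_seed"])
    ctx: dict[str, Any] = {}
    manifest: dict[str, Any] = {"rng_seed": seed, "stages": []}
    for entry in cfg["stages"]:
        if isinstance(entry, str):
            stage_name, params = entry, {}
        else:
            stage_name = entry["stage"]
            params = dict(entry.get("params") or {})
        if stage_name not in _STAGES:
            raise ConfigError(f"unknown stage {stage_name!r}")
        stage_dir = outroot / stage_name
        stage_dir.mkdir(parents=True, exist_ok=True)
        logger.info("stage %s starting", stage_name)
        t0 = time.monotonic()
        try:
            resolved = _STAGES[stage_name](stage_dir, params, seed, ctx)
        except Exception as exc:  # noqa: BLE001 - stage name must reach the user
            raise StageError(f"stage {stage_name!r} failed: {exc}") from exc
        elapsed = time.monotonic() - t0
        manifest["stages"].append(
            {
                "stage": stage_name,
                "parameters": resolved,
                "outputs": _checksum_dir(stage_dir),
                "wall_time_s": round(elapsed, 3),
            }
        )
        logger.info("stage %s done in %.1fs", stage_name, elapsed)
    with open(outroot / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
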