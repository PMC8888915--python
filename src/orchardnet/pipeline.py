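"""One-command orchestration of the full analysis on any input set.

Stage order mirrors the analysis: stratify -> rarefy to even depth ->
per-sample diversity -> per-stratum co-occurrence networks (topology +
keystones) -> indicator analysis -> guild read counts. Every run writes a
machine-readable manifest (parameters, seeds, package version, input and
output checksums); rerunning the same configuration and seed reproduces
byte-identical numeric outputs. Incomplete runs leave the manifest marked
``complete: false``.

Stratification presets encode the two model families of the study design:
``management`` keeps the four orchard strata (IPM/organic x crop/drive
row, grassland excluded) and ``land_use`` keeps the two drive-row strata
plus grassland (crop rows omitted for a conservative orchard-vs-grassland
comparison). ``all`` keeps all five strata (the network figure layout).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from . import cooccurrence, diversity, guilds as guilds_mod, indicator, io, rarefaction
from .containers import KEYSTONE_PRESETS

STRATIFY_MODES = ("all", "management", "land_use")

DEFAULTS = {
    "depth": 10_000,
    "seed": 0,
    "stratify": "all",
    "rho_min": 0.6,
    "alpha": 0.05,
    "keystone_preset": "fungi",
    "n_perm": 999,
    "min_prevalence": 0,
    "guild_select": None,  # None -> all annotated guilds
    "drop_shallow": False,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg


def select_samples(metadata, mode: str) -> list[str]:
    """Sample ids retained under a stratification mode."""
    if mode not in STRATIFY_MODES:
        raise ValueError(f"unknown stratify mode {mode!r}; choose from {STRATIFY_MODES}")
    df = metadata.table
    if mode == "management":
        keep = df["land_use"] != "grassland"
    elif mode == "land_use":
        keep = df["location"] != "crop_row"
    else:
        keep = df["sample_id"].notna()
    return list(df.loc[keep, "sample_id"])


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run every stage; returns the manifest (also written to out_dir)."""
    if not isinstance(config, dict):
        config = load_config(config)
    params = {**DEFAULTS, **{k: v for k, v in config.items() if k not in ("inputs", "out_dir")}}
    inputs = config.get("inputs", {})
    out_dir = Path(out_dir or config.get("out_dir", "pipeline_out"))

    # fail before any computation if an input is missing
    required = ["counts", "metadata"]
    for key in required:
        if key not in inputs:
            raise FileNotFoundError(f"pipeline config missing required input {key!r}")
    for key, path in inputs.items():
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input {key!r} not found: {path}")
    if params["keystone_preset"] not in KEYSTONE_PRESETS:
        raise ValueError(f"unknown keystone preset {params['keystone_preset']!r}")

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "networks").mkdir(exist_ok=True)
    manifest: dict = {
        "complete": False,
        "package_version": __version__,
        "parameters": params,
        "inputs": {k: str(v) for k, v in inputs.items() if v is not None},
        "input_checksums": {
            k: io.sha256_of(v) for k, v in inputs.items() if v is not None
        },
        "outputs": {},
        "log": [],
    }

    def log(msg: str) -> None:
        manifest["log"].append(msg)

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": io.sha256_of(path)}

    _write_manifest(manifest, out_dir)  # partial marker until the run finishes

    counts = io.read_count_table(inputs["counts"])
    metadata = io.read_metadata(inputs["metadata"])
    tree = io.read_newick(inputs["tree"]) if inputs.get("tree") else None
    guild_table = io.read_guild_table(inputs["guilds"]) if inputs.get("guilds") else None
    log(f"loaded {counts.n_taxa} taxa x {counts.n_samples} samples")

    keep = [s for s in select_samples(metadata, params["stratify"]) if s in set(counts.sample_ids)]
    counts = counts.select_samples(keep)
    metadata = metadata.subset(keep)
    log(f"stratify={params['stratify']}: {len(keep)} samples retained")

    rarefied = rarefaction.rarefy_counts(
        counts, int(params["depth"]), int(params["seed"]),
        drop_shallow=bool(params["drop_shallow"]),
    )
    if rarefied.n_samples < counts.n_samples:
        metadata = metadata.subset(rarefied.sample_ids)
    log(f"rarefied to depth {params['depth']}: {rarefied.n_samples} samples")
    io.write_count_table(rarefied, out_dir / "rarefied_counts.tsv")
    emit("rarefied_counts", out_dir / "rarefied_counts.tsv")

    div = diversity.diversity_table(rarefied, tree=tree)
    div.to_csv(out_dir / "diversity.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
    emit("diversity", out_dir / "diversity.tsv")
    log(f"diversity table: {len(div)} samples")

    nets = cooccurrence.per_stratum_networks(
        rarefied, metadata,
        rho_min=float(params["rho_min"]), alpha=float(params["alpha"]),
        min_prevalence=int(params["min_prevalence"]),
    )
    criteria = KEYSTONE_PRESETS[params["keystone_preset"]]
    topo_rows, keystone_rows = [], []
    for stratum, net in sorted(nets.items()):
        metrics = cooccurrence.node_metrics(net)
        keystones = cooccurrence.identify_keystones(metrics, criteria)
        cooccurrence.annotate_graph(net, criteria)
        topo = cooccurrence.topology_summary(net, modularity_seed=int(params["seed"]))
        topo_rows.append({"stratum": stratum, **topo.to_dict()})
        keystone_rows += [{"stratum": stratum, "taxon_id": t} for t in keystones]
        safe = stratum.replace("/", "_")
        io.write_network(net, out_dir / "networks" / f"{safe}.graphml", "graphml")
        io.write_network(net, out_dir / "networks" / f"{safe}_edges.tsv", "edge_list_tsv")
        emit(f"network_{safe}", out_dir / "networks" / f"{safe}.graphml")
        emit(f"edges_{safe}", out_dir / "networks" / f"{safe}_edges.tsv")
        log(f"network {stratum}: {net.n_nodes} nodes, {net.n_edges} edges, "
            f"{len(keystones)} keystones")
    import pandas as pd

    pd.DataFrame(topo_rows).to_csv(
        out_dir / "topology.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
    )
    emit("topology", out_dir / "topology.tsv")
    pd.DataFrame(keystone_rows, columns=["stratum", "taxon_id"]).to_csv(
        out_dir / "keystones.tsv", sep="\t", index=False
    )
    emit("keystones", out_dir / "keystones.tsv")

    ind = indicator.indicator_analysis(
        rarefied, metadata, n_perm=int(params["n_perm"]), seed=int(params["seed"])
    )
    ind.to_csv(out_dir / "indicators.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
    emit("indicators", out_dir / "indicators.tsv")
    bip, summary = indicator.association_network(ind, alpha=float(params["alpha"]))
    import networkx as nx

    nx.write_graphml(bip, str(out_dir / "association_network.graphml"))
    emit("association_network", out_dir / "association_network.graphml")
    log(f"indicator analysis: {summary['n_significant']} significant taxa, "
        f"specialist fraction {summary['specialist_fraction']}")

    if guild_table is not None:
        names = params["guild_select"] or guild_table.known_guilds()
        gtab = guilds_mod.guild_read_counts(rarefied, guild_table, list(names))
        gtab["unassigned"] = guilds_mod.unassigned_read_counts(rarefied, guild_table)
        gtab.to_csv(out_dir / "guild_counts.tsv", sep="\t")
        emit("guild_counts", out_dir / "guild_counts.tsv")
        log(f"guild counts for {len(names)} guilds")

    manifest["complete"] = True
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
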