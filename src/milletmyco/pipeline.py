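"""End-to-end orchestration: simulate-or-load -> validate -> rarefy ->
alpha/beta diversity -> guilds -> core mycobiome -> per-plant-type
co-occurrence networks -> network comparison.

One global seed expands into per-stage child streams, every output file is
hashed into a JSON manifest, and a rerun with the same config reproduces
identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, guilds, network as netmod, ordination, simulate
from .io import (
    CountTable,
    read_count_table,
    read_guild_db,
    read_metadata,
    read_taxonomy,
    validate_dataset,
    write_count_table,
    write_network,
)

log = logging.getLogger(__name__)

STAGES = [
    "inputs", "validate", "rarefy", "alpha", "beta",
    "guilds", "core", "networks",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; exactly one of (input paths, sim)."""

    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    guild_db_path: str | None = None  # None -> packaged mini lookup
    sim: simulate.SimConfig | None = None
    depth: int = 25_556
    permutations: int = 999
    prevalence: float = 0.75
    r_threshold: float = 0.6
    alpha_network: float = 0.01
    top_fraction: float = 0.02
    nmds_restarts: int = 20
    seed: int = 0
    out_dir: str = "results"
    strict: bool = True

    def validate(self) -> None:
        has_paths = self.counts_path is not None
        if has_paths == (self.sim is not None):
            raise ValueError("exactly one of input paths or a SimConfig must be set")
        if has_paths and self.metadata_path is None:
            raise ValueError("metadata_path required with counts_path")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if not 0 <= self.r_threshold < 1:
            raise ValueError("r_threshold must be in [0, 1)")
        if not 0 < self.alpha_network <= 1:
            raise ValueError("alpha_network must be in (0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _child(seed: int, idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(100 + idx,)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing tidy TSV/GraphML outputs plus
    ``manifest.json`` under ``config.out_dir``; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "sim"
        },
        "sim": dataclasses.asdict(config.sim) if config.sim else None,
        "stages": {},
    }
    if config.sim is not None:
        # JSON-safe
        manifest["sim"]["plots_per_site"] = list(config.sim.plots_per_site)
        manifest["sim"]["depth_range"] = list(config.sim.depth_range)

    def record(stage: str, files: list[Path], **extra):
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            "completed": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **extra,
        }

    stage = "inputs"
    try:
        if config.sim is not None:
            table, metadata, taxonomy, annotations, truth = simulate.generate_dataset(config.sim)
            write_count_table(table, out / "counts.tsv")
            from .io import write_metadata, write_taxonomy

            write_metadata(metadata, out / "metadata.tsv")
            write_taxonomy(taxonomy, out / "taxonomy.tsv")
            truth.to_json(out / "ground_truth.json")
            guild_db = guilds.packaged_guild_db()
            record(stage, [out / "counts.tsv", out / "metadata.tsv",
                           out / "taxonomy.tsv", out / "ground_truth.json"],
                   source="simulated", n_samples=table.shape[1], n_otus=table.shape[0])
        else:
            table = read_count_table(config.counts_path)
            metadata = read_metadata(config.metadata_path)
            taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
            guild_db = (
                read_guild_db(config.guild_db_path)
                if config.guild_db_path
                else guilds.packaged_guild_db()
            )
            annotations = None
            record(stage, [], source="loaded",
                   inputs={p: _sha256(Path(p)) for p in
                           [config.counts_path, config.metadata_path]
                           + ([config.taxonomy_path] if config.taxonomy_path else [])})

        stage = "validate"
        warnings = validate_dataset(table, metadata, taxonomy, strict=config.strict)
        record(stage, [], warnings=warnings)

        stage = "rarefy"
        rt = diversity.rarefy(table, config.depth, _child(config.seed, 0))
        write_count_table(rt, out / "rarefied.tsv")
        metadata_r = metadata.select_samples(rt.sample_ids)
        record(stage, [out / "rarefied.tsv"], depth=config.depth,
               n_retained=rt.shape[1], n_dropped=table.shape[1] - rt.shape[1])

        stage = "alpha"
        alpha = diversity.alpha_table(rt, metadata_r)
        alpha.to_csv(out / "alpha.tsv", sep="\t")
        record(stage, [out / "alpha.tsv"])

        stage = "beta"
        dist = ordination.bray_curtis(rt)
        pd.DataFrame(dist.values, index=dist.sample_ids, columns=dist.sample_ids).to_csv(
            out / "bray_curtis.tsv", sep="\t"
        )
        ord_ = ordination.nmds(dist, n_restarts=config.nmds_restarts, seed=_child(config.seed, 1))
        ord_.scores.assign(stress=ord_.stress).to_csv(out / "nmds_scores.tsv", sep="\t")
        perm = ordination.permanova(
            dist, metadata_r, n_perm=config.permutations, seed=_child(config.seed, 2)
        )
        perm.table.to_csv(out / "permanova.tsv", sep="\t")
        bd = ordination.betadisper(
            dist, metadata_r.frame["plant_type"], n_perm=config.permutations,
            seed=_child(config.seed, 3),
        )
        env = ordination.envfit(
            ord_, metadata_r, n_perm=config.permutations, seed=_child(config.seed, 4)
        )
        env.to_csv(out / "envfit.tsv", sep="\t")
        record(stage, [out / "bray_curtis.tsv", out / "nmds_scores.tsv",
                       out / "permanova.tsv", out / "envfit.tsv"],
               stress=ord_.stress, betadisper_F=bd.F, betadisper_p=bd.p)

        stage = "guilds"
        if annotations is None:
            if taxonomy is None:
                raise ValueError("taxonomy required for guild assignment")
            annotations = guilds.assign_guilds(taxonomy, guild_db)
        annotations.to_csv(out / "guild_annotations.tsv", sep="\t")
        trophic = guilds.group_relative_abundance(rt, annotations, level="trophic_group")
        trophic.to_csv(out / "trophic_abundance.tsv", sep="\t")
        soil_corr = guilds.soil_trophic_correlation(trophic, metadata_r)
        soil_corr.to_csv(out / "soil_trophic_correlation.tsv", sep="\t", index=False)
        record(stage, [out / "guild_annotations.tsv", out / "trophic_abundance.tsv",
                       out / "soil_trophic_correlation.tsv"],
               n_assigned=int((annotations["trophic_group"] != guilds.UNASSIGNED).sum()))

        stage = "core"
        core = netmod.core_mycobiome(rt, config.prevalence)
        pd.DataFrame({"prevalence": core.prevalence}).to_csv(out / "core_set.tsv", sep="\t")
        record(stage, [out / "core_set.tsv"], **core.summary())

        stage = "networks"
        net_files, summaries, metrics_by_pt = [], {}, {}
        hubs_by_pt = {}
        for pt in ("cultivated", "wild"):
            samp = [s for s in rt.sample_ids if metadata_r.frame.loc[s, "plant_type"] == pt]
            sub = rt.select_samples(samp).select_otus(core.otu_ids)
            g = netmod.build_network(
                sub, config.r_threshold, config.alpha_network,
                annotations=annotations, plant_type=pt,
            )
            write_network(g, out / f"network_{pt}.graphml", "graphml")
            write_network(g, out / f"network_{pt}_edges.csv", "edge_csv")
            net_files += [out / f"network_{pt}.graphml", out / f"network_{pt}_edges.csv"]
            if g.number_of_nodes():
                nm = netmod.node_metrics(g)
                nm.to_csv(out / f"node_metrics_{pt}.tsv", sep="\t")
                net_files.append(out / f"node_metrics_{pt}.tsv")
                metrics_by_pt[pt] = nm
                summaries[pt] = netmod.network_metrics(g, seed=config.seed)
                hr = netmod.identify_hubs(nm, config.top_fraction)
                hubs_by_pt[pt] = hr
            else:
                summaries[pt] = {"n_nodes": 0, "n_edges": 0}
                hubs_by_pt[pt] = netmod.HubReport([], float("nan"), float("nan"), 0, [], [])
        pd.DataFrame(summaries).to_csv(out / "network_metrics.tsv", sep="\t")
        hub_payload = {
            pt: {"hubs": hr.hubs, "k": hr.k, "degree_cutoff": hr.degree_cutoff,
                 "betweenness_cutoff": hr.betweenness_cutoff}
            for pt, hr in hubs_by_pt.items()
        }
        hub_payload["shared"] = sorted(
            set(hubs_by_pt["cultivated"].hubs) & set(hubs_by_pt["wild"].hubs)
        )
        with open(out / "hubs.json", "w") as fh:
            json.dump(hub_payload, fh, indent=1)
        net_files += [out / "network_metrics.tsv", out / "hubs.json"]
        if len(metrics_by_pt) == 2:
            cmp = netmod.compare_networks(metrics_by_pt["cultivated"], metrics_by_pt["wild"])
            cmp.to_csv(out / "network_comparison.tsv", sep="\t")
            net_files.append(out / "network_comparison.tsv")
        record(stage, net_files, summaries=summaries, hubs=hub_payload)

    except Exception as exc:  # record partial completion, then re-raise
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
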