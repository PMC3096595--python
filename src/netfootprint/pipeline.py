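"""End-to-end orchestration: classify -> interlogs -> merge -> classes ->
conservation/TRI/expansions -> degree stats -> domain phylogeny.

The pipeline is driven by a :class:`RunConfig` (loadable from YAML/JSON),
executes each stage through the library modules, writes per-species TF lists,
interaction tables and conserved-interaction tables plus a Newick tree, and
records a JSON manifest with input checksums, the seed and per-stage counts.
A stage failure aborts with the stage name after writing a partial manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import conservation, domain_phylogeny, io_formats, network_stats, orthology
from .tf_repertoire import classify_tfs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    species: list[str]
    fasta: dict[str, str]              # species -> path
    domains: dict[str, str]            # species -> InterProScan TSV path
    dbd_catalog: str
    ortholog_tables: dict[str, str]    # "SA-SB" -> sqltable path
    source_edges: list[str]            # edge-list TSV paths
    output_dir: str
    homodimer_mode: str = "full"
    dbd_filter: str = "both"
    required_species: list[str] | None = None
    top_k_domains: int = 10
    tree_method: str = "upgma"
    self_loop_policy: str = "partner_count"
    fit_method: str = "mle"
    min_tail: int = 10
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
        return cls(**obj)

    def validate(self) -> None:
        for sp in self.species:
            for group, mapping in (("fasta", self.fasta), ("domains", self.domains)):
                if sp not in mapping:
                    raise ValueError(f"no {group} path for species {sp}")
        paths = [*self.fasta.values(), *self.domains.values(),
                 self.dbd_catalog, *self.ortholog_tables.values(),
                 *self.source_edges]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "species": list(config.species),
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    all_inputs = {**{f"fasta:{s}": p for s, p in config.fasta.items()},
                  **{f"domains:{s}": p for s, p in config.domains.items()},
                  "dbd_catalog": config.dbd_catalog,
                  **{f"orthologs:{k}": p for k, p in config.ortholog_tables.items()},
                  **{f"source_edges:{i}": p
                     for i, p in enumerate(config.source_edges)}}

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
        raise PipelineError(stage, exc) from exc

    # ---- stage: inputs -----------------------------------------------------
    try:
        config.validate()
        for key, p in sorted(all_inputs.items()):
            manifest["inputs"][key] = _sha256(p)
        catalog = io_formats.read_dbd_catalog(config.dbd_catalog)
        proteins = {sp: io_formats.read_fasta(config.fasta[sp], sp)
                    for sp in config.species}
        annotations = {sp: io_formats.read_interproscan_tsv(config.domains[sp])
                       for sp in config.species}
        ortholog_maps: dict[tuple[str, str], orthology.OrthologMap] = {}
        for key, path in config.ortholog_tables.items():
            omap = io_formats.read_inparanoid_sqltable(path)
            ortholog_maps[omap.species_pair] = omap
        source_edges = []
        for path in config.source_edges:
            source_edges.extend(io_formats.read_source_edges(path))
    except Exception as exc:
        fail("inputs", exc)

    # ---- stage: classify ---------------------------------------------------
    try:
        tf_sets = {sp: classify_tfs(proteins[sp], annotations[sp], catalog)
                   for sp in config.species}
        manifest["stages"]["classify"] = {sp: len(tf_sets[sp])
                                          for sp in config.species}
        for sp in config.species:
            p = outdir / f"tf_list.{sp}.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("protein_id\tdbd_accessions\n")
                for pid in sorted(tf_sets[sp].members):
                    fh.write(f"{pid}\t{','.join(tf_sets[sp].dbd_accessions[pid])}\n")
            manifest["outputs"][f"tf_list:{sp}"] = str(p)
    except Exception as exc:
        fail("classify", exc)

    # ---- stage: interlogs --------------------------------------------------
    try:
        inferred = orthology.infer_interlogs(
            source_edges, ortholog_maps, tf_sets,
            target_species=config.species,
            homodimer_mode=config.homodimer_mode,
            dbd_filter=config.dbd_filter)
        source_nets = orthology.source_networks(source_edges)
        merged, counts = orthology.merge_networks(source_nets, inferred)
        for sp in config.species:
            if sp not in merged:
                merged[sp] = orthology.InteractionNetwork(sp)
        manifest["stages"]["interlogs"] = {
            sp: {k: int(v) for k, v in counts.loc[sp].items()}
            for sp in counts.index
        }
        for sp in config.species:
            p = outdir / f"interactions.{sp}.tsv"
            io_formats.write_edge_list(merged[sp], p, format="tsv")
            manifest["outputs"][f"interactions:{sp}"] = str(p)
    except Exception as exc:
        fail("interlogs", exc)

    # ---- stage: conservation ----------------------------------------------
    try:
        classes = conservation.build_interaction_classes(source_edges, inferred)
        required = config.required_species or list(config.species)
        conserved = conservation.conserved_classes(classes, required)
        tris = conservation.detect_tris(classes, config.species,
                                        ortholog_maps, tf_sets)
        expansions = conservation.detect_expansions(classes)
        manifest["stages"]["conservation"] = {
            "n_classes": len(classes),
            "n_conserved": len(conserved),
            "n_tri": len(tris),
            "n_expansions": int(len(expansions)),
        }
        p = outdir / "classes.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("class_id\tpresence_pattern\t" +
                     "\t".join(f"mult_{sp}" for sp in config.species) + "\n")
            for cls in classes:
                mult = cls.multiplicity
                fh.write(cls.class_id + "\t" +
                         ",".join(sorted(cls.presence_pattern)) + "\t" +
                         "\t".join(str(mult.get(sp, 0))
                                   for sp in config.species) + "\n")
        manifest["outputs"]["classes"] = str(p)
        for sp in config.species:
            p = outdir / f"conserved.{sp}.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("class_id\tprotein_a\tprotein_b\n")
                for cls in conserved:
                    for a, b in sorted(cls.interlogs.get(sp, ())):
                        fh.write(f"{cls.class_id}\t{a}\t{b}\n")
            manifest["outputs"][f"conserved:{sp}"] = str(p)
        p = outdir / "tri.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("class_id\trestricted_to\tmissing_species\tcause\n")
            for rec in tris:
                for sp, cause in rec.causes:
                    fh.write(f"{rec.class_id}\t"
                             f"{','.join(sorted(rec.restricted_to))}\t"
                             f"{sp}\t{cause}\n")
        manifest["outputs"]["tri"] = str(p)
        p = outdir / "expansions.tsv"
        expansions.to_csv(p, sep="\t", index=False)
        manifest["outputs"]["expansions"] = str(p)
    except Exception as exc:
        fail("conservation", exc)

    # ---- stage: stats ------------------------------------------------------
    try:
        stats_out = {}
        for sp in config.species:
            net = merged[sp]
            if len(net) == 0:
                stats_out[sp] = {"nodes": 0, "edges": 0}
                continue
            summary = network_stats.network_summary(net)
            dd = network_stats.degree_distribution(net, config.self_loop_policy)
            entry = {k: v for k, v in summary.items() if k != "species"}
            try:
                fit = network_stats.fit_power_law(
                    dd.values, method=config.fit_method,
                    min_tail=config.min_tail)
                entry["powerlaw_alpha"] = round(fit.alpha, 6)
                entry["powerlaw_xmin"] = fit.xmin
                entry["powerlaw_ks"] = round(fit.ks_statistic, 6)
                entry["powerlaw_ntail"] = fit.n_tail
            except ValueError as exc:
                entry["powerlaw_error"] = str(exc)
            stats_out[sp] = entry
        manifest["stages"]["stats"] = stats_out
    except Exception as exc:
        fail("stats", exc)

    # ---- stage: domain phylogeny -------------------------------------------
    try:
        profiles = [domain_phylogeny.composition_profile(tf_sets[sp],
                                                         annotations[sp])
                    for sp in config.species if len(tf_sets[sp])]
        if len(profiles) >= 2:
            _, union = domain_phylogeny.top_k_domains(profiles,
                                                      config.top_k_domains)
            table = domain_phylogeny.contingency_table(profiles, union)
            fisher = domain_phylogeny.fisher_species_test(
                table, seed=config.seed)
            dist = domain_phylogeny.species_distance_matrix(profiles, union)
            newick = domain_phylogeny.build_domain_tree(dist,
                                                        config.tree_method)
            p = outdir / "domain_tree.nwk"
            p.write_text(newick + "\n", encoding="utf-8")
            manifest["outputs"]["domain_tree"] = str(p)
            p = outdir / "domain_profiles.tsv"
            table.to_csv(p, sep="\t")
            manifest["outputs"]["domain_profiles"] = str(p)
            manifest["stages"]["domain_phylogeny"] = {
                "n_domains_union": len(union),
                "fisher_p": fisher.p_value,
                "fisher_method": fisher.method,
                "n_domain_types": {pr.species_id: pr.n_domain_types
                                   for pr in profiles},
            }
        else:
            manifest["stages"]["domain_phylogeny"] = {
                "skipped": "fewer than 2 non-empty TF sets"}
    except Exception as exc:
        fail("domain_phylogeny", exc)

    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True),
                    encoding="utf-8")
    manifest["outputs"]["manifest"] = str(path)
    return manifest
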