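"""End-to-end orchestration: filter -> annotate -> classify -> (enrich) ->
crossmap -> curate -> crossref, with serialized intermediates and a run
manifest.

Each stage writes its output as TSV/JSON so stages can be re-run
independently from their intermediates.  The combined target table is the
gene-level union of first-pass targets and cross-species additions
(deduplicated by gene name, falling back to accession for unnamed
entries)."""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as sio
from .annotation import filter_eggnog_hits, merge_annotations
from .crossmap import (
    CrossSpeciesConfig,
    SequenceStore,
    apply_curation,
    map_targets_across_species,
    read_curation_table,
)
from .crossref import crossref as run_crossref
from .enrichment import overrepresentation_test
from .filtering import filter_redundant
from .model import EggnogFilterConfig, GOCatalog
from .targets import screen_proteome

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    proteome: str = ""
    mapping: str = ""
    eggnog: Optional[str] = None
    topology: Optional[str] = None
    topology_dialect: str = "gff3_like"
    go_catalog: Optional[str] = None
    eggnog_filter: EggnogFilterConfig = field(default_factory=EggnogFilterConfig)
    enrichment_annotation: Optional[str] = None
    enrichment_alpha: float = 0.05
    crossmap_ref_targets: Optional[str] = None
    crossmap_store: Optional[str] = None
    crossmap_curation: Optional[str] = None
    cross_species: CrossSpeciesConfig = field(default_factory=CrossSpeciesConfig)
    sperm_list: Optional[str] = None
    outdir: str = "surfscreen_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        egg = raw.pop("eggnog_filter", None)
        cs = raw.pop("cross_species", None)
        cfg = cls(**raw)
        if egg:
            cfg.eggnog_filter = EggnogFilterConfig(**egg)
        if cs:
            cfg.cross_species = CrossSpeciesConfig(**cs)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "stages": {}}

    cat = sio.read_go_catalog(cfg.go_catalog) if cfg.go_catalog else GOCatalog()

    # stage: filter
    entries = sio.read_proteome_table(cfg.proteome)
    mapping = sio.read_transcript_mapping(cfg.mapping)
    filtered, audit = filter_redundant(entries, mapping)
    sio.write_proteome_table(filtered, outdir / "filtered.tsv")
    (outdir / "filter_audit.json").write_text(
        json.dumps(
            {
                "input_count": audit.input_count,
                "output_count": audit.output_count,
                "dropped_no_gene": audit.dropped_no_gene,
                "dropped_gene_duplicate": audit.dropped_gene_duplicate,
                "dropped_uniprot_duplicate_transcripts":
                    audit.dropped_uniprot_duplicate_transcripts,
                "warnings": audit.warnings,
            },
            indent=2,
        )
    )
    manifest["stages"]["filter"] = {
        "input": audit.input_count,
        "kept": audit.output_count,
        "dropped": audit.total_dropped,
    }

    # stage: annotate
    egg_rows = sio.read_eggnog_table(cfg.eggnog) if cfg.eggnog else []
    egg_kept = filter_eggnog_hits(egg_rows, cfg.eggnog_filter)
    topo = (
        sio.read_topology(cfg.topology, cfg.topology_dialect) if cfg.topology else []
    )
    annotated = merge_annotations(filtered, egg_kept, topo)
    manifest["stages"]["annotate"] = {
        "eggnog_rows": len(egg_rows),
        "eggnog_kept": len(egg_kept),
        "topology_rows": len(topo),
        "annotated": len(annotated),
    }

    # stage: classify
    calls, summary = screen_proteome(annotated, cat)
    with (outdir / "target_calls.tsv").open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "gene_name", "of_interest", "is_target",
             "triggering_classes", "via_es_tm", "experimental_support"]
        )
        for p, c in zip(annotated, calls):
            writer.writerow(
                [c.accession, p.display_name or "", int(c.of_interest), int(c.is_target),
                 ",".join(sorted(c.triggering_classes)), int(c.via_es_tm),
                 int(c.experimental_support)]
            )
    (outdir / "screen_summary.json").write_text(json.dumps(asdict(summary), indent=2))
    manifest["stages"]["classify"] = {
        "n_interest": summary.n_interest,
        "n_target": summary.n_target,
        "n_target_experimental": summary.n_target_experimental,
    }

    # optional stage: enrichment of the target set against the proteome
    if cfg.enrichment_annotation:
        annotation: dict[str, set[str]] = {}
        with Path(cfg.enrichment_annotation).open(newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                annotation.setdefault(row["term"], set()).add(row["accession"])
        reference = {e.accession for e in filtered}
        sample = [c.accession for c in calls if c.is_target]
        results = overrepresentation_test(
            sample, annotation, reference, alpha=cfg.enrichment_alpha
        )
        with (outdir / "enrichment.tsv").open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["term", "k", "n", "K", "N", "fold_enrichment", "p_raw",
                 "p_adjusted", "direction", "significant"]
            )
            for r in results:
                writer.writerow(
                    [r.term, r.k, r.n, r.K, r.N, f"{r.fold_enrichment:.4g}",
                     f"{r.p_raw:.4g}", f"{r.p_adjusted:.4g}", r.direction,
                     int(r.significant)]
                )
        manifest["stages"]["enrich"] = {
            "terms_tested": len(results),
            "significant": sum(r.significant for r in results),
        }

    # optional stage: cross-species mapping + curation
    additions: list[tuple[str, str]] = []
    if cfg.crossmap_ref_targets and cfg.crossmap_store:
        ref_targets = []
        with Path(cfg.crossmap_ref_targets).open(newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                ref_targets.append((row["gene_name"], row.get("protein_name", "")))
        store = SequenceStore.from_dir(cfg.crossmap_store)
        outcomes = map_targets_across_species(
            ref_targets, filtered, calls, store, cfg.cross_species
        )
        if cfg.crossmap_curation:
            records = read_curation_table(cfg.crossmap_curation)
            outcomes = apply_curation(
                outcomes, records, cfg.cross_species.target_chromosome, cfg.cross_species
            )
        with (outdir / "crossmap.tsv").open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["gene_name", "category", "similarity_pct", "exclusion_reason",
                 "chromosome_status", "needs_review", "ref_refseq", "query_refseq"]
            )
            for o in outcomes:
                writer.writerow(
                    [o.gene_name, o.category,
                     "" if o.similarity_pct is None else f"{o.similarity_pct:.1f}",
                     o.exclusion_reason or "", o.chromosome_status,
                     int(o.needs_review), o.ref_refseq or "", o.query_refseq or ""]
                )
        additions = [
            (o.gene_name, "") for o in outcomes if o.category == "additional_candidate"
        ]
        cats: dict[str, int] = {}
        for o in outcomes:
            cats[o.category] = cats.get(o.category, 0) + 1
        manifest["stages"]["crossmap"] = cats

    # combined target table: first-pass targets union cross-species additions
    by_acc = {p.entry.accession: p for p in annotated}
    combined: dict[str, tuple[str, str]] = {}
    for c in calls:
        if c.is_target:
            name = by_acc[c.accession].display_name
            combined.setdefault((name or c.accession).lower(), (name or "", c.accession))
    for gene, _ in additions:
        combined.setdefault(gene.lower(), (gene, ""))
    with (outdir / "combined_targets.tsv").open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_name", "accession"])
        for key in sorted(combined):
            writer.writerow(list(combined[key]))
    manifest["stages"]["combined_targets"] = {"n": len(combined)}

    # optional stage: spermatozoa cross-reference
    if cfg.sperm_list:
        sperm = sio.read_sperm_list(cfg.sperm_list)
        targets = [
            (by_acc[c.accession].display_name, c.accession, "first_pass_target")
            for c in calls
            if c.is_target
        ] + [(g, None, "cross_species_addition") for g, _ in additions]
        hits = run_crossref(targets, sperm)
        with (outdir / "sperm_crossref.tsv").open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_name", "uniprot_id", "matched_by", "origin"])
            for h in hits:
                writer.writerow([h.gene_name or "", h.uniprot_id or "", h.matched_by, h.origin])
        manifest["stages"]["crossref"] = {"hits": len(hits)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
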