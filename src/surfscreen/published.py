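"""Bundled transcriptions of the published screening results.

Three surface-target tables (rabbit X, human X, human Y) carry, per
protein, the printed topology label and matched GO-class abbreviations —
enough evidence to re-run the target classifier on each row.  A fourth
table lists the additional rabbit X-chromosome candidates derived from the
human targets, with the reported human/rabbit percent similarity and the
rabbit chromosome placement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .model import AnnotatedProtein, GOCatalog
from .targets import encode_published_row

_TABLES = {
    "rabbit_x": "rabbit_x_surface_targets.tsv",
    "human_x": "human_x_surface_targets.tsv",
    "human_y": "human_y_surface_targets.tsv",
}


@dataclass(frozen=True)
class PublishedTargetRow:
    accession: str
    gene_name: Optional[str]
    gene_source: str  # uniprot | eggnog | none
    protein_name: str
    topology: str
    go_classes: tuple[str, ...]
    experimental: bool


@dataclass(frozen=True)
class AdditionalTargetRow:
    refseq_human: str
    refseq_rabbit: str
    gene_name: str
    description: str
    similarity_pct: float
    chromosome: str


def _open(name: str):
    return resources.files("surfscreen.data").joinpath(name).open(newline="")


def load_target_table(which: str) -> list[PublishedTargetRow]:
    """Load one of the published surface-target tables.

    ``which`` is ``"rabbit_x"`` (61 proteins), ``"human_x"`` (132) or
    ``"human_y"`` (3).
    """
    if which not in _TABLES:
        raise KeyError(f"unknown table {which!r}; choose from {sorted(_TABLES)}")
    rows: list[PublishedTargetRow] = []
    with _open(_TABLES[which]) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                PublishedTargetRow(
                    accession=row["accession"],
                    gene_name=row["gene_name"] or None,
                    gene_source=row["gene_source"],
                    protein_name=row["protein_name"],
                    topology=row["topology"],
                    go_classes=tuple(row["go_classes"].split(",")),
                    experimental=row["experimental"] == "yes",
                )
            )
    return rows


def load_additional_targets() -> list[AdditionalTargetRow]:
    """The cross-species additions to the rabbit X target list (60 genes)."""
    rows: list[AdditionalTargetRow] = []
    with _open("rabbit_x_additional_targets.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                AdditionalTargetRow(
                    refseq_human=row["refseq_human"],
                    refseq_rabbit=row["refseq_rabbit"],
                    gene_name=row["gene_name"],
                    description=row["description"],
                    similarity_pct=float(row["similarity_pct"]),
                    chromosome=row["chromosome"],
                )
            )
    return rows


def encode_target_table(
    which: str, cat: GOCatalog = GOCatalog()
) -> list[AnnotatedProtein]:
    """Re-encode a published table's printed evidence as annotated proteins."""
    return [
        encode_published_row(
            accession=r.accession,
            topology_label=r.topology,
            go_classes=r.go_classes,
            cat=cat,
            gene_name=r.gene_name,
            experimental=r.experimental,
        )
        for r in load_target_table(which)
    ]


def combined_rabbit_target_genes() -> set[str]:
    """Gene-level union of first-pass rabbit targets and cross-species
    additions (unnamed entries fall back to their accession)."""
    first_pass = {
        (r.gene_name or r.accession).lower() for r in load_target_table("rabbit_x")
    }
    additions = {r.gene_name.lower() for r in load_additional_targets()}
    return first_pass | additions
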