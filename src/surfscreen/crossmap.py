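"""Cross-species target mapping: retrieval, isoform choice, similarity,
and the codified curation rules.

Reference-species targets (gene + protein name) are looked up in a query
species' proteome.  Per gene the store yields the known protein products;
one isoform per species is selected (isoform X1, else isoform 1, else the
longest), the pair is globally aligned, and the percent-similarity
statistic is attached.  Genes matching a query-species target are *common
targets*; genes found in the query proteome but absent from its own target
list are *additional candidates*; genes without products are *unresolved*.
Candidates below the review threshold (default 70 %) are flagged for
manual attention, never auto-excluded.

Curation then applies four exclusion rules in order: removed database
entries, genes on a chromosome other than the target one, duplicate
mappings onto one product (the alias-mapped gene loses), and unconfirmed
orthologs — unless the two species' flanking-gene neighbourhoods are
identical.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from .alignment import AlignmentParams, global_align
from .io import read_sequences, write_sequences
from .model import AnnotatedProtein, IntegrityError, ProteinEntry, TargetCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossSpeciesConfig:
    """Knobs of the cross-species comparison."""

    similarity_review_threshold_pct: float = 70.0
    neighbor_window: int = 3
    reference_species: str = "Homo sapiens"
    target_chromosome: str = "X"
    alignment: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if not 0 < self.similarity_review_threshold_pct <= 100:
            raise ValueError("similarity threshold must be in (0, 100]")


@dataclass(frozen=True)
class Product:
    refseq_id: str
    description: str
    sequence: str


@dataclass
class GeneProductSet:
    """Products returned for one (gene, species) query.

    ``status`` is ``"ok"``, ``"not_found"``, or ``"alias_only"`` (the gene
    name exists only as an alias of ``alias_of``; such products are not
    returned by default to keep alias genes from masquerading as the query).
    """

    gene_name: str
    species: str
    products: list[Product] = field(default_factory=list)
    status: str = "ok"
    alias_of: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [p.refseq_id for p in self.products]
        if len(ids) != len(set(ids)):
            raise IntegrityError(f"duplicate refseq ids for {self.gene_name}/{self.species}")
        if self.status == "ok" and not self.products:
            raise IntegrityError(f"ok status with no products: {self.gene_name}")


@dataclass(frozen=True)
class CurationRecord:
    """Database facts about one candidate gene, used by the curation rules."""

    gene_name: str
    removed_from_source: bool = False
    chromosome: Optional[str] = None
    ortholog_confirmed: bool = True
    flanking_genes_query: tuple[str, ...] = ()
    flanking_genes_subject: tuple[str, ...] = ()
    maps_to_same_product_as: Optional[str] = None
    is_alias_mapping: bool = False


@dataclass(frozen=True)
class CrossMapOutcome:
    """Final category of one reference target in the query species."""

    gene_name: str
    category: str  # common_target | additional_candidate | excluded | unresolved
    similarity_pct: Optional[float] = None
    exclusion_reason: Optional[str] = None
    chromosome_status: str = "other"  # on_chromosome | unplaced | other
    needs_review: bool = False
    query_refseq: Optional[str] = None
    ref_refseq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category == "excluded" and self.exclusion_reason is None:
            raise IntegrityError(f"{self.gene_name}: excluded without a reason")


class SequenceStore:
    """Accession-keyed product store for (species, gene) lookups.

    On disk: a ``manifest.tsv`` (gene, species, refseq_id, description,
    chromosome, primary_gene) plus one FASTA per (species, gene).  A live
    retrieval adapter writes the same layout, so all downstream code is
    source-agnostic.
    """

    def __init__(self) -> None:
        self._products: dict[tuple[str, str], list[Product]] = {}
        self._primary: dict[tuple[str, str], str] = {}
        self._chromosome: dict[tuple[str, str], str] = {}
        self._alias: dict[tuple[str, str], str] = {}  # alias name -> primary

    @staticmethod
    def _key(species: str, gene: str) -> tuple[str, str]:
        return species.strip().lower(), gene.strip().lower()

    def add_product(
        self,
        species: str,
        gene: str,
        refseq_id: str,
        description: str,
        sequence: str,
        chromosome: str = "",
        primary_gene: Optional[str] = None,
        aliases: Iterable[str] = (),
    ) -> None:
        key = self._key(species, gene)
        self._products.setdefault(key, []).append(Product(refseq_id, description, sequence))
        self._primary[key] = primary_gene or gene
        self._chromosome[key] = chromosome
        for alias in aliases:
            self._alias[self._key(species, alias)] = gene

    def chromosome(self, species: str, gene: str) -> Optional[str]:
        return self._chromosome.get(self._key(species, gene))

    def lookup(self, species: str, gene: str) -> GeneProductSet:
        key = self._key(species, gene)
        if key in self._products:
            return GeneProductSet(
                gene_name=gene, species=species, products=list(self._products[key])
            )
        if key in self._alias:
            return GeneProductSet(
                gene_name=gene,
                species=species,
                products=[],
                status="alias_only",
                alias_of=self._alias[key],
            )
        return GeneProductSet(gene_name=gene, species=species, products=[], status="not_found")

    # --- disk layout ------------------------------------------------------

    @classmethod
    def from_dir(cls, path: str | Path) -> "SequenceStore":
        path = Path(path)
        store = cls()
        manifest = path / "manifest.tsv"
        with manifest.open(newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                fasta = path / f"{_slug(row['species'])}__{_slug(row['gene'])}.fasta"
                seqs = read_sequences(fasta) if fasta.exists() else {}
                store.add_product(
                    species=row["species"],
                    gene=row["gene"],
                    refseq_id=row["refseq_id"],
                    description=row["description"],
                    sequence=seqs.get(row["refseq_id"], ""),
                    chromosome=row.get("chromosome", ""),
                    primary_gene=row.get("primary_gene") or row["gene"],
                    aliases=[a for a in (row.get("aliases") or "").split(";") if a],
                )
        return store

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for (species, gene), products in sorted(self._products.items()):
            aliases = sorted(a for (sp, a), prim in self._alias.items()
                             if sp == species and prim.lower() == gene)
            seqs = {p.refseq_id: p.sequence for p in products if p.sequence}
            if seqs:
                write_sequences(seqs, path / f"{_slug(species)}__{_slug(gene)}.fasta")
            for p in products:
                rows.append(
                    [gene, species, p.refseq_id, p.description,
                     self._chromosome.get((species, gene), ""),
                     self._primary.get((species, gene), gene), ";".join(aliases)]
                )
        with (path / "manifest.tsv").open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["gene", "species", "refseq_id", "description", "chromosome",
                 "primary_gene", "aliases"]
            )
            writer.writerows(rows)


def _slug(s: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", s.strip()).strip("_")


def fetch_gene_products(gene: str, species: str, store: SequenceStore) -> GeneProductSet:
    """Look up the products of one gene in one species.

    Alias-only matches are flagged (``status="alias_only"``) rather than
    silently accepted, preventing distinct genes with shared alias names
    from contaminating the comparison; an absent gene yields a
    ``"not_found"`` status, never an exception.
    """
    return store.lookup(species, gene)


_ISOFORM_X1 = re.compile(r"\bisoform X1\b")
_ISOFORM_1 = re.compile(r"\bisoform 1\b")


def select_isoform(product_set: GeneProductSet) -> tuple[str, str]:
    """Pick one product: isoform X1, else isoform 1, else the longest.

    Ties break on the lexicographically smallest RefSeq ID.
    """
    if not product_set.products:
        raise ValueError(f"no products to select for {product_set.gene_name}")
    for pattern in (_ISOFORM_X1, _ISOFORM_1):
        hits = sorted(
            (p for p in product_set.products if pattern.search(p.description)),
            key=lambda p: p.refseq_id,
        )
        if hits:
            return hits[0].refseq_id, hits[0].sequence
    best = sorted(product_set.products, key=lambda p: (-len(p.sequence), p.refseq_id))[0]
    return best.refseq_id, best.sequence


def _similarity(
    ref_seq: str, query_seq: str, params: AlignmentParams, ref_id: str, query_id: str
) -> float:
    return global_align(
        query_seq, ref_seq, params, query_id=query_id, subject_id=ref_id
    ).similarity_pct


def map_targets_across_species(
    ref_targets: list[tuple[str, str]],
    query_proteome: list[ProteinEntry],
    query_targets: list[TargetCall],
    store: SequenceStore,
    cfg: CrossSpeciesConfig = CrossSpeciesConfig(),
    query_species: str = "Oryctolagus cuniculus",
) -> list[CrossMapOutcome]:
    """Categorise each reference-species target in the query species.

    ``ref_targets`` are (gene name, protein name) pairs for the reference
    species' targets; ``query_targets`` are the query species' own target
    calls over ``query_proteome``.  Every reference target yields exactly
    one outcome.
    """
    target_accs = {t.accession for t in query_targets if t.is_target}
    query_target_genes = {
        e.gene_name.lower() for e in query_proteome
        if e.gene_name and e.accession in target_accs
    }

    outcomes: list[CrossMapOutcome] = []
    for gene, _protein_name in ref_targets:
        ref_set = fetch_gene_products(gene, cfg.reference_species, store)
        query_set = fetch_gene_products(gene, query_species, store)

        similarity = ref_id = query_id = None
        if ref_set.status == "ok" and query_set.status == "ok":
            ref_id, ref_seq = select_isoform(ref_set)
            query_id, query_seq = select_isoform(query_set)
            if ref_seq and query_seq:
                similarity = _similarity(ref_seq, query_seq, cfg.alignment, ref_id, query_id)

        chrom = store.chromosome(query_species, gene)
        if chrom is None or chrom == "":
            chrom_status = "other"
        elif chrom.strip().lower() in ("unplaced", "un"):
            chrom_status = "unplaced"
        elif chrom.strip().upper() == cfg.target_chromosome.upper():
            chrom_status = "on_chromosome"
        else:
            chrom_status = "other"

        if gene.lower() in query_target_genes:
            category = "common_target"
        elif query_set.status == "ok":
            category = "additional_candidate"
        else:
            category = "unresolved"

        outcomes.append(
            CrossMapOutcome(
                gene_name=gene,
                category=category,
                similarity_pct=similarity,
                chromosome_status=chrom_status,
                needs_review=(
                    similarity is not None
                    and similarity < cfg.similarity_review_threshold_pct
                ),
                query_refseq=query_id,
                ref_refseq=ref_id,
            )
        )
    return outcomes


def apply_curation(
    outcomes: list[CrossMapOutcome],
    records: list[CurationRecord],
    target_chromosome: str = "X",
    cfg: CrossSpeciesConfig = CrossSpeciesConfig(),
) -> list[CrossMapOutcome]:
    """Apply the four exclusion rules, in order, to candidate outcomes.

    1. entries removed from the source database;
    2. entries placed on a chromosome other than the target (unplaced
       entries are retained);
    3. several genes mapping to one product: the gene for which the product
       is primary is kept, alias mappings are excluded;
    4. unconfirmed orthologs — exempt when the ordered flanking-gene lists
       of the two species are identical.

    A missing curation record leaves the outcome unchanged with a warning.
    """
    by_gene = {r.gene_name.lower(): r for r in records}
    out: list[CrossMapOutcome] = []
    for o in outcomes:
        if o.category not in ("additional_candidate", "common_target"):
            out.append(o)
            continue
        rec = by_gene.get(o.gene_name.lower())
        if rec is None:
            logger.warning("no curation record for %s; outcome unchanged", o.gene_name)
            out.append(o)
            continue
        if rec.removed_from_source:
            out.append(replace(o, category="excluded", exclusion_reason="removed_entry"))
            continue
        chrom = (rec.chromosome or "").strip()
        if chrom and chrom.lower() not in ("unplaced", "un") and \
                chrom.upper() != target_chromosome.upper():
            out.append(replace(o, category="excluded", exclusion_reason="other_chromosome"))
            continue
        if rec.maps_to_same_product_as is not None and rec.is_alias_mapping:
            out.append(replace(o, category="excluded", exclusion_reason="duplicate_mapping"))
            continue
        if not rec.ortholog_confirmed:
            window = 2 * cfg.neighbor_window
            flanks_q = rec.flanking_genes_query[:window]
            flanks_s = rec.flanking_genes_subject[:window]
            if not (flanks_q and flanks_q == flanks_s):
                out.append(replace(o, category="excluded", exclusion_reason="not_ortholog"))
                continue
        out.append(o)
    return out


@dataclass(frozen=True)
class EggnogMatch:
    """An unnamed protein whose orthology-assigned name hits a candidate."""

    candidate_gene: str
    accession: str
    needs_similarity_check: bool = True


def match_unnamed_via_eggnog(
    unnamed: list[AnnotatedProtein], candidates: list[CrossMapOutcome]
) -> list[EggnogMatch]:
    """Cross-reference orthology-assigned names of unnamed proteins against
    the candidate genes; every match requires a follow-up similarity and
    orthology verification."""
    candidate_genes = {c.gene_name.lower(): c.gene_name for c in candidates}
    matches: list[EggnogMatch] = []
    for p in unnamed:
        if p.entry.gene_name or not p.eggnog_name:
            continue
        hit = candidate_genes.get(p.eggnog_name.lower())
        if hit is not None:
            matches.append(EggnogMatch(candidate_gene=hit, accession=p.entry.accession))
    return matches


def read_curation_table(path: str | Path) -> list[CurationRecord]:
    """Read curation facts from TSV (lists ';'-joined, booleans yes/no)."""
    records: list[CurationRecord] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                CurationRecord(
                    gene_name=row["gene_name"],
                    removed_from_source=row.get("removed", "no").lower() in ("yes", "true", "1"),
                    chromosome=row.get("chromosome") or None,
                    ortholog_confirmed=row.get("ortholog", "yes").lower()
                    in ("yes", "true", "1"),
                    flanking_genes_query=tuple(
                        g for g in (row.get("flanks_query") or "").split(";") if g
                    ),
                    flanking_genes_subject=tuple(
                        g for g in (row.get("flanks_subject") or "").split(";") if g
                    ),
                    maps_to_same_product_as=row.get("same_product_as") or None,
                    is_alias_mapping=row.get("alias_mapping", "no").lower()
                    in ("yes", "true", "1"),
                )
            )
    return records


def write_curation_table(records: list[CurationRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene_name", "removed", "chromosome", "ortholog", "flanks_query",
             "flanks_subject", "same_product_as", "alias_mapping"]
        )
        for r in records:
            writer.writerow(
                [
                    r.gene_name,
                    "yes" if r.removed_from_source else "no",
                    r.chromosome or "",
                    "yes" if r.ortholog_confirmed else "no",
                    ";".join(r.flanking_genes_query),
                    ";".join(r.flanking_genes_subject),
                    r.maps_to_same_product_as or "",
                    "yes" if r.is_alias_mapping else "no",
                ]
            )
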