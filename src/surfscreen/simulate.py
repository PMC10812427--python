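"""Self-contained synthetic fixtures with ground-truth ledgers.

The generator emulates the statistical structure the screening pipeline
assumes: multi-transcript genes with redundant UniProt-style entries
(reviewed/canonical flags), GO annotations split between a UniProt-style
source and orthology-transfer rows of varying hit quality, topology
predictions consistent with the planted interest/target labels, and, for
the cross-species stage, two-species product stores with isoform-labelled
descriptions, alias genes, wrong-chromosome genes and non-orthologs with
or without identical flanking-gene neighbourhoods.

Every planted target satisfies the surface/membrane decision rule by
construction and every planted non-target violates it, so the expected
outcome of each stage is known exactly and recorded in a
:class:`GroundTruthLedger` — the oracle for end-to-end tests.

It does not attempt realistic GO DAG structure or phylogenetic sequence
evolution; sequences are uniform over the 20 standard residues, which is
sufficient for rule-based stages and keeps column-identity expectations in
closed form (divergence is applied substitutions-first, then indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .crossmap import CurationRecord, SequenceStore
from .io import (
    write_eggnog_table,
    write_proteome_table,
    write_sequences,
    write_topology,
    write_transcript_mapping,
)
from .model import (
    EggnogAnnotation,
    IntegrityError,
    OrthologyType,
    ProteinEntry,
    ProteinType,
    TargetCall,
    TopologyPrediction,
    TranscriptMapping,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# representative catalog GO IDs used when planting annotations
_GO_SURFACE = "GO:0009986"  # cell surface
_GO_MEMBRANE = "GO:0005886"  # plasma membrane
_GO_ES = "GO:0005615"  # extracellular space
_GO_NEUTRAL = ("GO:0008150", "GO:0003674", "GO:0005575")  # non-catalog filler


@dataclass(frozen=True)
class SimConfig:
    """Generator conditions.

    ``duplicate_entry_rate`` defaults to the redundancy level observed in
    the rabbit chromosome proteome (39.5 % duplicate entries; the human
    proteome's 62 % is the other motivated choice).  Interest/surface/
    transmembrane rates default to the proportions of the screened rabbit
    set (about 16 % of entries with a localisation of interest, 61/100
    surface-accessible among them, about 19 % transmembrane).
    """

    n_genes: int = 500
    transcripts_per_gene_mean: float = 1.5
    duplicate_entry_rate: float = 0.395
    p_reviewed: float = 0.1
    go_interest_rate: float = 0.16
    go_surface_given_interest: float = 0.6
    p_es_only_given_interest: float = 0.1
    p_transmembrane: float = 0.19
    p_no_gene_entry: float = 0.02
    p_eggnog_row: float = 0.45
    p_eggnog_violation: float = 0.3
    seq_length_range: tuple[int, int] = (60, 400)
    ortholog_sub_rate: float = 0.10
    ortholog_indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.seq_length_range[0] < 30:
            raise ValueError("minimum sequence length is 30")
        for p in (
            self.duplicate_entry_rate,
            self.p_reviewed,
            self.go_interest_rate,
            self.go_surface_given_interest,
            self.p_es_only_given_interest,
            self.p_transmembrane,
            self.p_no_gene_entry,
            self.p_eggnog_row,
            self.p_eggnog_violation,
            self.ortholog_sub_rate,
            self.ortholog_indel_rate,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0,1]")


@dataclass
class GroundTruthLedger:
    """What each pipeline stage is expected to produce on the fixture."""

    expected_survivors: set[str] = field(default_factory=set)
    expected_interest: set[str] = field(default_factory=set)
    expected_targets: set[str] = field(default_factory=set)
    expected_dropped_no_gene: set[str] = field(default_factory=set)
    expected_dropped_duplicate: set[str] = field(default_factory=set)
    n_eggnog_rows: int = 0
    n_eggnog_pass: int = 0
    planted_enriched_terms: list[str] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_crossref_overlap: set[str] = field(default_factory=set)
    expected_outcomes: dict[str, tuple[str, Optional[str]]] = field(default_factory=dict)

    def check(self) -> None:
        if not self.expected_targets <= self.expected_interest:
            raise IntegrityError("ledger: targets not a subset of interest")
        if not self.expected_interest <= self.expected_survivors:
            raise IntegrityError("ledger: interest not a subset of survivors")


@dataclass
class ProteomeFixture:
    """In-memory fixture set for the first-pass screening stages."""

    entries: list[ProteinEntry]
    mapping: list[TranscriptMapping]
    eggnog: list[EggnogAnnotation]
    topology: list[TopologyPrediction]
    sequences: dict[str, str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.tsv",
            "mapping": outdir / "mapping.tsv",
            "eggnog": outdir / "eggnog.tsv",
            "topology": outdir / "topology.gff",
            "fasta": outdir / "sequences.fasta",
        }
        write_proteome_table(self.entries, paths["proteome"])
        write_transcript_mapping(self.mapping, paths["mapping"])
        write_eggnog_table(self.eggnog, paths["eggnog"])
        write_topology(self.topology, paths["topology"])
        write_sequences(self.sequences, paths["fasta"])
        return paths


def _random_seq(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _topology_for(
    acc: str, transmembrane: bool, rng: np.random.Generator
) -> TopologyPrediction:
    if transmembrane:
        with_sp = bool(rng.random() < 0.25)
        return TopologyPrediction(
            accession=acc,
            protein_type=ProteinType.TM_SP if with_sp else ProteinType.TM,
            n_tmr=int(rng.integers(1, 8)),
            has_signal_peptide=with_sp,
        )
    with_sp = bool(rng.random() < 0.08)
    return TopologyPrediction(
        accession=acc,
        protein_type=ProteinType.GLOB_SP if with_sp else ProteinType.GLOB,
        n_tmr=0,
        has_signal_peptide=with_sp,
    )


def generate_proteome(cfg: SimConfig) -> tuple[ProteomeFixture, GroundTruthLedger]:
    """Generate a redundant proteome with planted filter/classification truth."""
    rng = np.random.default_rng(cfg.seed)
    ledger = GroundTruthLedger()
    entries: list[ProteinEntry] = []
    mapping: list[TranscriptMapping] = []
    eggnog: list[EggnogAnnotation] = []
    topology: list[TopologyPrediction] = []
    sequences: dict[str, str] = {}
    acc_counter = 0

    def next_acc() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"SYN{acc_counter:05d}"

    for g in range(1, cfg.n_genes + 1):
        gene_id = f"ENSSYNG{g:07d}"
        gene_name = f"GENE{g}"
        n_tx = 1 + int(rng.geometric(1.0 / cfg.transcripts_per_gene_mean))
        tx_ids = [f"ENSSYNT{g:07d}{k}" for k in range(n_tx)]
        for k, tid in enumerate(tx_ids):
            mapping.append(TranscriptMapping(tid, gene_id, is_canonical=(k == 0)))

        # planted labels
        interest = rng.random() < cfg.go_interest_rate
        transmembrane = rng.random() < cfg.p_transmembrane
        go_ids: set[str] = set(rng.choice(_GO_NEUTRAL, size=1))
        is_target = False
        es_only = False
        if interest:
            roll = rng.random()
            if roll < cfg.p_es_only_given_interest:
                # ES-only entries are of interest (and targets) iff transmembrane
                es_only = True
                go_ids.add(_GO_ES)
                interest = transmembrane
                is_target = transmembrane
            elif rng.random() < cfg.go_surface_given_interest:
                go_ids.add(_GO_SURFACE)
                is_target = True
            else:
                go_ids.add(_GO_MEMBRANE)
                is_target = transmembrane
        seq = _random_seq(rng, *cfg.seq_length_range)

        # split GO between the UniProt column and an orthology-transfer row
        egg_go: set[str] = set()
        has_egg = rng.random() < cfg.p_eggnog_row
        if has_egg and (interest or es_only) and rng.random() < 0.5 and len(go_ids) > 1:
            moved = sorted(g_ for g_ in go_ids if g_ not in _GO_NEUTRAL)[0]
            go_ids.discard(moved)
            egg_go.add(moved)

        primary = ProteinEntry(
            accession=next_acc(),
            reviewed=bool(rng.random() < cfg.p_reviewed),
            gene_name=gene_name,
            protein_name=f"Synthetic protein {g}",
            length=len(seq),
            chromosome="X",
            sequence=seq,
            go_ids=frozenset(go_ids),
            transcript_ids=tuple(tx_ids[: min(2, n_tx)]),  # canonical first
        )
        entries.append(primary)
        sequences[primary.accession] = seq
        topology.append(_topology_for(primary.accession, transmembrane, rng))
        ledger.expected_survivors.add(primary.accession)
        if interest:
            ledger.expected_interest.add(primary.accession)
        if is_target:
            ledger.expected_targets.add(primary.accession)

        if has_egg:
            violation = rng.random() < cfg.p_eggnog_violation
            row = _eggnog_row(primary.accession, gene_name, egg_go, violation, rng)
            eggnog.append(row)
            ledger.n_eggnog_rows += 1
            if not violation:
                ledger.n_eggnog_pass += 1
            if violation and egg_go:
                # the planted GO travelled on a failing row: restore it on the
                # entry so the classification truth is unaffected
                entries[-1] = _with_go(primary, frozenset(go_ids | egg_go))

        # redundant duplicate entry for the same gene (never reviewed, never
        # canonical, so the primary always survives the gene contest)
        if n_tx > 1 and rng.random() < cfg.duplicate_entry_rate:
            dup_seq = _random_seq(rng, *cfg.seq_length_range)
            dup = ProteinEntry(
                accession=next_acc(),
                reviewed=False,
                gene_name=gene_name,
                protein_name=f"Synthetic protein {g} (redundant)",
                length=len(dup_seq),
                chromosome="X",
                sequence=dup_seq,
                go_ids=frozenset(),
                transcript_ids=(tx_ids[-1],),
            )
            # guard: if the primary were unreviewed and non-canonical the
            # contest would tie-break lexicographically; the primary holds the
            # canonical transcript, so it wins regardless of review status
            entries.append(dup)
            sequences[dup.accession] = dup_seq
            topology.append(_topology_for(dup.accession, False, rng))
            ledger.expected_dropped_duplicate.add(dup.accession)

        # unmapped orphan entry (transcript without a gene association)
        if rng.random() < cfg.p_no_gene_entry:
            orphan_tx = f"ENSSYNTX{g:07d}"
            mapping.append(TranscriptMapping(orphan_tx, None, False))
            orphan_seq = _random_seq(rng, *cfg.seq_length_range)
            orphan = ProteinEntry(
                accession=next_acc(),
                reviewed=False,
                gene_name=None,
                protein_name="Uncharacterized protein",
                length=len(orphan_seq),
                chromosome="X",
                sequence=orphan_seq,
                go_ids=frozenset(),
                transcript_ids=(orphan_tx,),
            )
            entries.append(orphan)
            sequences[orphan.accession] = orphan_seq
            topology.append(_topology_for(orphan.accession, False, rng))
            ledger.expected_dropped_no_gene.add(orphan.accession)

    ledger.check()
    fixture = ProteomeFixture(entries, mapping, eggnog, topology, sequences)
    return fixture, ledger


def _with_go(e: ProteinEntry, go_ids: frozenset[str]) -> ProteinEntry:
    return ProteinEntry(
        accession=e.accession,
        reviewed=e.reviewed,
        gene_name=e.gene_name,
        protein_name=e.protein_name,
        length=e.length,
        chromosome=e.chromosome,
        sequence=e.sequence,
        go_ids=go_ids,
        transcript_ids=e.transcript_ids,
    )


def _eggnog_row(
    acc: str,
    gene_name: str,
    go_ids: set[str],
    violation: bool,
    rng: np.random.Generator,
) -> EggnogAnnotation:
    evalue = float(10 ** rng.uniform(-40, -5))
    bit_score = float(rng.uniform(80, 400))
    ident = float(rng.uniform(85, 100))
    qcov = float(rng.uniform(85, 100))
    scov = float(rng.uniform(85, 100))
    orth = OrthologyType.ONE2ONE
    if violation:
        which = int(rng.integers(0, 4))
        if which == 0:
            evalue = float(rng.uniform(0.01, 1.0))
        elif which == 1:
            bit_score = float(rng.uniform(5, 59))
        elif which == 2:
            ident = float(rng.uniform(10, 79))
        else:
            orth = OrthologyType.OTHER
    return EggnogAnnotation(
        query_accession=acc,
        preferred_name=gene_name,
        description=f"ortholog of {gene_name}",
        go_ids=frozenset() if violation else frozenset(go_ids),
        orthology_type=orth,
        evalue=evalue,
        bit_score=bit_score,
        pct_identity=ident,
        query_coverage=qcov,
        subject_coverage=scov,
        go_evidence_experimental=not violation,
    )


def mutate_sequence(
    seq: str, sub_rate: float, indel_rate: float, seed: int | np.random.Generator = 0
) -> tuple[str, dict]:
    """Apply per-position substitutions, then single-residue indels.

    Substitutions replace a residue uniformly among the 19 alternatives.
    Indels act per position: deletion with probability ``indel_rate/2``,
    insertion of a random residue before the position with
    ``indel_rate/2``.  The ledger records exact edit counts and positions.
    """
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues = list(AMINO_ACIDS)
    subs: list[int] = []
    out: list[str] = []
    for i, ch in enumerate(seq):
        if rng.random() < sub_rate:
            alternatives = [r for r in residues if r != ch]
            ch = str(rng.choice(alternatives))
            subs.append(i)
        out.append(ch)
    mutated = out
    insertions: list[int] = []
    deletions: list[int] = []
    if indel_rate > 0:
        final: list[str] = []
        for i, ch in enumerate(mutated):
            roll = rng.random()
            if roll < indel_rate / 2:
                deletions.append(i)
                continue
            if roll < indel_rate:
                final.append(str(rng.choice(residues)))
                insertions.append(i)
            final.append(ch)
        mutated = final
    ledger = {
        "n_sub": len(subs),
        "n_ins": len(insertions),
        "n_del": len(deletions),
        "sub_positions": subs,
        "ins_positions": insertions,
        "del_positions": deletions,
    }
    return "".join(mutated), ledger


@dataclass
class CrossmapFixture:
    """Two-species fixture exercising every mapping/curation scenario."""

    store: SequenceStore
    ref_targets: list[tuple[str, str]]
    query_proteome: list[ProteinEntry]
    query_targets: list[TargetCall]
    curation: list[CurationRecord]
    ref_species: str = "Homo sapiens"
    query_species: str = "Oryctolagus cuniculus"


def generate_crossmap_fixture(cfg: SimConfig) -> tuple[CrossmapFixture, GroundTruthLedger]:
    """Plant every curation scenario at least once; ledger records the
    expected :class:`~surfscreen.crossmap.CrossMapOutcome` per gene."""
    rng = np.random.default_rng(cfg.seed + 7)
    ledger = GroundTruthLedger()
    store = SequenceStore()
    ref_species, query_species = "Homo sapiens", "Oryctolagus cuniculus"
    ref_targets: list[tuple[str, str]] = []
    query_proteome: list[ProteinEntry] = []
    query_targets: list[TargetCall] = []
    curation: list[CurationRecord] = []

    n_common = max(3, cfg.n_genes // 100)
    n_additional = max(3, cfg.n_genes // 150)
    n_missing = 2
    counter = 0

    def add_gene(
        tag: str,
        *,
        in_query_store: bool = True,
        query_is_target: bool = False,
        sub_rate: Optional[float] = None,
        chromosome: str = "X",
        removed: bool = False,
        ortholog: bool = True,
        identical_flanks: Optional[bool] = None,
        alias_pair: bool = False,
    ) -> str:
        nonlocal counter
        counter += 1
        gene = f"{tag}{counter}"
        protein_name = f"synthetic {tag.lower()} protein {counter}"
        ref_seq = _random_seq(rng, *cfg.seq_length_range)
        store.add_product(
            ref_species, gene, f"NP_{counter:06d}",
            f"{protein_name} isoform 1", ref_seq, chromosome="X",
        )
        # a decoy isoform ensures the selection rule is exercised
        store.add_product(
            ref_species, gene, f"XP_{counter:06d}",
            f"{protein_name} isoform X1",
            ref_seq,
            chromosome="X",
        )
        ref_targets.append((gene, protein_name))
        rate = cfg.ortholog_sub_rate if sub_rate is None else sub_rate
        query_seq, _ = mutate_sequence(ref_seq, rate, cfg.ortholog_indel_rate, rng)
        if in_query_store:
            store.add_product(
                query_species, gene, f"XP_Q{counter:06d}",
                f"{protein_name} isoform X1", query_seq, chromosome=chromosome,
            )
            ledger.ortholog_pairs.append((gene, gene, rate))
        if query_is_target:
            acc = f"QRY{counter:05d}"
            query_proteome.append(
                ProteinEntry(
                    accession=acc, gene_name=gene, protein_name=protein_name,
                    length=len(query_seq), chromosome="X", sequence=query_seq,
                    go_ids=frozenset({_GO_SURFACE}),
                )
            )
            query_targets.append(
                TargetCall(acc, of_interest=True, is_target=True,
                           triggering_classes=frozenset({"CS"}))
            )
        flanks = tuple(f"NBR{counter}_{k}" for k in range(2 * 3))
        curation.append(
            CurationRecord(
                gene_name=gene,
                removed_from_source=removed,
                chromosome=chromosome,
                ortholog_confirmed=ortholog,
                flanking_genes_query=flanks,
                flanking_genes_subject=(
                    flanks if (identical_flanks or ortholog)
                    else tuple(f"OTH{counter}_{k}" for k in range(2 * 3))
                ),
                is_alias_mapping=False,
                maps_to_same_product_as=None,
            )
        )
        return gene

    for _ in range(n_common):
        g = add_gene("CMN", query_is_target=True)
        ledger.expected_outcomes[g] = ("common_target", None)
    for _ in range(n_additional):
        g = add_gene("ADD")
        ledger.expected_outcomes[g] = ("additional_candidate", None)
    for _ in range(n_missing):
        g = add_gene("MIS", in_query_store=False)
        ledger.expected_outcomes[g] = ("unresolved", None)

    g = add_gene("CHR", chromosome="2")
    ledger.expected_outcomes[g] = ("excluded", "other_chromosome")
    g = add_gene("REM", removed=True)
    ledger.expected_outcomes[g] = ("excluded", "removed_entry")
    g = add_gene("ORT", ortholog=False, identical_flanks=False)
    ledger.expected_outcomes[g] = ("excluded", "not_ortholog")
    g = add_gene("NBE", ortholog=False, identical_flanks=True)
    ledger.expected_outcomes[g] = ("additional_candidate", None)
    g = add_gene("LOW", sub_rate=0.5)
    ledger.expected_outcomes[g] = ("additional_candidate", None)
    g = add_gene("UNP", chromosome="Unplaced")
    ledger.expected_outcomes[g] = ("additional_candidate", None)

    # duplicate-mapping pair: both ref genes resolve to one query product;
    # the alias-mapped gene is excluded during curation
    primary = add_gene("DUP")
    counter += 1
    alias_gene = f"DUPALIAS{counter}"
    ref_seq = _random_seq(rng, *cfg.seq_length_range)
    store.add_product(ref_species, alias_gene, f"NP_{counter:06d}",
                      f"alias-shared protein isoform 1", ref_seq, chromosome="X")
    store.add_product(
        query_species, alias_gene, f"XP_Q{counter:06d}",
        "alias-shared protein isoform 1",
        mutate_sequence(ref_seq, cfg.ortholog_sub_rate, 0.0, rng)[0],
        chromosome="X",
    )
    ref_targets.append((alias_gene, "alias-shared protein"))
    curation.append(
        CurationRecord(
            gene_name=alias_gene,
            chromosome="X",
            maps_to_same_product_as=primary,
            is_alias_mapping=True,
        )
    )
    ledger.expected_outcomes[alias_gene] = ("excluded", "duplicate_mapping")
    ledger.expected_outcomes[primary] = ("additional_candidate", None)

    # planted crossref overlap: a subset of genes later listed in the
    # spermatozoa reference list
    all_genes = sorted(ledger.expected_outcomes)
    overlap = rng.choice(all_genes, size=min(7, len(all_genes)), replace=False)
    ledger.planted_crossref_overlap = set(str(g) for g in overlap)

    fixture = CrossmapFixture(
        store=store,
        ref_targets=ref_targets,
        query_proteome=query_proteome,
        query_targets=query_targets,
        curation=curation,
        ref_species=ref_species,
        query_species=query_species,
    )
    return fixture, ledger
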