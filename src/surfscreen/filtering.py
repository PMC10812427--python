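"""Redundancy filtering of a raw chromosome proteome.

UniProt chromosome proteomes carry many entries per gene (isoforms,
unreviewed fragments, multi-transcript mappings).  The filter reduces the
table to at most one entry per gene:

1. entries whose transcripts all lack an associated gene (or that have no
   transcript mapping at all) are dropped;
2. an entry mapped to several transcripts keeps a single transcript
   association, preferring the canonical one;
3. among entries sharing a gene, one survivor is kept — a reviewed entry if
   any, else the entry whose transcript is canonical, else the
   lexicographically smallest accession (deterministic tie-break).

Every dropped record is accounted for in a :class:`FilterAudit`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import IntegrityError, ProteinEntry, TranscriptMapping

logger = logging.getLogger(__name__)


@dataclass
class FilterAudit:
    """Exact bookkeeping of the filtering run; counts always reconcile."""

    input_count: int = 0
    dropped_no_gene: list[str] = field(default_factory=list)
    dropped_gene_duplicate: list[tuple[str, str, str]] = field(default_factory=list)
    dropped_uniprot_duplicate_transcripts: list[tuple[str, str, tuple[str, ...]]] = field(
        default_factory=list
    )
    output_count: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def total_dropped(self) -> int:
        return len(self.dropped_no_gene) + len(self.dropped_gene_duplicate)

    def check(self) -> None:
        if self.input_count != self.output_count + self.total_dropped:
            raise IntegrityError(
                f"audit does not reconcile: {self.input_count} != "
                f"{self.output_count} + {self.total_dropped}"
            )


def _index_mapping(mapping: list[TranscriptMapping]) -> dict[str, TranscriptMapping]:
    by_tid: dict[str, TranscriptMapping] = {}
    canonical_gene_of: dict[str, str] = {}
    for m in mapping:
        prev = by_tid.get(m.transcript_id)
        if prev is not None and prev.gene_id != m.gene_id:
            raise IntegrityError(
                f"transcript {m.transcript_id} mapped to two genes: {prev.gene_id}, {m.gene_id}"
            )
        by_tid[m.transcript_id] = m
        if m.is_canonical and m.gene_id is not None:
            known = canonical_gene_of.setdefault(m.transcript_id, m.gene_id)
            if known != m.gene_id:
                raise IntegrityError(
                    f"canonical transcript {m.transcript_id} claimed by genes "
                    f"{known} and {m.gene_id}"
                )
    return by_tid


def filter_redundant(
    entries: list[ProteinEntry], mapping: list[TranscriptMapping]
) -> tuple[list[ProteinEntry], FilterAudit]:
    """Apply the three redundancy rules; returns survivors plus an audit."""
    by_tid = _index_mapping(mapping)
    audit = FilterAudit(input_count=len(entries))

    # rules 1-2: resolve each entry to a single gene-bearing transcript
    resolved: list[tuple[ProteinEntry, str, str]] = []  # (entry, transcript, gene)
    for e in entries:
        gene_bearing = [
            t for t in e.transcript_ids if t in by_tid and by_tid[t].gene_id is not None
        ]
        if not gene_bearing:
            audit.dropped_no_gene.append(e.accession)
            continue
        canonical = [t for t in gene_bearing if by_tid[t].is_canonical]
        chosen = sorted(canonical)[0] if canonical else sorted(gene_bearing)[0]
        resolved.append((e, chosen, by_tid[chosen].gene_id))

    # rule 3: one survivor per gene
    by_gene: dict[str, list[tuple[ProteinEntry, str]]] = {}
    for e, tid, gene in resolved:
        by_gene.setdefault(gene, []).append((e, tid))

    survivors: dict[str, ProteinEntry] = {}
    for gene, members in by_gene.items():
        if len(members) == 1:
            e, tid = members[0]
            survivors[e.accession] = _with_transcript(e, tid)
            continue
        reviewed = sorted((e.accession for e, _ in members if e.reviewed))
        canonical = sorted((e.accession for e, t in members if by_tid[t].is_canonical))
        if reviewed:
            keep, reason = reviewed[0], "reviewed_priority"
            if len(reviewed) > 1:
                msg = f"gene {gene}: multiple reviewed entries {reviewed}; kept {keep}"
                audit.warnings.append(msg)
                logger.warning(msg)
        elif canonical:
            keep, reason = canonical[0], "canonical_priority"
        else:
            keep, reason = min(e.accession for e, _ in members), "tie_break"
        for e, tid in members:
            if e.accession == keep:
                survivors[e.accession] = _with_transcript(e, tid)
            else:
                audit.dropped_gene_duplicate.append((e.accession, keep, reason))

    # record transcript deduplication for surviving multi-transcript entries
    surviving_tid = {e.accession: e.transcript_ids[0] for e in survivors.values()}
    for e in entries:
        if e.accession in surviving_tid and len(e.transcript_ids) > 1:
            kept = surviving_tid[e.accession]
            audit.dropped_uniprot_duplicate_transcripts.append(
                (e.accession, kept, tuple(t for t in e.transcript_ids if t != kept))
            )

    ordered = [survivors[e.accession] for e in entries if e.accession in survivors]
    audit.output_count = len(ordered)
    audit.check()
    return ordered, audit


def _with_transcript(e: ProteinEntry, tid: str) -> ProteinEntry:
    if e.transcript_ids == (tid,):
        return e
    return ProteinEntry(
        accession=e.accession,
        reviewed=e.reviewed,
        gene_name=e.gene_name,
        protein_name=e.protein_name,
        length=e.length,
        chromosome=e.chromosome,
        sequence=e.sequence,
        go_ids=e.go_ids,
        transcript_ids=(tid,),
    )
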