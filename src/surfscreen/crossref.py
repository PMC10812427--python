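"""Cross-reference of candidate targets against a spermatozoa protein list.

Targets hit when their gene name (case-insensitive exact match) or UniProt
ID appears in the reference list; each target is reported at most once,
with the key(s) that matched and the target's origin (first-pass screen or
cross-species addition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import SpermProteinList


@dataclass(frozen=True)
class CrossrefHit:
    gene_name: Optional[str]
    uniprot_id: Optional[str]
    matched_by: str  # gene_name | uniprot_id | both
    origin: str  # first_pass_target | cross_species_addition


def crossref(
    targets: list[tuple[Optional[str], Optional[str], str]],
    sperm: SpermProteinList,
) -> list[CrossrefHit]:
    """Match ``(gene, uniprot_id, origin)`` targets against the sperm list."""
    sperm_genes = {g.lower() for g, _ in sperm.records if g}
    sperm_ids = {u for _, u in sperm.records if u}

    hits: list[CrossrefHit] = []
    seen: set[tuple[Optional[str], Optional[str]]] = set()
    for gene, uid, origin in targets:
        key = (gene.lower() if gene else None, uid)
        if key in seen:
            continue
        by_gene = bool(gene) and gene.lower() in sperm_genes
        by_id = bool(uid) and uid in sperm_ids
        if not (by_gene or by_id):
            continue
        seen.add(key)
        matched_by = "both" if (by_gene and by_id) else ("gene_name" if by_gene else "uniprot_id")
        hits.append(
            CrossrefHit(gene_name=gene, uniprot_id=uid, matched_by=matched_by, origin=origin)
        )
    hits.sort(key=lambda h: (h.gene_name is None, (h.gene_name or "").lower(),
                             h.uniprot_id or ""))
    return hits
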