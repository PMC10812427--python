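"""Annotation merging: orthology-hit filtering and GO-source union.

A protein's working GO set is the union of its UniProt annotations and any
GO IDs transferred by one-to-one orthology that survive the hit-quality
filter.  Each GO ID keeps a record of which source(s) contributed it, and a
separate set tracks IDs carried with experimental evidence — the later
target call reports whether any of its triggering IDs are in that set.
"""

from __future__ import annotations

from .model import (
    AnnotatedProtein,
    EggnogAnnotation,
    EggnogFilterConfig,
    IntegrityError,
    ProteinEntry,
    TopologyPrediction,
)

#: UniProt evidence codes treated as experimental when the proteome export
#: carries per-GO evidence (configurable; the manual-assertion EXP family
#: plus their high-throughput variants).
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"}
)


def filter_eggnog_hits(
    raw: list[EggnogAnnotation], cfg: EggnogFilterConfig = EggnogFilterConfig()
) -> list[EggnogAnnotation]:
    """Keep only rows meeting every hit-quality threshold (inclusive).

    When ``cfg.require_experimental_go`` is set, rows lacking experimental
    GO evidence are retained (their name/description still contribute) but
    their GO IDs are stripped.
    """
    out: list[EggnogAnnotation] = []
    for r in raw:
        if r.evalue > cfg.max_evalue:
            continue
        if r.bit_score < cfg.min_bit_score:
            continue
        if r.pct_identity < cfg.min_identity_pct:
            continue
        if r.query_coverage < cfg.min_query_cov_pct:
            continue
        if r.subject_coverage < cfg.min_subject_cov_pct:
            continue
        if cfg.require_one2one and r.orthology_type.value != "one2one":
            continue
        if cfg.require_experimental_go and not r.go_evidence_experimental and r.go_ids:
            r = EggnogAnnotation(
                query_accession=r.query_accession,
                preferred_name=r.preferred_name,
                description=r.description,
                go_ids=frozenset(),
                orthology_type=r.orthology_type,
                evalue=r.evalue,
                bit_score=r.bit_score,
                pct_identity=r.pct_identity,
                query_coverage=r.query_coverage,
                subject_coverage=r.subject_coverage,
                go_evidence_experimental=False,
            )
        out.append(r)
    return out


def merge_annotations(
    entries: list[ProteinEntry],
    egg: list[EggnogAnnotation],
    topo: list[TopologyPrediction],
    uniprot_experimental_go: dict[str, frozenset[str]] | None = None,
) -> list[AnnotatedProtein]:
    """Build one :class:`AnnotatedProtein` per entry.

    ``uniprot_experimental_go`` optionally maps accession -> GO IDs whose
    UniProt evidence code is experimental; orthology-transferred GO IDs are
    experimental by construction (the hit filter enforces it).
    """
    egg_by_acc: dict[str, EggnogAnnotation] = {}
    for r in egg:
        if r.query_accession in egg_by_acc:
            raise IntegrityError(
                f"two orthology rows for {r.query_accession} after filtering"
            )
        egg_by_acc[r.query_accession] = r
    topo_by_acc: dict[str, TopologyPrediction] = {}
    for t in topo:
        if t.accession in topo_by_acc:
            raise IntegrityError(f"two topology rows for {t.accession}")
        topo_by_acc[t.accession] = t
    uniprot_experimental_go = uniprot_experimental_go or {}

    out: list[AnnotatedProtein] = []
    for e in entries:
        hit = egg_by_acc.get(e.accession)
        egg_go = hit.go_ids if hit else frozenset()
        union = e.go_ids | egg_go
        sources = {
            gid: frozenset(
                (["uniprot"] if gid in e.go_ids else [])
                + (["eggnog"] if gid in egg_go else [])
            )
            for gid in union
        }
        experimental = frozenset(uniprot_experimental_go.get(e.accession, frozenset())) | (
            egg_go if (hit and hit.go_evidence_experimental) else frozenset()
        )
        out.append(
            AnnotatedProtein(
                entry=e,
                go_union=union,
                go_sources=sources,
                eggnog_name=(hit.preferred_name if (hit and not e.gene_name) else None),
                experimental_evidence_go=experimental & union,
                topology=topo_by_acc.get(e.accession),
            )
        )
    return out
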