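"""Two-stage interest/target classification.

A protein is *of interest* when its merged GO set contains any catalog GO ID
of interest, or when its only relevant annotation is extracellular space
(ES) and it is predicted transmembrane.  It is a *target* — plausibly
accessible from the cell surface — when it carries a surface-class GO ID
(CS, ESPM, ECESPM, ACESPM, ICESPM, ESCW, ESCOM), or a membrane-class GO ID
(PM, ACPM, ICPM, ES) combined with predicted transmembrane topology.

Only exact catalog GO IDs trigger; ontology descendants are not expanded
(see :func:`classify_interest`'s ``expand`` hook for the opt-in variant).
Proteins with no topology prediction are treated as non-transmembrane and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    AnnotatedProtein,
    GOCatalog,
    ProteinType,
    TargetCall,
    TOPOLOGY_LABELS,
    ProteinEntry,
)


def _is_tm(p: AnnotatedProtein) -> bool:
    return p.topology is not None and p.topology.protein_type.is_transmembrane


def classify_interest(
    p: AnnotatedProtein, cat: GOCatalog
) -> tuple[bool, frozenset[str], bool]:
    """Return ``(of_interest, matched class abbreviations, via_es_tm)``.

    ``via_es_tm`` is True only when interest was granted solely through the
    ES + transmembrane route (no other interest class present).
    """
    classes = cat.classes_for(p.go_union)
    has_es = cat.es_id in p.go_union
    if classes:
        return True, classes | (frozenset({"ES"}) if has_es else frozenset()), False
    if has_es and _is_tm(p):
        return True, frozenset({"ES"}), True
    return False, frozenset({"ES"}) if has_es else frozenset(), False


def classify_target(p: AnnotatedProtein, cat: GOCatalog = GOCatalog()) -> TargetCall:
    """Apply the surface/membrane decision rule to one annotated protein."""
    of_interest, classes, via_es_tm = classify_interest(p, cat)
    surface = classes & cat.surface_classes
    membrane = classes & cat.membrane_classes_requiring_tm
    tm = _is_tm(p)
    if surface:
        is_target, triggering = True, surface
    elif membrane and tm:
        is_target, triggering = True, membrane
    else:
        is_target, triggering = False, classes if of_interest else frozenset()
    experimental = False
    if is_target:
        trigger_ids = {
            gid
            for gid in p.go_union
            if cat.interest_ids.get(gid) in triggering
            or (gid == cat.es_id and "ES" in triggering)
        }
        experimental = bool(trigger_ids & p.experimental_evidence_go)
    return TargetCall(
        accession=p.entry.accession,
        of_interest=of_interest,
        is_target=is_target,
        triggering_classes=triggering,
        via_es_tm=via_es_tm,
        experimental_support=experimental,
        topology_missing=p.topology is None,
    )


@dataclass
class ScreenSummary:
    """Aggregate counts over a screened proteome."""

    n_proteins: int = 0
    n_interest: int = 0
    n_target: int = 0
    n_target_experimental: int = 0
    n_topology_missing: int = 0
    topology_counts: dict[str, int] = field(default_factory=dict)


def screen_proteome(
    annotated: list[AnnotatedProtein], cat: GOCatalog = GOCatalog()
) -> tuple[list[TargetCall], ScreenSummary]:
    """Classify every protein and summarise the screen."""
    calls = [classify_target(p, cat) for p in annotated]
    summary = ScreenSummary(n_proteins=len(annotated))
    for p, c in zip(annotated, calls):
        summary.n_interest += c.of_interest
        summary.n_target += c.is_target
        summary.n_target_experimental += c.is_target and c.experimental_support
        summary.n_topology_missing += c.topology_missing
        key = p.topology.protein_type.value if p.topology else "missing"
        summary.topology_counts[key] = summary.topology_counts.get(key, 0) + 1
    return calls, summary


def encode_published_row(
    accession: str,
    topology_label: str,
    go_classes: list[str] | tuple[str, ...],
    cat: GOCatalog = GOCatalog(),
    gene_name: str | None = None,
    experimental: bool = False,
) -> AnnotatedProtein:
    """Reconstruct an annotated protein from a printed result-table row.

    Result tables report a topology label (``TM``, ``SP+TM``, ``SP``,
    ``GLOB``) and the matched GO-class abbreviations; each abbreviation is
    mapped back to a representative catalog GO ID so the classifier can be
    re-run on the printed evidence.
    """
    ptype = TOPOLOGY_LABELS[topology_label.strip()]
    go_ids = frozenset(cat.representative_id(ab.strip()) for ab in go_classes)
    from .model import TopologyPrediction  # local to avoid a cycle in type docs

    topo = TopologyPrediction(
        accession=accession,
        protein_type=ptype,
        n_tmr=1 if ptype.is_transmembrane else 0,
        has_signal_peptide=ptype.has_signal_peptide,
    )
    return AnnotatedProtein(
        entry=ProteinEntry(accession=accession, gene_name=gene_name),
        go_union=go_ids,
        go_sources={g: frozenset({"uniprot"}) for g in go_ids},
        experimental_evidence_go=go_ids if experimental else frozenset(),
        topology=topo,
    )
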