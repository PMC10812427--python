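"""Shared domain types for the surface-target screening pipeline.

The pipeline screens a chromosome-scoped proteome for proteins that are
plausibly accessible from the cell surface.  Evidence is combined from three
sources: Gene Ontology (GO) cellular-component annotations taken from a
UniProt-style export, GO annotations transferred by one-to-one orthology
(eggNOG-mapper-style output), and a five-way transmembrane-topology
prediction (DeepTMHMM-style output).  The types below are deliberately
thin ``dataclass`` records; all behaviour lives in the stage modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

GO_ID_RE = re.compile(r"^GO:\d{7}$")


class ProteinType(str, Enum):
    """Five-way topology classification of a protein chain.

    TM      alpha-helical transmembrane, no signal peptide
    TM_SP   alpha-helical transmembrane with a signal peptide
    BETA    beta-barrel transmembrane
    GLOB    globular, no signal peptide
    GLOB_SP globular with a signal peptide
    """

    TM = "TM"
    TM_SP = "TM_SP"
    BETA = "BETA"
    GLOB = "GLOB"
    GLOB_SP = "GLOB_SP"

    @property
    def is_transmembrane(self) -> bool:
        return self in (ProteinType.TM, ProteinType.TM_SP, ProteinType.BETA)

    @property
    def has_signal_peptide(self) -> bool:
        return self in (ProteinType.TM_SP, ProteinType.GLOB_SP)


#: Printed-table topology labels <-> five-way classes.  Result tables print
#: "SP" for a globular protein whose only feature is a signal peptide and
#: "SP+TM" for a transmembrane protein with one; this is the single place
#: where the two vocabularies interconvert.
TOPOLOGY_LABELS: Mapping[str, ProteinType] = {
    "TM": ProteinType.TM,
    "SP+TM": ProteinType.TM_SP,
    "TM+SP": ProteinType.TM_SP,
    "SP": ProteinType.GLOB_SP,
    "GLOB": ProteinType.GLOB,
    "BETA": ProteinType.BETA,
}


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


class IntegrityError(ValueError):
    """An input violates a uniqueness/consistency contract."""


@dataclass
class ProteinEntry:
    """One proteome record (one row of a UniProt-style export)."""

    accession: str
    reviewed: bool = False
    gene_name: Optional[str] = None
    protein_name: str = ""
    length: int = 0
    chromosome: str = ""
    sequence: Optional[str] = None
    go_ids: frozenset[str] = field(default_factory=frozenset)
    transcript_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise IntegrityError("accession must be non-empty")
        self.go_ids = frozenset(self.go_ids)
        self.transcript_ids = tuple(self.transcript_ids)
        for gid in self.go_ids:
            if not GO_ID_RE.match(gid):
                raise IntegrityError(f"malformed GO ID {gid!r} on {self.accession}")
        if self.sequence is not None and self.length and len(self.sequence) != self.length:
            raise IntegrityError(
                f"{self.accession}: length field {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass(frozen=True)
class TranscriptMapping:
    """BioMart-style transcript -> gene association with a canonical flag."""

    transcript_id: str
    gene_id: Optional[str] = None
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise IntegrityError("transcript_id must be non-empty")


class OrthologyType(str, Enum):
    ONE2ONE = "one2one"
    OTHER = "other"


@dataclass
class EggnogAnnotation:
    """One orthology-transfer annotation row (eggNOG-mapper-style output)."""

    query_accession: str
    preferred_name: Optional[str] = None
    description: Optional[str] = None
    go_ids: frozenset[str] = field(default_factory=frozenset)
    orthology_type: OrthologyType = OrthologyType.OTHER
    evalue: float = 0.0
    bit_score: float = 0.0
    pct_identity: float = 0.0
    query_coverage: float = 0.0
    subject_coverage: float = 0.0
    go_evidence_experimental: bool = False

    def __post_init__(self) -> None:
        self.go_ids = frozenset(self.go_ids)
        if self.evalue < 0:
            raise IntegrityError(f"{self.query_accession}: negative e-value")
        for pct in (self.pct_identity, self.query_coverage, self.subject_coverage):
            if not 0 <= pct <= 100:
                raise IntegrityError(f"{self.query_accession}: percentage {pct} outside [0,100]")


@dataclass(frozen=True)
class EggnogFilterConfig:
    """Hit-quality thresholds for accepting orthology-transferred annotation.

    Defaults follow the screening protocol: e-value <= 1e-3, bit score >= 60,
    identity / query coverage / subject coverage >= 80 %, one-to-one orthology
    only, and GO transfer restricted to experimentally supported annotation.
    All thresholds are inclusive.
    """

    max_evalue: float = 0.001
    min_bit_score: float = 60.0
    min_identity_pct: float = 80.0
    min_query_cov_pct: float = 80.0
    min_subject_cov_pct: float = 80.0
    require_one2one: bool = True
    require_experimental_go: bool = True


@dataclass(frozen=True)
class TopologyPrediction:
    """Per-protein topology call: five-way type, TMR count, signal peptide."""

    accession: str
    protein_type: ProteinType
    n_tmr: int = 0
    has_signal_peptide: bool = False

    def __post_init__(self) -> None:
        needs_tmr = self.protein_type in (ProteinType.TM, ProteinType.TM_SP, ProteinType.BETA)
        if needs_tmr != (self.n_tmr >= 1):
            raise IntegrityError(
                f"{self.accession}: n_tmr={self.n_tmr} inconsistent with type "
                f"{self.protein_type.value}"
            )
        if self.has_signal_peptide != self.protein_type.has_signal_peptide:
            raise IntegrityError(
                f"{self.accession}: signal-peptide flag inconsistent with type "
                f"{self.protein_type.value}"
            )


#: GO cellular-component IDs of interest and their class abbreviations.
#: PM plasma membrane, CS cell surface, ESPM external side of plasma membrane,
#: ECESPM extrinsic component of external side of PM, ACPM anchored component
#: of PM (kept although obsoleted upstream: it denotes a topology), ACESPM
#: anchored component of external side of PM, ICESPM integral component of
#: external side of PM, ICPM integral component of PM, ESCW external side of
#: cell wall, ESCOM external side of cell outer membrane.
DEFAULT_INTEREST_IDS: Mapping[str, str] = {
    "GO:0005886": "PM",
    "GO:0005904": "PM",
    "GO:0009986": "CS",
    "GO:0009928": "CS",
    "GO:0009929": "CS",
    "GO:0009897": "ESPM",
    "GO:0031232": "ECESPM",
    "GO:0046658": "ACPM",
    "GO:0031362": "ACESPM",
    "GO:0071575": "ICESPM",
    "GO:0005887": "ICPM",
    "GO:0010339": "ESCW",
    "GO:0031240": "ESCOM",
}

ES_GO_ID = "GO:0005615"  # extracellular space


@dataclass(frozen=True)
class GOCatalog:
    """The fixed GO vocabulary driving interest/target classification.

    ``surface_classes`` grant target status directly; ``membrane_classes_
    requiring_tm`` (which include ES, extracellular space) grant it only when
    the protein is predicted transmembrane.  The two sets are disjoint and
    jointly cover every abbreviation in the catalog.
    """

    interest_ids: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_INTEREST_IDS)
    )
    es_id: str = ES_GO_ID
    surface_classes: frozenset[str] = frozenset(
        {"CS", "ESPM", "ECESPM", "ACESPM", "ICESPM", "ESCW", "ESCOM"}
    )
    membrane_classes_requiring_tm: frozenset[str] = frozenset({"PM", "ACPM", "ICPM", "ES"})

    def __post_init__(self) -> None:
        overlap = self.surface_classes & self.membrane_classes_requiring_tm
        if overlap:
            raise IntegrityError(f"surface/membrane class sets overlap: {sorted(overlap)}")
        abbrevs = set(self.interest_ids.values()) | {"ES"}
        covered = self.surface_classes | self.membrane_classes_requiring_tm
        missing = abbrevs - covered
        if missing:
            raise IntegrityError(f"catalog abbreviations not covered: {sorted(missing)}")

    def classes_for(self, go_ids: frozenset[str] | set[str]) -> frozenset[str]:
        """Interest-class abbreviations matched by exact GO IDs (ES excluded)."""
        return frozenset(self.interest_ids[g] for g in go_ids if g in self.interest_ids)

    def representative_id(self, abbrev: str) -> str:
        """First catalog GO ID carrying the given class abbreviation."""
        if abbrev == "ES":
            return self.es_id
        for gid, ab in self.interest_ids.items():
            if ab == abbrev:
                return gid
        raise KeyError(abbrev)


@dataclass(frozen=True)
class SpermProteinList:
    """Reference list of proteins reported in spermatozoa (gene and/or ID keyed)."""

    records: tuple[tuple[Optional[str], Optional[str]], ...]

    def __post_init__(self) -> None:
        for gene, uid in self.records:
            if not gene and not uid:
                raise IntegrityError("sperm-list record with neither gene name nor UniProt ID")


@dataclass
class AnnotatedProtein:
    """A proteome entry after GO-source merging and topology attachment."""

    entry: ProteinEntry
    go_union: frozenset[str] = field(default_factory=frozenset)
    go_sources: Mapping[str, frozenset[str]] = field(default_factory=dict)
    eggnog_name: Optional[str] = None
    experimental_evidence_go: frozenset[str] = field(default_factory=frozenset)
    topology: Optional[TopologyPrediction] = None

    @property
    def display_name(self) -> Optional[str]:
        return self.entry.gene_name or self.eggnog_name


@dataclass(frozen=True)
class TargetCall:
    """Outcome of the two-stage interest/target decision for one protein."""

    accession: str
    of_interest: bool
    is_target: bool
    triggering_classes: frozenset[str] = frozenset()
    via_es_tm: bool = False
    experimental_support: bool = False
    topology_missing: bool = False

    def __post_init__(self) -> None:
        if self.is_target and not self.of_interest:
            raise IntegrityError(f"{self.accession}: target without interest")


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's overrepresentation statistics against a reference set."""

    term: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_raw: float
    p_adjusted: float
    direction: str  # "over" | "under"
    significant: bool


def validate_go_catalog(cat: GOCatalog) -> None:
    """Re-check catalog invariants (used after loading external configs)."""
    GOCatalog(
        interest_ids=dict(cat.interest_ids),
        es_id=cat.es_id,
        surface_classes=cat.surface_classes,
        membrane_classes_requiring_tm=cat.membrane_classes_requiring_tm,
    )


def parse_go_field(raw: str) -> frozenset[str]:
    """Split a multi-valued GO column into clean GO IDs.

    Accepts ";" or "," separators and strips bracketed descriptive text,
    e.g. ``"GO:0005886 [plasma membrane]; GO:0009986"``.
    """
    if not raw or not raw.strip():
        return frozenset()
    cleaned = re.sub(r"\[[^\]]*\]", "", raw)
    parts = re.split(r"[;,]", cleaned)
    ids = []
    for p in parts:
        p = p.strip()
        if not p:
            continue
        if not GO_ID_RE.match(p):
            raise FormatError(f"malformed GO ID {p!r}")
        ids.append(p)
    return frozenset(ids)


def check_unique(values: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise IntegrityError(f"duplicate {what}: {v}")
        seen.add(v)
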