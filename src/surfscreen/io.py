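"""Readers and writers for every external format the pipeline touches.

All tabular inputs are plain TSV with a header row; absent values are
encoded as empty fields on write, and both empty fields and the printed
placeholder ``-`` are read back as absent.  Sequence IO goes through
Biopython's ``SeqIO``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    EggnogAnnotation,
    FormatError,
    GOCatalog,
    IntegrityError,
    OrthologyType,
    ProteinEntry,
    ProteinType,
    SpermProteinList,
    TopologyPrediction,
    TranscriptMapping,
    parse_go_field,
    validate_go_catalog,
)

PROTEOME_COLUMNS = [
    "accession",
    "reviewed",
    "gene_name",
    "protein_name",
    "length",
    "chromosome",
    "go_ids",
    "transcript_ids",
]

_BOOL_TRUE = {"yes", "true", "1", "reviewed"}
_BOOL_FALSE = {"no", "false", "0", "unreviewed", ""}


def _parse_bool(raw: str, context: str) -> bool:
    low = raw.strip().lower()
    if low in _BOOL_TRUE:
        return True
    if low in _BOOL_FALSE:
        return False
    raise FormatError(f"{context}: cannot interpret {raw!r} as a boolean")


def _absent(raw: Optional[str]) -> Optional[str]:
    if raw is None:
        return None
    raw = raw.strip()
    return None if raw in ("", "-") else raw


def _read_rows(path: str | Path, required: list[str], what: str):
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{what} file {path} is empty (no header)")
        for col in required:
            if col not in reader.fieldnames:
                raise FormatError(f"{what} file {path} is missing required column {col!r}")
        yield from reader


def read_proteome_table(path: str | Path, format: str = "uniprot_tsv") -> list[ProteinEntry]:
    """Read a UniProt-style proteome export into ``ProteinEntry`` records.

    Multi-valued GO and transcript columns are split on ";" (GO also accepts
    ","); missing gene names come back as ``None``, never ``""``.
    """
    if format != "uniprot_tsv":
        raise ValueError(f"unsupported proteome format {format!r}")
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for row in _read_rows(path, PROTEOME_COLUMNS, "proteome"):
        acc = row["accession"].strip()
        if acc in seen:
            raise IntegrityError(f"duplicate accession {acc} in {path}")
        seen.add(acc)
        seq = _absent(row.get("sequence", ""))
        transcripts = tuple(
            t.strip() for t in (row["transcript_ids"] or "").split(";") if t.strip()
        )
        entries.append(
            ProteinEntry(
                accession=acc,
                reviewed=_parse_bool(row["reviewed"], acc),
                gene_name=_absent(row["gene_name"]),
                protein_name=(row["protein_name"] or "").strip(),
                length=int(row["length"]) if row["length"].strip() else 0,
                chromosome=row["chromosome"].strip(),
                sequence=seq,
                go_ids=parse_go_field(row["go_ids"]),
                transcript_ids=transcripts,
            )
        )
    return entries


def write_proteome_table(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROTEOME_COLUMNS + ["sequence"])
        for e in entries:
            writer.writerow(
                [
                    e.accession,
                    "yes" if e.reviewed else "no",
                    e.gene_name or "",
                    e.protein_name,
                    e.length,
                    e.chromosome,
                    ";".join(sorted(e.go_ids)),
                    ";".join(e.transcript_ids),
                    e.sequence or "",
                ]
            )


def read_transcript_mapping(path: str | Path) -> list[TranscriptMapping]:
    """Read a BioMart-style transcript/gene/canonical table."""
    out: list[TranscriptMapping] = []
    canonical_by_gene: dict[str, str] = {}
    for row in _read_rows(path, ["transcript_id", "gene_id", "is_canonical"], "mapping"):
        m = TranscriptMapping(
            transcript_id=row["transcript_id"].strip(),
            gene_id=_absent(row["gene_id"]),
            is_canonical=_parse_bool(row["is_canonical"], row["transcript_id"]),
        )
        if m.is_canonical and m.gene_id is not None:
            prev = canonical_by_gene.setdefault(m.gene_id, m.transcript_id)
            if prev != m.transcript_id:
                raise IntegrityError(
                    f"gene {m.gene_id} has two canonical transcripts: {prev}, {m.transcript_id}"
                )
        out.append(m)
    return out


def write_transcript_mapping(mappings: Iterable[TranscriptMapping], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["transcript_id", "gene_id", "is_canonical"])
        for m in mappings:
            writer.writerow([m.transcript_id, m.gene_id or "", "yes" if m.is_canonical else "no"])


EGGNOG_COLUMNS = [
    "query",
    "seed_ortholog",
    "evalue",
    "score",
    "preferred_name",
    "description",
    "GOs",
    "orthology_type",
    "identity",
    "query_cov",
    "subject_cov",
    "go_evidence",
]


def read_eggnog_table(path: str | Path) -> list[EggnogAnnotation]:
    """Read an eggNOG-mapper-style annotation table (one row per hit)."""
    out: list[EggnogAnnotation] = []
    for row in _read_rows(path, EGGNOG_COLUMNS, "eggNOG"):
        orth = row["orthology_type"].strip().lower()
        out.append(
            EggnogAnnotation(
                query_accession=row["query"].strip(),
                preferred_name=_absent(row["preferred_name"]),
                description=_absent(row["description"]),
                go_ids=parse_go_field(row["GOs"]),
                orthology_type=(
                    OrthologyType.ONE2ONE if orth in ("one2one", "1:1", "one-to-one")
                    else OrthologyType.OTHER
                ),
                evalue=float(row["evalue"]),
                bit_score=float(row["score"]),
                pct_identity=float(row["identity"]),
                query_coverage=float(row["query_cov"]),
                subject_coverage=float(row["subject_cov"]),
                go_evidence_experimental=_parse_bool(row["go_evidence"], row["query"]),
            )
        )
    return out


def write_eggnog_table(rows: Iterable[EggnogAnnotation], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EGGNOG_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.query_accession,
                    "",
                    repr(r.evalue),
                    r.bit_score,
                    r.preferred_name or "",
                    r.description or "",
                    ";".join(sorted(r.go_ids)),
                    r.orthology_type.value,
                    r.pct_identity,
                    r.query_coverage,
                    r.subject_coverage,
                    "yes" if r.go_evidence_experimental else "no",
                ]
            )


# --- topology -------------------------------------------------------------

#: region labels accepted in the GFF3-like dialect
_TM_REGIONS = {"TMhelix"}
_BETA_REGIONS = {"Beta sheet"}
_SP_REGIONS = {"signal"}
_PLAIN_REGIONS = {"inside", "outside", "periplasm"}
_ALL_REGIONS = _TM_REGIONS | _BETA_REGIONS | _SP_REGIONS | _PLAIN_REGIONS


def _classify(n_helix: int, n_beta: int, has_sp: bool, acc: str) -> TopologyPrediction:
    if n_beta:
        ptype = ProteinType.BETA
        # the five-way scheme has no BETA+SP class; a signal on a barrel is kept as BETA
        has_sp = False
    elif n_helix:
        ptype = ProteinType.TM_SP if has_sp else ProteinType.TM
    else:
        ptype = ProteinType.GLOB_SP if has_sp else ProteinType.GLOB
    return TopologyPrediction(
        accession=acc,
        protein_type=ptype,
        n_tmr=n_helix + n_beta,
        has_signal_peptide=ptype.has_signal_peptide,
    )


def read_topology(path: str | Path, dialect: str = "gff3_like") -> list[TopologyPrediction]:
    """Parse topology predictions in either supported dialect.

    ``gff3_like``: tab-separated region records ``accession  label  start  end``
    with ``#`` comment lines; TMR count is the number of ``TMhelix`` /
    ``Beta sheet`` records.  ``three_line``: ``>accession | TYPE`` header,
    sequence line, per-residue label line (S signal, M helix, B sheet,
    I/O/P loop).
    """
    path = Path(path)
    if dialect == "gff3_like":
        return _read_topology_gff(path)
    if dialect == "three_line":
        return _read_topology_3line(path)
    raise ValueError(f"unknown topology dialect {dialect!r}")


def _read_topology_gff(path: Path) -> list[TopologyPrediction]:
    per_acc: dict[str, dict] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("//"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected tab-separated region record")
            acc, label = parts[0].strip(), parts[1].strip()
            if label not in _ALL_REGIONS:
                raise FormatError(f"{path}:{lineno}: unknown region label {label!r}")
            state = per_acc.setdefault(acc, {"helix": 0, "beta": 0, "sp": False})
            if acc not in order:
                order.append(acc)
            if label in _TM_REGIONS:
                state["helix"] += 1
            elif label in _BETA_REGIONS:
                state["beta"] += 1
            elif label in _SP_REGIONS:
                state["sp"] = True
    return [
        _classify(per_acc[a]["helix"], per_acc[a]["beta"], per_acc[a]["sp"], a) for a in order
    ]


def _read_topology_3line(path: Path) -> list[TopologyPrediction]:
    out: list[TopologyPrediction] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3:
        raise FormatError(f"{path}: three-line dialect requires records of 3 lines")
    for i in range(0, len(lines), 3):
        header, _seq, labels = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise FormatError(f"{path}: record {i // 3 + 1} header does not start with '>'")
        acc = header[1:].split("|")[0].strip()
        bad = set(labels) - set("SMBIOP")
        if bad:
            raise FormatError(f"{path}: unknown residue labels {sorted(bad)} for {acc}")
        n_helix = _count_runs(labels, "M")
        n_beta = _count_runs(labels, "B")
        out.append(_classify(n_helix, n_beta, labels.startswith("S"), acc))
    return out


def _count_runs(labels: str, char: str) -> int:
    runs, inside = 0, False
    for c in labels:
        if c == char and not inside:
            runs, inside = runs + 1, True
        elif c != char:
            inside = False
    return runs


def write_topology(preds: Iterable[TopologyPrediction], path: str | Path) -> None:
    """Write predictions in the GFF3-like dialect (synthetic region spans)."""
    with Path(path).open("w") as fh:
        for p in preds:
            fh.write(f"# {p.accession} type={p.protein_type.value}\n")
            pos = 1
            if p.has_signal_peptide:
                fh.write(f"{p.accession}\tsignal\t{pos}\t{pos + 19}\n")
                pos += 20
            label = "Beta sheet" if p.protein_type is ProteinType.BETA else "TMhelix"
            for _ in range(p.n_tmr):
                fh.write(f"{p.accession}\tinside\t{pos}\t{pos + 4}\n")
                pos += 5
                fh.write(f"{p.accession}\t{label}\t{pos}\t{pos + 19}\n")
                pos += 20
            fh.write(f"{p.accession}\toutside\t{pos}\t{pos + 9}\n")


# --- sequences ------------------------------------------------------------


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{accession: sequence}``.

    The key is the header token before the first whitespace; sequences are
    upper-cased.  Duplicate keys and empty sequences are integrity errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        key = rec.id
        if key in out:
            raise IntegrityError(f"duplicate FASTA key {key} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise IntegrityError(f"empty sequence for {key} in {path}")
        out[key] = seq
    return out


def write_sequences(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --- sperm-protein reference list ----------------------------------------


def read_sperm_list(path: str | Path) -> SpermProteinList:
    records = []
    for row in _read_rows(path, ["gene_name", "uniprot_id"], "sperm list"):
        records.append((_absent(row["gene_name"]), _absent(row["uniprot_id"])))
    return SpermProteinList(records=tuple(records))


# --- GO catalog config ----------------------------------------------------


def read_go_catalog(path: str | Path) -> GOCatalog:
    """Load a GO catalog override from YAML; invariants are re-validated."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    cat = GOCatalog(
        interest_ids=dict(raw["interest_ids"]),
        es_id=raw.get("es_id", "GO:0005615"),
        surface_classes=frozenset(raw["surface_classes"]),
        membrane_classes_requiring_tm=frozenset(raw["membrane_classes_requiring_tm"]),
    )
    validate_go_catalog(cat)
    return cat
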