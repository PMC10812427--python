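"""Redundancy filter: priority rules, audit conservation, idempotence.

The reference oracle below re-applies the three rules by exhaustive
case analysis, independently of the implementation's bookkeeping."""

import pytest

from surfscreen.filtering import filter_redundant
from surfscreen.model import IntegrityError, ProteinEntry, TranscriptMapping
from surfscreen.simulate import SimConfig, generate_proteome


def _entry(acc, reviewed=False, transcripts=()):
    return ProteinEntry(accession=acc, reviewed=reviewed, transcript_ids=transcripts)


def brute_force_survivors(entries, mapping):
    """Independent re-application of the filtering rules."""
    gene_of = {m.transcript_id: m.gene_id for m in mapping}
    canonical = {m.transcript_id for m in mapping if m.is_canonical}
    per_gene: dict[str, list] = {}
    for e in entries:
        tids = [t for t in e.transcript_ids if gene_of.get(t) is not None]
        if not tids:
            continue  # rule 1
        tid = min(sorted(t for t in tids if t in canonical) or sorted(tids))
        per_gene.setdefault(gene_of[tid], []).append((e, tid))
    keep = set()
    for gene, members in per_gene.items():
        reviewed = sorted(e.accession for e, _ in members if e.reviewed)
        canon = sorted(e.accession for e, t in members if t in canonical)
        if reviewed:
            keep.add(reviewed[0])
        elif canon:
            keep.add(canon[0])
        else:
            keep.add(min(e.accession for e, _ in members))
    return keep


class TestPriorityRules:
    def test_reviewed_beats_canonical(self):
        mapping = [
            TranscriptMapping("T1", "G1", is_canonical=True),
            TranscriptMapping("T2", "G1", is_canonical=False),
        ]
        entries = [
            _entry("A", reviewed=False, transcripts=("T1",)),
            _entry("B", reviewed=True, transcripts=("T2",)),
        ]
        kept, audit = filter_redundant(entries, mapping)
        assert [e.accession for e in kept] == ["B"]
        assert audit.dropped_gene_duplicate == [("A", "B", "reviewed_priority")]

    def test_canonical_when_no_reviewed(self):
        mapping = [
            TranscriptMapping("T1", "G1", is_canonical=False),
            TranscriptMapping("T2", "G1", is_canonical=True),
        ]
        entries = [_entry("A", transcripts=("T1",)), _entry("B", transcripts=("T2",))]
        kept, audit = filter_redundant(entries, mapping)
        assert [e.accession for e in kept] == ["B"]
        assert audit.dropped_gene_duplicate[0][2] == "canonical_priority"

    def test_unmapped_entry_dropped(self):
        mapping = [TranscriptMapping("T1", None)]
        kept, audit = filter_redundant([_entry("A", transcripts=("T1",))], mapping)
        assert kept == [] and audit.dropped_no_gene == ["A"]

    def test_no_transcripts_at_all_dropped(self):
        kept, audit = filter_redundant([_entry("A")], [])
        assert kept == [] and audit.dropped_no_gene == ["A"]

    def test_multi_transcript_entry_keeps_canonical(self):
        mapping = [
            TranscriptMapping("T1", "G1", is_canonical=False),
            TranscriptMapping("T2", "G1", is_canonical=True),
        ]
        kept, audit = filter_redundant([_entry("A", transcripts=("T1", "T2"))], mapping)
        assert kept[0].transcript_ids == ("T2",)
        assert audit.dropped_uniprot_duplicate_transcripts == [("A", "T2", ("T1",))]

    def test_two_reviewed_entries_warn_not_error(self):
        mapping = [
            TranscriptMapping("T1", "G1", is_canonical=True),
            TranscriptMapping("T2", "G1"),
        ]
        entries = [
            _entry("B", reviewed=True, transcripts=("T2",)),
            _entry("A", reviewed=True, transcripts=("T1",)),
        ]
        kept, audit = filter_redundant(entries, mapping)
        assert [e.accession for e in kept] == ["A"]  # lexicographic among reviewed
        assert audit.warnings

    def test_canonical_claimed_by_two_genes_is_error(self):
        mapping = [
            TranscriptMapping("T1", "G1", is_canonical=True),
            TranscriptMapping("T1", "G2", is_canonical=True),
        ]
        with pytest.raises(IntegrityError):
            filter_redundant([_entry("A", transcripts=("T1",))], mapping)


class TestAgainstOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 11])
    def test_synthetic_proteome_matches_brute_force(self, seed):
        fixture, ledger = generate_proteome(SimConfig(n_genes=40, seed=seed))
        kept, audit = filter_redundant(fixture.entries, fixture.mapping)
        got = {e.accession for e in kept}
        assert got == brute_force_survivors(fixture.entries, fixture.mapping)
        assert got == ledger.expected_survivors

    def test_audit_conservation(self):
        fixture, _ = generate_proteome(SimConfig(n_genes=60, seed=4))
        _, audit = filter_redundant(fixture.entries, fixture.mapping)
        audit.check()
        dropped = set(audit.dropped_no_gene) | {a for a, _, _ in audit.dropped_gene_duplicate}
        assert len(dropped) == audit.total_dropped  # no accession in two categories

    def test_idempotence(self):
        fixture, _ = generate_proteome(SimConfig(n_genes=50, seed=9))
        kept, _ = filter_redundant(fixture.entries, fixture.mapping)
        again, audit = filter_redundant(kept, fixture.mapping)
        assert [e.accession for e in again] == [e.accession for e in kept]
        assert audit.total_dropped == 0

    def test_output_sets_unique_and_subset(self):
        fixture, _ = generate_proteome(SimConfig(n_genes=80, seed=2))
        kept, _ = filter_redundant(fixture.entries, fixture.mapping)
        accs = [e.accession for e in kept]
        assert len(accs) == len(set(accs))
        assert set(accs) <= {e.accession for e in fixture.entries}
        gene_of = {m.transcript_id: m.gene_id for m in fixture.mapping}
        genes = [gene_of[e.transcript_ids[0]] for e in kept]
        assert len(genes) == len(set(genes))
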