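"""Interest/target decision rule and its monotonicity properties."""

import pytest

from surfscreen.model import AnnotatedProtein, ProteinEntry, ProteinType, TopologyPrediction
from surfscreen.simulate import SimConfig, generate_proteome
from surfscreen.annotation import filter_eggnog_hits, merge_annotations
from surfscreen.filtering import filter_redundant
from surfscreen.targets import (
    classify_interest,
    classify_target,
    encode_published_row,
    screen_proteome,
)


def _protein(go_ids, ptype=None, experimental=frozenset()):
    topo = None
    if ptype is not None:
        topo = TopologyPrediction(
            accession="A1",
            protein_type=ptype,
            n_tmr=1 if ptype.is_transmembrane else 0,
            has_signal_peptide=ptype.has_signal_peptide,
        )
    go = frozenset(go_ids)
    return AnnotatedProtein(
        entry=ProteinEntry(accession="A1"),
        go_union=go,
        go_sources={g: frozenset({"uniprot"}) for g in go},
        experimental_evidence_go=frozenset(experimental),
        topology=topo,
    )


class TestInterest:
    def test_surface_go_with_globular_topology(self, catalog):
        ok, classes, via = classify_interest(
            _protein({"GO:0009986"}, ProteinType.GLOB), catalog
        )
        assert ok and classes == {"CS"} and not via

    def test_es_alone_globular_not_interest(self, catalog):
        ok, _, via = classify_interest(_protein({"GO:0005615"}, ProteinType.GLOB), catalog)
        assert not ok and not via

    def test_es_alone_transmembrane_is_interest(self, catalog):
        ok, classes, via = classify_interest(
            _protein({"GO:0005615"}, ProteinType.TM), catalog
        )
        assert ok and via and classes == {"ES"}

    def test_no_relevant_go(self, catalog):
        ok, classes, _ = classify_interest(_protein({"GO:0008150"}, ProteinType.TM), catalog)
        assert not ok and classes == frozenset()


class TestTarget:
    def test_surface_branch_ignores_topology(self, catalog):
        # signal-peptide-only protein with surface annotation is a target
        call = classify_target(
            _protein(
                {"GO:0009986", "GO:0005886", "GO:0009897", "GO:0046658", "GO:0031362"},
                ProteinType.GLOB_SP,
            ),
            catalog,
        )
        assert call.is_target and "CS" in call.triggering_classes

    def test_membrane_branch_requires_tm(self, catalog):
        glob = classify_target(_protein({"GO:0005886"}, ProteinType.GLOB), catalog)
        assert glob.of_interest and not glob.is_target
        tm = classify_target(_protein({"GO:0005886"}, ProteinType.TM), catalog)
        assert tm.is_target and tm.triggering_classes == {"PM"}

    def test_es_tm_route_is_target(self, catalog):
        call = classify_target(_protein({"GO:0005615"}, ProteinType.TM), catalog)
        assert call.is_target and call.via_es_tm and call.triggering_classes == {"ES"}

    def test_beta_counts_as_transmembrane(self, catalog):
        call = classify_target(_protein({"GO:0005886"}, ProteinType.BETA), catalog)
        assert call.is_target

    def test_missing_topology_treated_as_non_tm_and_flagged(self, catalog):
        call = classify_target(_protein({"GO:0005886"}, None), catalog)
        assert not call.is_target and call.topology_missing

    def test_experimental_support_requires_triggering_go(self, catalog):
        supported = classify_target(
            _protein({"GO:0009986"}, ProteinType.GLOB, experimental={"GO:0009986"}),
            catalog,
        )
        assert supported.experimental_support
        # experimental evidence on a non-triggering ID does not count
        unsupported = classify_target(
            _protein(
                {"GO:0009986", "GO:0005615"}, ProteinType.GLOB,
                experimental={"GO:0005615"},
            ),
            catalog,
        )
        assert unsupported.is_target and not unsupported.experimental_support

    def test_target_implies_interest_always(self, catalog):
        fixture, _ = generate_proteome(SimConfig(n_genes=150, seed=13))
        kept, _ = filter_redundant(fixture.entries, fixture.mapping)
        annotated = merge_annotations(
            kept, filter_eggnog_hits(fixture.eggnog), fixture.topology
        )
        calls, _ = screen_proteome(annotated, catalog)
        assert all(c.of_interest for c in calls if c.is_target)

    def test_adding_surface_go_is_monotone(self, catalog):
        for ptype in (ProteinType.GLOB, ProteinType.TM, ProteinType.GLOB_SP):
            for base in ({"GO:0005886"}, {"GO:0008150"}, set()):
                before = classify_target(_protein(base, ptype), catalog)
                after = classify_target(_protein(base | {"GO:0009986"}, ptype), catalog)
                assert after.is_target >= before.is_target

    def test_surface_branch_invariant_to_topology(self, catalog):
        calls = {
            ptype: classify_target(_protein({"GO:0009986"}, ptype), catalog).is_target
            for ptype in ProteinType
        }
        assert all(calls.values())


class TestScreen:
    def test_empty_proteome(self, catalog):
        calls, summary = screen_proteome([], catalog)
        assert calls == [] and summary.n_target == 0 and summary.n_interest == 0

    def test_planted_labels_recovered(self, catalog):
        fixture, ledger = generate_proteome(SimConfig(n_genes=300, seed=21))
        kept, _ = filter_redundant(fixture.entries, fixture.mapping)
        annotated = merge_annotations(
            kept, filter_eggnog_hits(fixture.eggnog), fixture.topology
        )
        calls, summary = screen_proteome(annotated, catalog)
        assert {c.accession for c in calls if c.is_target} == ledger.expected_targets
        assert {c.accession for c in calls if c.of_interest} == ledger.expected_interest
        assert summary.n_target == len(ledger.expected_targets)


class TestPublishedRowEncoding:
    @pytest.mark.parametrize(
        "label,expected",
        [("TM", ProteinType.TM), ("SP+TM", ProteinType.TM_SP),
         ("SP", ProteinType.GLOB_SP), ("GLOB", ProteinType.GLOB)],
    )
    def test_topology_label_mapping(self, label, expected, catalog):
        p = encode_published_row("X1", label, ("PM",), catalog)
        assert p.topology.protein_type is expected

    def test_class_abbreviations_round_trip(self, catalog):
        p = encode_published_row("X1", "TM", ("PM", "CS", "ES"), catalog)
        assert catalog.classes_for(p.go_union) == {"PM", "CS"}
        assert catalog.es_id in p.go_union
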