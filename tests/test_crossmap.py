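"""Cross-species mapping: store lookups, isoform choice, curation rules."""

import pytest

from surfscreen.crossmap import (
    CrossMapOutcome,
    CrossSpeciesConfig,
    CurationRecord,
    GeneProductSet,
    Product,
    SequenceStore,
    apply_curation,
    fetch_gene_products,
    map_targets_across_species,
    match_unnamed_via_eggnog,
    select_isoform,
)
from surfscreen.model import AnnotatedProtein, ProteinEntry
from surfscreen.simulate import SimConfig, generate_crossmap_fixture


@pytest.fixture()
def store():
    s = SequenceStore()
    s.add_product("speciesA", "GENE1", "NP_000001", "protein one isoform 1",
                  "MKTAYIAKQRGH", chromosome="X")
    s.add_product("speciesA", "GENE1", "XP_000002", "protein one isoform X1",
                  "MKTAYIAKQRGHMKT", chromosome="X")
    s.add_product("speciesB", "GENE1", "XP_900001", "protein one isoform X1",
                  "MKTAYIAKQRGW", chromosome="X")
    s.add_product("speciesA", "GENE2", "NP_000003", "protein two",
                  "WWTAYIAKQRGH", chromosome="X", aliases=["GENE2ALT"])
    return s


class TestStore:
    def test_two_isoforms_returned(self, store):
        res = fetch_gene_products("GENE1", "speciesA", store)
        assert res.status == "ok" and len(res.products) == 2

    def test_alias_only_flagged_not_accepted(self, store):
        res = fetch_gene_products("GENE2ALT", "speciesA", store)
        assert res.status == "alias_only" and res.alias_of == "GENE2"
        assert res.products == []

    def test_missing_gene_not_found(self, store):
        res = fetch_gene_products("NOPE", "speciesA", store)
        assert res.status == "not_found" and res.products == []

    def test_round_trip_through_directory(self, store, tmp_path):
        store.to_dir(tmp_path / "store")
        back = SequenceStore.from_dir(tmp_path / "store")
        orig = fetch_gene_products("GENE1", "speciesA", store)
        rt = fetch_gene_products("GENE1", "speciesA", back)
        assert {(p.refseq_id, p.sequence) for p in orig.products} == {
            (p.refseq_id, p.sequence) for p in rt.products
        }
        assert back.chromosome("speciesA", "GENE2") == "X"
        assert fetch_gene_products("GENE2ALT", "speciesA", back).status == "alias_only"


class TestIsoformSelection:
    def _set(self, products):
        return GeneProductSet(gene_name="G", species="s", products=products)

    def test_x1_preferred_over_isoform_1(self):
        chosen, _ = select_isoform(self._set([
            Product("P2", "thing isoform 1", "AA"),
            Product("P1", "thing isoform X1", "CC"),
        ]))
        assert chosen == "P1"

    def test_isoform_1_over_longest(self):
        chosen, _ = select_isoform(self._set([
            Product("P1", "thing isoform 1", "AA"),
            Product("P2", "unlabeled", "AAAAAAAAAA"),
        ]))
        assert chosen == "P1"

    def test_longest_when_unlabeled(self):
        chosen, _ = select_isoform(self._set([
            Product("P1", "a", "AAA"),
            Product("P2", "b", "AAAAA"),
        ]))
        assert chosen == "P2"

    def test_isoform_10_does_not_match_isoform_1(self):
        chosen, _ = select_isoform(self._set([
            Product("P1", "thing isoform 10", "AA"),
            Product("P2", "thing isoform 1", "CC"),
        ]))
        assert chosen == "P2"

    def test_equal_length_tie_breaks_lexicographically(self):
        chosen, _ = select_isoform(self._set([
            Product("P2", "b", "AAAAA"),
            Product("P1", "a", "CCCCC"),
        ]))
        assert chosen == "P1"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            select_isoform(self._set([]))


class TestMapping:
    def test_synthetic_fixture_category_recovery(self):
        fixture, ledger = generate_crossmap_fixture(SimConfig(n_genes=300, seed=2))
        outcomes = map_targets_across_species(
            fixture.ref_targets, fixture.query_proteome, fixture.query_targets,
            fixture.store,
        )
        outcomes = apply_curation(outcomes, fixture.curation)
        got = {o.gene_name: (o.category, o.exclusion_reason) for o in outcomes}
        assert got == ledger.expected_outcomes

    def test_absent_gene_unresolved(self, store):
        (o,) = map_targets_across_species(
            [("NOPE", "missing protein")], [], [], store,
            CrossSpeciesConfig(reference_species="speciesA"), query_species="speciesB",
        )
        assert o.category == "unresolved" and o.similarity_pct is None

    def test_divergent_ortholog_flagged_for_review(self):
        fixture, _ = generate_crossmap_fixture(SimConfig(n_genes=300, seed=2))
        outcomes = map_targets_across_species(
            fixture.ref_targets, fixture.query_proteome, fixture.query_targets,
            fixture.store,
        )
        low = [o for o in outcomes if o.gene_name.startswith("LOW")]
        assert low and all(o.needs_review for o in low)
        assert all(o.similarity_pct < 70 for o in low)
        ok = [o for o in outcomes if o.gene_name.startswith("ADD")]
        assert ok and not any(o.needs_review for o in ok)


class TestCuration:
    def _candidate(self, gene):
        return CrossMapOutcome(gene_name=gene, category="additional_candidate")

    def test_wrong_chromosome_excluded(self):
        (o,) = apply_curation(
            [self._candidate("IL3")],
            [CurationRecord(gene_name="IL3", chromosome="2")],
            target_chromosome="X",
        )
        assert o.category == "excluded" and o.exclusion_reason == "other_chromosome"

    def test_unplaced_not_excluded(self):
        (o,) = apply_curation(
            [self._candidate("G")],
            [CurationRecord(gene_name="G", chromosome="Unplaced")],
        )
        assert o.category == "additional_candidate"

    def test_removed_entry_excluded_first(self):
        (o,) = apply_curation(
            [self._candidate("G")],
            [CurationRecord(gene_name="G", removed_from_source=True, chromosome="2")],
        )
        assert o.exclusion_reason == "removed_entry"

    def test_non_ortholog_with_identical_flanks_retained(self):
        flanks = ("LPAR4", "A", "B", "C", "D", "GPR174")
        (o,) = apply_curation(
            [self._candidate("P2Y")],
            [CurationRecord(gene_name="P2Y", ortholog_confirmed=False,
                            flanking_genes_query=flanks,
                            flanking_genes_subject=flanks)],
        )
        assert o.category == "additional_candidate"

    def test_non_ortholog_different_flanks_excluded(self):
        (o,) = apply_curation(
            [self._candidate("G")],
            [CurationRecord(gene_name="G", ortholog_confirmed=False,
                            flanking_genes_query=("A", "B"),
                            flanking_genes_subject=("A", "C"))],
        )
        assert o.exclusion_reason == "not_ortholog"

    def test_alias_of_shared_product_excluded(self):
        outcomes = [self._candidate("OPN1"), self._candidate("OPN2")]
        records = [
            CurationRecord(gene_name="OPN1", chromosome="X"),
            CurationRecord(gene_name="OPN2", chromosome="X",
                           maps_to_same_product_as="OPN1", is_alias_mapping=True),
        ]
        kept = apply_curation(outcomes, records)
        assert kept[0].category == "additional_candidate"
        assert kept[1].exclusion_reason == "duplicate_mapping"

    def test_missing_record_leaves_outcome_unchanged(self):
        (o,) = apply_curation([self._candidate("G")], [])
        assert o.category == "additional_candidate"


class TestEggnogNameMatching:
    def _unnamed(self, acc, eggnog_name):
        return AnnotatedProtein(
            entry=ProteinEntry(accession=acc, gene_name=None), eggnog_name=eggnog_name
        )

    def test_match_emitted_case_insensitive(self):
        candidates = [CrossMapOutcome(gene_name="MMGT1", category="additional_candidate")]
        (m,) = match_unnamed_via_eggnog([self._unnamed("A1", "mmgt1")], candidates)
        assert m.candidate_gene == "MMGT1" and m.accession == "A1"
        assert m.needs_similarity_check

    def test_no_unnamed_entries(self):
        assert match_unnamed_via_eggnog(
            [], [CrossMapOutcome(gene_name="G", category="additional_candidate")]
        ) == []

    def test_planted_eggnog_only_names_recovered(self):
        candidates = [
            CrossMapOutcome(gene_name=g, category="additional_candidate")
            for g in ("AAA1", "BBB2", "CCC3")
        ]
        unnamed = [
            self._unnamed("U1", "AAA1"),
            self._unnamed("U2", "BBB2"),
            self._unnamed("U3", "CCC3"),
            self._unnamed("U4", "ZZZ9"),  # no candidate
        ]
        named = AnnotatedProtein(
            entry=ProteinEntry(accession="U5", gene_name="AAA1"), eggnog_name="AAA1"
        )
        matches = match_unnamed_via_eggnog(unnamed + [named], candidates)
        assert {(m.candidate_gene, m.accession) for m in matches} == {
            ("AAA1", "U1"), ("BBB2", "U2"), ("CCC3", "U3")
        }
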