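"""Affine-gap global aligner and the percent-similarity statistic.

Two independent oracles back the aligner: brute-force enumeration of
every global alignment (small inputs), and Biopython's PairwiseAligner
as a cross-check on the optimal score.
"""

import random

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from hypothesis import given, strategies as st

from surfscreen.alignment import (
    AlignmentInputError,
    AlignmentParams,
    AlignmentResult,
    DegenerateAlignmentError,
    global_align,
    global_score,
    similarity_score,
)
from surfscreen.simulate import AMINO_ACIDS, mutate_sequence

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_best_score(a, b, open_=-11.0, ext=-1.0):
    """Score of the best global alignment by exhaustive path enumeration."""
    best = [-np.inf]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "D")
        if i < len(a):
            rec(i + 1, j, score + (ext if last == "U" else open_), "U")
        if j < len(b):
            rec(i, j + 1, score + (ext if last == "L" else open_), "L")

    rec(0, 0, 0.0, "")
    return best[0]


class TestScores:
    def test_self_alignment_scores_diagonal_sum(self):
        seq = "MKTAYIAK"
        r = global_align(seq, seq)
        assert r.score == sum(BLOSUM62[c, c] for c in seq)
        assert r.matches == len(seq) and r.indel_columns == 0
        assert r.similarity_pct == 100.0

    def test_single_substitution(self):
        r = global_align("ACDEFGHIK", "ACDEFGHIR")
        assert (r.matches, r.aln_length, r.indel_columns) == (8, 9, 0)
        assert r.similarity_pct == pytest.approx(800 / 9)

    def test_gap_cost_accounting(self):
        # forcing a single 2-residue gap: open + extend
        a, b = "MKTAYIAKQRGH", "MKTAYKQRGH"
        r = global_align(a, b)
        assert r.aligned_subject.count("-") == 2
        no_gap_score = sum(BLOSUM62[c, c] for c in b)
        assert r.score == no_gap_score - 11 - 1

    def test_matches_enumeration_oracle_small(self):
        rng = random.Random(7)
        alphabet = "ACDE"
        for _ in range(150):
            a = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 6)))
            assert global_score(a, b) == pytest.approx(enumerate_best_score(a, b))

    def test_matches_biopython_score(self):
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = BLOSUM62
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list(AMINO_ACIDS), size=120))
        for seed in range(10):
            other, _ = mutate_sequence(base, 0.15, 0.03, seed)
            assert global_score(base, other) == pytest.approx(aligner.score(base, other))

    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
    )
    def test_score_symmetry(self, a, b):
        assert global_score(a, b) == pytest.approx(global_score(b, a))

    def test_unknown_residues_scored_fixed(self):
        # U is outside the BLOSUM62 alphabet: -1 against everything
        r = global_align("MU", "MU")
        assert r.score == BLOSUM62["M", "M"] - 1

    def test_invalid_character_names_position(self):
        with pytest.raises(AlignmentInputError, match="position 3"):
            global_align("MK1T", "MKT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentInputError):
            global_align("", "MKT")


class TestSimilarity:
    def test_substitutions_only_closed_form(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=200))
        for seed in range(5):
            mutated, ledger = mutate_sequence(seq, 0.08, 0.0, seed)
            r = global_align(seq, mutated)
            if r.indel_columns == 0:  # substitution costs < gap costs: diagonal
                expected = 100 * (len(seq) - ledger["n_sub"]) / len(seq)
                assert r.similarity_pct == pytest.approx(expected)

    def test_all_matching_non_indel_columns(self):
        r = AlignmentResult(
            query_id="q", subject_id="s", score=0.0,
            aligned_query="MKTAYIAK--", aligned_subject="--TAYIAKQR",
            aln_length=10, matches=6, indel_columns=4, similarity_pct=0.0,
        )
        assert similarity_score(r) == 100.0

    def test_zero_matches(self):
        r = global_align("AAAA", "WWWW")
        assert r.matches == 0 and r.similarity_pct == 0.0

    def test_column_recount_oracle(self):
        rng = np.random.default_rng(19)
        base = "".join(rng.choice(list(AMINO_ACIDS), size=150))
        for seed in range(8):
            other, _ = mutate_sequence(base, 0.2, 0.05, seed)
            r = global_align(base, other)
            matches = sum(
                x == y and x != "-"
                for x, y in zip(r.aligned_query, r.aligned_subject)
            )
            gap_cols = sum(
                "-" in (x, y) for x, y in zip(r.aligned_query, r.aligned_subject)
            )
            assert not any(
                x == y == "-" for x, y in zip(r.aligned_query, r.aligned_subject)
            )
            assert r.matches == matches and r.indel_columns == gap_cols
            assert r.similarity_pct == pytest.approx(
                100 * matches / (r.aln_length - gap_cols)
            )

    def test_degenerate_alignment_rejected(self):
        r = AlignmentResult(
            query_id="q", subject_id="s", score=0.0,
            aligned_query="A-", aligned_subject="-A",
            aln_length=2, matches=0, indel_columns=2, similarity_pct=0.0,
        )
        with pytest.raises(DegenerateAlignmentError):
            similarity_score(r)

    def test_gap_event_metric_option(self):
        r = AlignmentResult(
            query_id="q", subject_id="s", score=0.0,
            aligned_query="MKT--AYIAK", aligned_subject="MKTAAAYIAK",
            aln_length=10, matches=8, indel_columns=2, similarity_pct=0.0,
        )
        assert similarity_score(r) == 100.0  # columns metric: 8/8
        events = similarity_score(r, AlignmentParams(indel_metric="events"))
        assert events == pytest.approx(100 * 8 / 9)


class TestParams:
    def test_gap_param_ordering_enforced(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=-1, gap_extend=-11)

    def test_semiglobal_frees_end_gaps(self):
        # a short probe inside a longer sequence: semiglobal pays no end gaps
        probe, long_seq = "AYIAK", "MKTAYIAKQRGH"
        semi = global_align(probe, long_seq, AlignmentParams(mode="semiglobal"))
        assert semi.score == sum(BLOSUM62[c, c] for c in probe)
        glob = global_align(probe, long_seq)
        assert glob.score < semi.score
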