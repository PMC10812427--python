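"""Global pairwise protein alignment with affine gaps, and the similarity
statistic computed from it.

The aligner is a Gotoh three-state dynamic program (match state plus one
insertion state per sequence) under BLOSUM62 scoring with gap open -11 and
gap extend -1: a gap of length ``g`` costs ``open + (g-1)*extend``, and end
gaps are penalised like internal ones (true global alignment; a semiglobal
variant with free end gaps is available behind ``mode="semiglobal"``).
Traceback is deterministic with tie order diagonal > up > left.

The similarity percentage is ``100 * matches / (alignment length - indel
columns)`` — percent identity over the residue-residue columns of the
optimal alignment.  An alternative denominator counting gap *events*
instead of gap columns is available via ``indel_metric="events"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e12
_TOL = 1e-9


class AlignmentInputError(ValueError):
    """A sequence contains a character the scorer cannot accept."""


class DegenerateAlignmentError(ValueError):
    """The alignment has no residue-residue columns; similarity undefined."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters: substitution matrix name and affine gap costs."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    mode: str = "global"  # or "semiglobal" (free end gaps)
    #: score for residue pairs involving letters absent from the matrix
    unknown_score: float = -1.0
    indel_metric: str = "columns"  # or "events"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.mode not in ("global", "semiglobal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.indel_metric not in ("columns", "events"):
            raise ValueError(f"unknown indel metric {self.indel_metric!r}")


@dataclass(frozen=True)
class AlignmentResult:
    """An aligned pair with its score and column statistics."""

    query_id: str
    subject_id: str
    score: float
    aligned_query: str
    aligned_subject: str
    aln_length: int
    matches: int
    indel_columns: int
    similarity_pct: float


@lru_cache(maxsize=4)
def _score_table(matrix_name: str, unknown_score: float) -> np.ndarray:
    """26x26 substitution-score lookup indexed by ``ord(ch) - ord('A')``.

    Letters outside the matrix alphabet score ``unknown_score`` against
    everything, including themselves.
    """
    mat = substitution_matrices.load(matrix_name)
    table = np.full((26, 26), float(unknown_score))
    letters = [c for c in mat.alphabet if c.isalpha()]
    for a in letters:
        for b in letters:
            table[ord(a) - 65, ord(b) - 65] = float(mat[a, b])
    return table


def _encode(seq: str, name: str) -> np.ndarray:
    s = seq.upper()
    codes = np.frombuffer(s.encode("ascii", errors="replace"), dtype=np.uint8).astype(int) - 65
    bad = np.nonzero((codes < 0) | (codes > 25))[0]
    if bad.size:
        pos = int(bad[0])
        raise AlignmentInputError(f"{name}: invalid residue {seq[pos]!r} at position {pos + 1}")
    return codes


def global_align(
    a: str,
    b: str,
    params: AlignmentParams = AlignmentParams(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal affine-gap alignment of ``a`` (query) against ``b`` (subject)."""
    if not a or not b:
        raise AlignmentInputError("sequences must be non-empty")
    ca, cb = _encode(a, query_id), _encode(b, subject_id)
    table = _score_table(params.substitution_matrix, params.unknown_score)
    sub = table[np.ix_(ca, cb)]  # (la, lb) pair scores
    open_, ext = float(params.gap_open), float(params.gap_extend)
    semiglobal = params.mode == "semiglobal"
    la, lb = len(ca), len(cb)

    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)  # gap in query (left moves)
    Iy = np.full((la + 1, lb + 1), NEG)  # gap in subject (up moves)
    M[0, 0] = 0.0
    j = np.arange(1, lb + 1)
    Ix[0, 1:] = 0.0 if semiglobal else open_ + ext * (j - 1)

    jj = np.arange(lb + 1)
    for i in range(1, la + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub[i - 1] + best_prev[:-1]
        Iy[i] = np.maximum(np.maximum(M[i - 1], Ix[i - 1]) + open_, Iy[i - 1] + ext)
        if semiglobal:
            Iy[i, 0] = 0.0
        base = np.maximum(M[i], Iy[i])
        run = np.maximum.accumulate(base - ext * jj)
        Ix[i, 1:] = open_ - ext + ext * jj[1:] + run[:-1]

    if semiglobal:
        # free trailing gaps: best boundary cell, then pad
        end_i, end_j, state, score = _best_boundary(M, Ix, Iy, la, lb)
        core_a, core_b = _traceback(a.upper(), b.upper(), sub, M, Ix, Iy, open_, ext,
                                    end_i, end_j, state)
        aligned_a = core_a + a.upper()[end_i:] + "-" * (lb - end_j)
        aligned_b = core_b + "-" * (la - end_i) + b.upper()[end_j:]
    else:
        state, score = _state_at(M, Ix, Iy, la, lb)
        aligned_a, aligned_b = _traceback(
            a.upper(), b.upper(), sub, M, Ix, Iy, open_, ext, la, lb, state
        )
    return _finish(query_id, subject_id, score, aligned_a, aligned_b, params)


def _state_at(M, Ix, Iy, i, j):
    # state preference on ties: M (diagonal) > Iy (up) > Ix (left)
    vals = (M[i, j], Iy[i, j], Ix[i, j])
    best = max(vals)
    for state, v in zip("MYX", vals):
        if math.isclose(v, best, abs_tol=_TOL):
            return state, best
    raise AssertionError("unreachable")


def _best_boundary(M, Ix, Iy, la, lb):
    best = (0, 0, "M", NEG)
    for i in range(la + 1):
        state, val = _state_at(M, Ix, Iy, i, lb)
        if val > best[3] + _TOL:
            best = (i, lb, state, val)
    for j in range(lb + 1):
        state, val = _state_at(M, Ix, Iy, la, j)
        if val > best[3] + _TOL:
            best = (la, j, state, val)
    return best


def _traceback(a, b, sub, M, Ix, Iy, open_, ext, i, j, state):
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if j == 0:  # only up-moves remain
            state = "Y"
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        if i == 0:  # only left-moves remain
            state = "X"
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            continue
        if state == "M":
            assert i > 0 and j > 0
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _match_state(M, Ix, Iy, i, j, target)
        elif state == "Y":  # up: a-residue against gap in subject
            assert i > 0
            out_a.append(a[i - 1])
            out_b.append("-")
            val = Iy[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if math.isclose(val, M[i, j] + open_, abs_tol=_TOL):
                state = "M"
            elif math.isclose(val, Iy[i, j] + ext, abs_tol=_TOL):
                state = "Y"
            else:
                state = "X"
        else:  # "X", left: b-residue against gap in query
            assert j > 0
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Ix[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if math.isclose(val, M[i, j] + open_, abs_tol=_TOL):
                state = "M"
            elif math.isclose(val, Ix[i, j] + ext, abs_tol=_TOL):
                state = "X"
            else:
                state = "Y"
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _match_state(M, Ix, Iy, i, j, target):
    for state, grid in (("M", M), ("Y", Iy), ("X", Ix)):
        if math.isclose(grid[i, j], target, abs_tol=_TOL):
            return state
    raise AssertionError(f"traceback lost at ({i},{j})")


def _finish(query_id, subject_id, score, aligned_a, aligned_b, params) -> AlignmentResult:
    aln_len = len(aligned_a)
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    indel_cols = sum(x == "-" or y == "-" for x, y in zip(aligned_a, aligned_b))
    result = AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        aligned_query=aligned_a,
        aligned_subject=aligned_b,
        aln_length=aln_len,
        matches=matches,
        indel_columns=indel_cols,
        similarity_pct=0.0,
    )
    return AlignmentResult(
        **{**result.__dict__, "similarity_pct": similarity_score(result, params)}
    )


def _gap_events(aligned: str) -> int:
    events, inside = 0, False
    for c in aligned:
        if c == "-" and not inside:
            events, inside = events + 1, True
        elif c != "-":
            inside = False
    return events


def similarity_score(
    r: AlignmentResult, params: AlignmentParams = AlignmentParams()
) -> float:
    """Percent similarity: matches over non-indel alignment columns.

    With ``indel_metric="events"`` the denominator subtracts the number of
    gap runs instead of gap columns (a documented alternative reading; it
    can exceed 100 and is off by default).
    """
    if params.indel_metric == "columns":
        denom = r.aln_length - r.indel_columns
    else:
        denom = r.aln_length - _gap_events(r.aligned_query) - _gap_events(r.aligned_subject)
    if denom <= 0:
        raise DegenerateAlignmentError(
            f"{r.query_id}/{r.subject_id}: no residue-residue columns"
        )
    return 100.0 * r.matches / denom


def global_score(a: str, b: str, params: AlignmentParams = AlignmentParams()) -> float:
    """Optimal alignment score only (convenience for property checks)."""
    return global_align(a, b, params).score
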