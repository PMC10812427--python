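"""GO-term overrepresentation statistics.

For a sample of ``n`` accessions drawn from a reference of ``N``, a term
annotating ``k`` of the sample and ``K`` of the reference has fold
enrichment ``FE = (k/n)/(K/N)``.  Significance is a one-sided Fisher exact
(hypergeometric tail) test — ``P[X >= k]`` for overrepresentation,
``P[X <= k]`` for underrepresentation, ``X ~ Hypergeometric(N, K, n)`` —
with Bonferroni correction over the number of terms tested.  Tails are
computed through :mod:`scipy.stats`'s log-space hypergeometric survival /
distribution functions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .model import EnrichmentResult


class UndefinedEnrichmentError(ValueError):
    """Fold enrichment is undefined (empty sample or unannotated reference)."""


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Sample annotation rate over reference annotation rate."""
    _check_table(k, n, K, N)
    if n == 0 or K == 0:
        raise UndefinedEnrichmentError(f"FE undefined for n={n}, K={K}")
    return (k / n) / (K / N)


def fisher_exact_p(k: int, n: int, K: int, N: int, direction: str = "over") -> float:
    """One-sided hypergeometric tail probability for a 2x2 table."""
    _check_table(k, n, K, N)
    if direction == "over":
        return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))
    if direction == "under":
        return float(min(1.0, hypergeom.cdf(k, N, K, n)))
    raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")


def _check_table(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and n <= N and K <= N and N > 0):
        raise ValueError(f"invalid contingency table k={k}, n={n}, K={K}, N={N}")
    if k < n - (N - K):
        raise ValueError(f"infeasible table k={k}, n={n}, K={K}, N={N}")


def overrepresentation_test(
    sample: Iterable[str],
    annotation: Mapping[str, set[str] | frozenset[str]],
    reference: set[str] | frozenset[str],
    alpha: float = 0.05,
    direction: str = "auto",
) -> list[EnrichmentResult]:
    """Test every annotated term for over/underrepresentation in the sample.

    ``direction="auto"`` tests each term on the side of its observed
    deviation (the convention of enrichment-service reports); ``"over"`` or
    ``"under"`` fixes one side for all terms, which is the calibrated
    choice for type-I-error studies.  ``p_adjusted = min(1, p * m)`` with
    ``m`` the number of terms tested in the run.
    """
    sample_set = set(sample)
    reference = set(reference)
    stray = sample_set - reference
    if stray:
        raise ValueError(f"sample accessions outside the reference: {sorted(stray)}")
    n, N = len(sample_set), len(reference)

    tested: list[tuple[str, int, int]] = []
    for term in sorted(annotation):
        members = set(annotation[term]) & reference
        K = len(members)
        k = len(members & sample_set)
        if k >= 1 or K >= 1:
            tested.append((term, k, K))
    m = len(tested)

    results: list[EnrichmentResult] = []
    for term, k, K in tested:
        fe = fold_enrichment(k, n, K, N) if (K > 0 and n > 0) else float("nan")
        side = direction
        if side == "auto":
            side = "over" if fe >= 1 else "under"
        p = fisher_exact_p(k, n, K, N, side)
        p_adj = min(1.0, p * m)
        results.append(
            EnrichmentResult(
                term=term,
                k=k,
                n=n,
                K=K,
                N=N,
                fold_enrichment=fe,
                p_raw=p,
                p_adjusted=p_adj,
                direction=side,
                significant=p_adj < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.term))
    return results
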