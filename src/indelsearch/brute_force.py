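"""Exhaustive baseline for the indel substructure search.

For a text of size N, a query of size m and an indel budget k, the naive
algorithm tries every start position, every split of the budget into k'
query-side and k'' text-side deletions, and every pair of deletion index
sets, computing each RMSD directly.  Its cost is O(N * m^(k+1)) but it is
trivially correct, which makes it the ground-truth oracle for every test of
the filter-and-verify engine.  No pruning is (or should ever be) added
here.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterator

import numpy as np

from .core_geometry import Chain, _rmsd_arrays
from .indel_search import MatchReport, SearchParams

__all__ = ["reduced_subsequences", "naive_search", "pair_count", "BudgetExceededError"]

DEFAULT_MAX_EVALS = 10_000_000


class BudgetExceededError(RuntimeError):
    """Raised when the oracle exceeds its RMSD-evaluation cap."""


def reduced_subsequences(S: Chain, k: int) -> Iterator[tuple[tuple[int, ...], Chain]]:
    """All k-reduced subsequence structures of ``S``.

    Yields every set of ``k`` deleted 0-based indices in lexicographic
    order, together with the induced subchain (residue order preserved).
    There are C(|S|, k) items; they are streamed, never materialized.
    """
    n = len(S)
    if not 0 <= k < n:
        raise ValueError(f"deletion count must satisfy 0 <= k < |S|, got k={k}, |S|={n}")
    for dels in combinations(range(n), k):
        yield dels, S.delete(dels)


def pair_count(m: int, window_limit: int, k: int) -> int:
    """Number of (deletion-set, deletion-set) RMSD evaluations at one position.

    ``window_limit`` is the number of text residues available from the
    position to the end of its structure; splits whose window does not fit
    are excluded, matching the enumeration of :func:`naive_search`.
    """
    total = 0
    for kq in range(k + 1):
        for kt in range(k - kq + 1):
            L = m - kq + kt
            if L <= window_limit:
                total += comb(m, kq) * comb(L, kt)
    return total


def naive_search(
    P: Chain,
    Q: Chain,
    params: SearchParams,
    *,
    max_evals: int = DEFAULT_MAX_EVALS,
) -> list[MatchReport]:
    """Exhaustive search of ``P`` for indel-tolerant matches of ``Q``.

    Returns one report per matching position ``i`` (1-based,
    ``1 <= i <= N - m + k + 1``), carrying the minimum-RMSD witness; among
    equal-RMSD witnesses the lexicographically smallest
    (k', k'', query deletions, text deletions) is kept, because the
    enumeration visits them in that order and only strict improvements
    replace the incumbent.
    """
    k = params.k
    c = params.c
    N, m = len(P), len(Q)
    params.validate_for_query(m)
    if m > N:
        raise ValueError(f"query (m={m}) longer than text (N={N})")
    Qarr = Q.coords
    Parr = P.coords
    # reduced queries and text-side keep-index sets, enumerated once, lex order
    reduced_queries = {
        kq: [(dels, np.delete(Qarr, dels, axis=0)) for dels in combinations(range(m), kq)]
        for kq in range(k + 1)
    }
    keep_sets: dict[tuple[int, int], list] = {}
    for kq in range(k + 1):
        for kt in range(k - kq + 1):
            L = m - kq + kt
            if (L, kt) not in keep_sets:
                keep_sets[(L, kt)] = [
                    (dels, np.array([x for x in range(L) if x not in dels], dtype=np.intp))
                    for dels in combinations(range(L), kt)
                ]
    evals = 0
    reports: list[MatchReport] = []
    for i in range(1, N - m + k + 2):
        best: tuple | None = None  # (rmsd, kq, kt, qdels, tdels)
        for kq in range(k + 1):
            for kt in range(k - kq + 1):
                L = m - kq + kt
                if i - 1 + L > N:
                    continue
                window = Parr[i - 1 : i - 1 + L]
                for qdels, Qred in reduced_queries[kq]:
                    for tdels, keep in keep_sets[(L, kt)]:
                        evals += 1
                        if evals > max_evals:
                            raise BudgetExceededError(
                                f"naive search exceeded {max_evals} RMSD evaluations"
                            )
                        r = _rmsd_arrays(Qred, window[keep])
                        if best is None or r < best[0]:
                            best = (r, kq, kt, qdels, tdels)
        if best is not None and best[0] <= c:
            r, kq, kt, qdels, tdels = best
            reports.append(
                MatchReport(
                    structure_id=P.label,
                    position=i,
                    k_prime=kq,
                    k_double_prime=kt,
                    query_deletions=tuple(d + 1 for d in qdels),
                    text_deletions=tuple(d + 1 for d in tdels),
                    rmsd=r,
                )
            )
    return reports
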