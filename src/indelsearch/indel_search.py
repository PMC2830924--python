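"""Filter-and-verify substructure search with an indel budget.

Problem.  Given a text chain P of size N, a query chain Q of size m, an
RMSD threshold c and an indel budget k < m, report every position i
(1 <= i <= N - m + k + 1) such that some k'-reduced subsequence structure
of Q superposes onto some k''-reduced subsequence structure of the window
P[i .. i - k' + k'' + m - 1] with RMSD <= c, for some k' + k'' <= k.

Algorithm.  The query is cut into 3k + 2 equal-length divided substructures
of size m' = floor(m / (3k + 2)) (plus a short unused remainder).  If the
query matches at position i, then in any witnessing alignment at most k of
the divided substructures can contain an indel and at most k more can be
shifted across a part boundary, so at least 2k + 2 of them survive
*ungapped*: they appear verbatim as length-m' text windows within k
positions of their nominal offset, and the subsequence bound
RMSD(sub) <= sqrt(m/m') * RMSD(full) caps their deviation.  Replacing the
RMSD by its O(1) half-split lower bound D gives a filter (Constraint 2)
whose per-position test costs O(k^2) after an O(N) sliding-table pass:
positions with fewer than 2k + 2 "hit" substructures cannot match and are
discarded; the survivors are verified exhaustively.  Under the random-walk
model of chain molecules the expected number of survivors is
O(N / m^(k+1)), which makes the whole search average-case linear in N
while remaining exact — the output is identical to the brute-force scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import sqrt
from typing import TYPE_CHECKING, Union

import numpy as np

from .core_geometry import Chain, _rmsd_arrays
from .lower_bound import WindowFTable, build_window_table, half_split_statistic

if TYPE_CHECKING:  # pragma: no cover
    from .io import StructureDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "QueryDivision",
    "HitProfile",
    "MatchReport",
    "SearchStats",
    "QueryTooShortError",
    "divide_query",
    "constraint2_threshold",
    "constraint2_hit",
    "enumerate_candidates",
    "verify_candidate",
    "search",
]


class QueryTooShortError(ValueError):
    """The query is too short to be divided into 3k+2 parts of length >= 2.

    Callers should fall back to the brute-force engine (``search`` does so
    transparently).
    """


@dataclass(frozen=True)
class SearchParams:
    """Search thresholds: RMSD bound ``c`` (distance units) and indel budget ``k``."""

    c: float
    k: int

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"RMSD threshold c must be positive, got {self.c}")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 0):
            raise ValueError(f"indel budget k must be a non-negative integer, got {self.k}")

    def validate_for_query(self, m: int) -> None:
        if not self.k < m:
            raise ValueError(f"indel budget k={self.k} must be smaller than the query size m={m}")


@dataclass(frozen=True)
class QueryDivision:
    """The 3k+2 equal-length divided substructures of a query.

    ``parts[j-1]`` is Q[(j-1)m'+1 .. j*m'] (1-based residue ranges) with
    m' = floor(m/(3k+2)); ``remainder`` is the trailing piece of length
    m - (3k+2)m', possibly None.  Concatenating parts then remainder
    reproduces the query exactly.
    """

    parts: tuple[Chain, ...]
    remainder: Chain | None
    part_offsets: tuple[int, ...]  # 1-based start of each part within Q
    m_prime: int
    k: int
    m: int


@dataclass(frozen=True)
class HitProfile:
    """Per-position filter outcome over a text chain.

    ``hit_flags[i-1, j-1]`` says whether divided substructure j satisfies
    Constraint 2 at 1-based text position i; a position is a candidate when
    at least 2k+2 parts hit.  ``filter_ops`` counts the arithmetic
    comparisons spent, for the linear-cost checks.
    """

    hit_flags: np.ndarray  # (n_positions, 3k+2) bool
    k: int
    threshold: float
    filter_ops: int

    @property
    def n_positions(self) -> int:
        return self.hit_flags.shape[0]

    @property
    def hit_counts(self) -> np.ndarray:
        return self.hit_flags.sum(axis=1)

    def candidates(self) -> np.ndarray:
        """1-based candidate positions (>= 2k+2 hit substructures)."""
        return np.flatnonzero(self.hit_counts >= 2 * self.k + 2) + 1


@dataclass(frozen=True)
class MatchReport:
    """A matching text position with its best witness.

    ``position`` is 1-based within ``structure_id``.  The witness deletes
    ``query_deletions`` (1-based residue indices of Q, k' of them) and
    ``text_deletions`` (1-based indices *within the matched window*
    P[i .. i - k' + k'' + m - 1], k'' of them); the two reduced structures
    superpose with the reported ``rmsd``.
    """

    structure_id: str
    position: int
    k_prime: int
    k_double_prime: int
    query_deletions: tuple[int, ...]
    text_deletions: tuple[int, ...]
    rmsd: float

    @property
    def window_length_delta(self) -> int:
        return self.k_double_prime - self.k_prime


@dataclass
class SearchStats:
    """Counters from one search run, for the average-case scaling checks."""

    engine: str
    n_text: int
    n_query: int
    k: int
    c: float
    m_prime: int | None
    n_positions: int
    candidate_count: int
    filter_ops: int
    rmsd_evaluations: int | None
    part_hit_rates: np.ndarray | None
    fallback: bool = False


def divide_query(Q: Chain, k: int) -> QueryDivision:
    """Cut the query into 3k+2 parts of length m' = floor(m/(3k+2)).

    Raises :class:`QueryTooShortError` when m < 2(3k+2), i.e. when the
    parts would be shorter than 2 residues (the half-split statistic needs
    two half-centroids); the caller should use the brute-force engine then.
    """
    m = len(Q)
    n_parts = 3 * k + 2
    m_prime = m // n_parts
    if m_prime < 2:
        raise QueryTooShortError(
            f"query of size {m} cannot be divided into {n_parts} parts of length >= 2"
        )
    parts = tuple(Q[(j - 1) * m_prime : j * m_prime] for j in range(1, n_parts + 1))
    rest = Q[n_parts * m_prime :] if m > n_parts * m_prime else None
    offsets = tuple((j - 1) * m_prime + 1 for j in range(1, n_parts + 1))
    return QueryDivision(
        parts=parts, remainder=rest, part_offsets=offsets, m_prime=m_prime, k=k, m=m
    )


def constraint2_threshold(c: float, m: int, m_prime: int) -> float:
    """Filter threshold on D for a divided substructure of length m'.

    The subsequence bound gives RMSD(part pair) <= sqrt(m/m') * c for any
    ungapped part of a witnessing alignment; the half-split lower bound
    satisfies D <= sqrt(m'/(2*floor(m'/2))) * RMSD (equality factor 1 for
    even m').  Their product, c * sqrt(m / (2*floor(m'/2))), is the loosest
    threshold that still guarantees zero false negatives for every part
    length.
    """
    return c * sqrt(m / (2.0 * (m_prime // 2)))


def constraint2_hit(
    Qdiv: QueryDivision,
    j: int,
    i: int,
    table: WindowFTable,
    params: SearchParams,
) -> bool:
    """Does divided substructure j hit at text position i (Constraint 2)?

    True iff some window start l in [i + (j-1)m' - k, i + (j-1)m' + k]
    (1-based, clipped to valid window starts) has
    D(Q_j, P[l .. l+m'-1]) <= threshold.  Each D costs O(1) thanks to the
    precomputed window table.
    """
    if table.window_length != Qdiv.m_prime:
        raise ValueError("window table was built with a different part length")
    thr = constraint2_threshold(params.c, Qdiv.m, Qdiv.m_prime)
    f_q = half_split_statistic(Qdiv.parts[j - 1])
    center = i + (j - 1) * Qdiv.m_prime
    n_windows = len(table)
    for ell in range(center - params.k, center + params.k + 1):
        if 1 <= ell <= n_windows and abs(f_q - table.f_at(ell)) <= thr:
            return True
    return False


def enumerate_candidates(P: Chain, Qdiv: QueryDivision, params: SearchParams) -> HitProfile:
    """Step 1 of the search: hit counts for every position of the text.

    Vectorized sliding-window evaluation; total arithmetic is
    O((3k+2) * (2k+1) * N) and is counted in ``filter_ops``.
    """
    k = params.k
    m, m_prime = Qdiv.m, Qdiv.m_prime
    n_parts = 3 * k + 2
    N = len(P)
    n_pos = N - m + k + 1
    thr = constraint2_threshold(params.c, m, m_prime)
    if n_pos < 1:
        return HitProfile(
            hit_flags=np.zeros((0, n_parts), dtype=bool), k=k, threshold=thr, filter_ops=0
        )
    table = build_window_table(P, m_prime)
    n_windows = len(table)
    f_parts = np.array([half_split_statistic(p) for p in Qdiv.parts])
    ok = np.abs(table.f_values[None, :] - f_parts[:, None]) <= thr  # (parts, windows)
    hit = np.zeros((n_pos, n_parts), dtype=bool)
    pos0 = np.arange(n_pos)  # i - 1
    for j0 in range(n_parts):
        for off in range(-k, k + 1):
            ell0 = pos0 + j0 * m_prime + off
            valid = (ell0 >= 0) & (ell0 < n_windows)
            hit[valid, j0] |= ok[j0, ell0[valid]]
    ops = n_parts * n_windows + n_parts * (2 * k + 1) * n_pos
    return HitProfile(hit_flags=hit, k=k, threshold=thr, filter_ops=ops)


from functools import lru_cache


@lru_cache(maxsize=256)
def _keep_index_sets(L: int, kt: int) -> tuple:
    """All kt-deletion sets of a length-L window with their kept indices, lex order."""
    return tuple(
        (dels, np.array([x for x in range(L) if x not in dels], dtype=np.intp))
        for dels in combinations(range(L), kt)
    )


def _query_deletion_cache(Qarr: np.ndarray, k: int) -> dict[int, list]:
    """Reduced query structures per query-side deletion count, lex order."""
    m = Qarr.shape[0]
    return {
        kq: [(dels, np.delete(Qarr, dels, axis=0)) for dels in combinations(range(m), kq)]
        for kq in range(k + 1)
    }


def _verify(
    Parr: np.ndarray,
    Qarr: np.ndarray,
    i: int,
    params: SearchParams,
    end_limit: int,
    qcache: dict[int, list],
) -> tuple[tuple | None, int]:
    """Step 2 at one position: best witness over all admissible deletions.

    Enumerates k' + k'' <= k in lexicographic (k', k'', query-set,
    text-set) order with strict-improvement updates, so ties resolve to the
    lexicographically smallest witness.  Windows running past ``end_limit``
    (1-based, the end of the position's source structure) are skipped.
    Returns (witness-or-None, number of RMSD evaluations).
    """
    k, c = params.k, params.c
    m = Qarr.shape[0]
    best: tuple | None = None
    evals = 0
    for kq in range(k + 1):
        for kt in range(k - kq + 1):
            L = m - kq + kt
            if i - 1 + L > end_limit:
                continue
            window = Parr[i - 1 : i - 1 + L]
            for qdels, Qred in qcache[kq]:
                for tdels, keep in _keep_index_sets(L, kt):
                    evals += 1
                    r = _rmsd_arrays(Qred, window[keep])
                    if best is None or r < best[0]:
                        best = (r, kq, kt, qdels, tdels)
    if best is not None and best[0] <= c:
        return best, evals
    return None, evals


def verify_candidate(P: Chain, Q: Chain, i: int, params: SearchParams) -> MatchReport | None:
    """Exact verification of one candidate position of a single text chain."""
    params.validate_for_query(len(Q))
    qcache = _query_deletion_cache(Q.coords, params.k)
    best, _ = _verify(P.coords, Q.coords, i, params, end_limit=len(P), qcache=qcache)
    if best is None:
        return None
    r, kq, kt, qdels, tdels = best
    return MatchReport(
        structure_id=P.label,
        position=i,
        k_prime=kq,
        k_double_prime=kt,
        query_deletions=tuple(d + 1 for d in qdels),
        text_deletions=tuple(d + 1 for d in tdels),
        rmsd=r,
    )


def search(
    P: Union[Chain, "StructureDatabase"],
    Q: Chain,
    params: SearchParams,
) -> tuple[list[MatchReport], SearchStats]:
    """Find all indel-tolerant matches of ``Q`` in a text chain or database.

    Runs the filter (step 1) over the concatenated text, masks candidates
    whose smallest admissible window would cross a structure boundary, and
    verifies the survivors exhaustively (step 2).  The reported position
    set and witnesses are identical to the brute-force scan; only the work
    differs.  Queries too short for the division (m < 2(3k+2)) fall back to
    the brute-force engine with a logged warning.
    """
    from .io import StructureDatabase  # deferred: io imports nothing from here

    db = P if isinstance(P, StructureDatabase) else StructureDatabase.from_chains([P])
    m = len(Q)
    k, c = params.k, params.c
    params.validate_for_query(m)
    N = len(db.concatenated)
    if m > N:
        raise ValueError(f"query (m={m}) longer than the database ({N} residues)")

    try:
        qdiv = divide_query(Q, k)
    except QueryTooShortError:
        logger.warning(
            "query of size %d too short for a %d-part division; falling back to brute force",
            m,
            3 * k + 2,
        )
        from .brute_force import naive_search

        matches: list[MatchReport] = []
        for sid, chain in db.items():
            matches.extend(naive_search(Chain(chain.coords, sid), Q, params))
        stats = SearchStats(
            engine="naive-fallback",
            n_text=N,
            n_query=m,
            k=k,
            c=c,
            m_prime=None,
            n_positions=max(N - m + k + 1, 0),
            candidate_count=max(N - m + k + 1, 0),
            filter_ops=0,
            rmsd_evaluations=None,
            part_hit_rates=None,
            fallback=True,
        )
        return matches, stats

    profile = enumerate_candidates(db.concatenated, qdiv, params)
    qcache = _query_deletion_cache(Q.coords, k)
    Parr = db.concatenated.coords
    matches = []
    evals = 0
    n_verified = 0
    for i in profile.candidates():
        i = int(i)
        seg = db.segment_of_position(i)
        if seg is None:
            continue
        sid, seg_start, seg_end = seg  # 1-based global inclusive bounds
        if i + (m - k) - 1 > seg_end:
            continue  # no admissible window fits inside this structure
        n_verified += 1
        best, ne = _verify(Parr, Q.coords, i, params, end_limit=seg_end, qcache=qcache)
        evals += ne
        if best is not None:
            r, kq, kt, qdels, tdels = best
            matches.append(
                MatchReport(
                    structure_id=sid,
                    position=i - seg_start + 1,
                    k_prime=kq,
                    k_double_prime=kt,
                    query_deletions=tuple(d + 1 for d in qdels),
                    text_deletions=tuple(d + 1 for d in tdels),
                    rmsd=r,
                )
            )
    stats = SearchStats(
        engine="filter",
        n_text=N,
        n_query=m,
        k=k,
        c=c,
        m_prime=qdiv.m_prime,
        n_positions=profile.n_positions,
        candidate_count=int(len(profile.candidates())),
        filter_ops=profile.filter_ops,
        rmsd_evaluations=evals,
        part_hit_rates=profile.hit_flags.mean(axis=0) if profile.n_positions else None,
        fallback=False,
    )
    return matches, stats
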