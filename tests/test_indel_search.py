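"""The filter-and-verify engine: division, filtering, verification, search."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelsearch.brute_force import naive_search
from indelsearch.core_geometry import Chain, concat, rmsd
from indelsearch.indel_search import (
    QueryTooShortError,
    SearchParams,
    constraint2_hit,
    divide_query,
    enumerate_candidates,
    search,
    verify_candidate,
)
from indelsearch.io import StructureDatabase
from indelsearch.lower_bound import build_window_table
from indelsearch.random_walk import PlantSpec, RandomWalkParams, generate_chain, plant

from conftest import plant_random, random_chain, report_key


def walk(n, seed, r=1.0, label="walk"):
    return generate_chain(RandomWalkParams(n=n, r=r, seed=seed), label)


class TestSearchParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SearchParams(c=0.0, k=1)
        with pytest.raises(ValueError):
            SearchParams(c=1.0, k=-1)
        with pytest.raises(ValueError):
            SearchParams(c=1.0, k=5).validate_for_query(5)


class TestDivideQuery:
    @pytest.mark.parametrize(
        "m, k, m_prime, rest",
        [(10, 1, 2, 0), (11, 1, 2, 1), (16, 0, 8, 0), (30, 1, 6, 0), (23, 1, 4, 3)],
    )
    def test_part_arithmetic(self, m, k, m_prime, rest, rng):
        div = divide_query(random_chain(rng, m), k)
        assert len(div.parts) == 3 * k + 2
        assert all(len(p) == m_prime for p in div.parts)
        assert div.m_prime == m_prime
        assert (len(div.remainder) if div.remainder else 0) == rest
        assert div.part_offsets == tuple(1 + j * m_prime for j in range(3 * k + 2))

    def test_too_short_signals_fallback(self, rng):
        with pytest.raises(QueryTooShortError):
            divide_query(random_chain(rng, 7), 2)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(m=st.integers(10, 60), k=st.integers(0, 3))
    def test_parts_concatenate_to_query(self, m, k):
        if m < 2 * (3 * k + 2):
            return
        q = random_chain(np.random.default_rng(m * 7 + k), m)
        div = divide_query(q, k)
        pieces = list(div.parts) + ([div.remainder] if div.remainder else [])
        np.testing.assert_array_equal(concat(*pieces).coords, q.coords)


class TestConstraint2:
    def test_exact_copy_hits_everywhere(self, rng):
        text = walk(120, 3)
        pos = 41
        query = Chain(text.coords[pos - 1 : pos - 1 + 24], "q")
        params = SearchParams(c=0.3, k=1)
        div = divide_query(query, params.k)
        table = build_window_table(text, div.m_prime)
        for j in range(1, 3 * params.k + 3):
            assert constraint2_hit(div, j, pos, table, params)

    def test_k0_checks_single_window(self, rng):
        text = walk(60, 4)
        query = walk(16, 5, label="q")
        params = SearchParams(c=0.2, k=0)
        div = divide_query(query, 0)
        table = build_window_table(text, div.m_prime)
        # manual single-window check must coincide with constraint2_hit
        from indelsearch.indel_search import constraint2_threshold
        from indelsearch.lower_bound import half_split_statistic

        thr = constraint2_threshold(params.c, div.m, div.m_prime)
        for i in (1, 10, 30):
            for j in (1, 2):
                ell = i + (j - 1) * div.m_prime
                expected = abs(
                    half_split_statistic(div.parts[j - 1]) - table.f_at(ell)
                ) <= thr
                assert constraint2_hit(div, j, i, table, params) == expected


class TestEnumerateCandidates:
    def test_text_equals_query(self, rng):
        q = walk(20, 6, label="q")
        div = divide_query(q, 1)
        profile = enumerate_candidates(q, div, SearchParams(c=0.5, k=1))
        assert 1 in profile.candidates()

    def test_monotone_in_threshold(self, rng):
        text, query = walk(400, 7), walk(24, 8)
        k = 1
        div = divide_query(query, k)
        small = enumerate_candidates(text, div, SearchParams(c=0.15, k=k))
        large = enumerate_candidates(text, div, SearchParams(c=0.6, k=k))
        assert set(small.candidates()).issubset(set(large.candidates()))

    def test_hit_counts_match_scalar_constraint(self, rng):
        text, query = walk(90, 9), walk(20, 10)
        params = SearchParams(c=0.4, k=1)
        div = divide_query(query, params.k)
        table = build_window_table(text, div.m_prime)
        profile = enumerate_candidates(text, div, params)
        for i in range(1, profile.n_positions + 1):
            for j in range(1, 3 * params.k + 3):
                assert profile.hit_flags[i - 1, j - 1] == constraint2_hit(
                    div, j, i, table, params
                )

    def test_filter_cost_linear_in_text_size(self):
        query = walk(40, 11)
        params = SearchParams(c=0.3, k=1)
        div = divide_query(query, params.k)
        ops = {}
        for N in (2000, 4000, 8000):
            profile = enumerate_candidates(walk(N, N), div, params)
            ops[N] = profile.filter_ops
        assert ops[4000] / ops[2000] == pytest.approx(2.0, rel=0.05)
        assert ops[8000] / ops[4000] == pytest.approx(2.0, rel=0.05)


class TestVerifyCandidate:
    def test_exact_copy(self, rng):
        text = walk(80, 12)
        query = Chain(text.coords[19:35], "q")
        rep = verify_candidate(text, query, 20, SearchParams(c=0.5, k=1))
        assert rep is not None
        assert (rep.k_prime, rep.k_double_prime) == (0, 0)
        assert rep.rmsd < 1e-12

    def test_single_deletion_witness(self, rng):
        query = walk(12, 13, label="q")
        text = walk(40, 14)
        spec = PlantSpec(query=query, position=9, deletions=(5,), seed=1, bond_scale=1.0)
        mutated, truth = plant(text, spec)
        rep = verify_candidate(mutated, query, 9, SearchParams(c=0.1, k=1))
        assert rep is not None
        assert (rep.k_prime, rep.k_double_prime) == (1, 0)
        assert rep.query_deletions == (5,)
        assert rep.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_witness_rmsd_recomputes(self, rng):
        text, query = walk(60, 15), walk(14, 16, label="q")
        mutated, truth = plant_random(rng, text, query, k=2, noise_sigma=0.05)
        rep = verify_candidate(mutated, query, truth.position, SearchParams(c=0.5, k=2))
        assert rep is not None
        L = len(query) - rep.k_prime + rep.k_double_prime
        window = mutated[rep.position - 1 : rep.position - 1 + L]
        qred = query.delete([d - 1 for d in rep.query_deletions])
        wred = window.delete([d - 1 for d in rep.text_deletions])
        assert rmsd(qred, wred) == pytest.approx(rep.rmsd, abs=1e-9)

    def test_min_rmsd_matches_oracle(self, rng):
        """Per-position minimum over the whole (k', k'', sets) space."""
        for trial in range(6):
            text, query = walk(30, 100 + trial), walk(10, 200 + trial, label="q")
            k = trial % 3
            params = SearchParams(c=100.0, k=k)  # threshold loose: min always reported
            i = int(rng.integers(1, 30 - 10 + k + 2))
            rep = verify_candidate(text, query, i, params)
            oracle = naive_search(text, query, params)
            oracle_at_i = [m for m in oracle if m.position == i]
            assert rep is not None and len(oracle_at_i) == 1
            assert report_key(rep)[1:] == report_key(oracle_at_i[0])[1:]


class TestSearch:
    def test_planted_positions_recovered(self, rng):
        """Exact, noisy and indel-mutated plants must all be reported."""
        text = walk(400, 17, label="text")
        query = walk(24, 18, label="q")
        specs = [
            PlantSpec(query=query, position=30, seed=2, bond_scale=1.0),
            PlantSpec(query=query, position=150, noise_sigma=0.05, seed=3, bond_scale=1.0),
            PlantSpec(
                query=query, position=300, deletions=(7,), insertions=(12,),
                noise_sigma=0.03, seed=4, bond_scale=1.0,
            ),
        ]
        for spec in specs:
            text, truth = plant(text, spec)
            assert truth.rmsd <= 0.3
        matches, stats = search(text, query, SearchParams(c=0.3, k=2))
        positions = {m.position for m in matches}
        assert {30, 150, 300} <= positions
        assert stats.engine == "filter" and not stats.fallback

    def test_negative_control(self):
        """Unrelated random walks at a tight threshold: no matches, 20 seeds."""
        for seed in range(20):
            text = walk(300, 1000 + seed)
            query = walk(30, 2000 + seed, label="q")
            matches, _ = search(text, query, SearchParams(c=0.1, k=1))
            assert matches == []

    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_equivalence_with_oracle(self, k):
        """Identical position sets and witnesses on randomized instances."""
        rng = np.random.default_rng(50 + k)
        for trial in range(4):
            N = int(rng.integers(60, 121))
            m = int(rng.integers(8, 13))
            c = float(rng.choice([0.2, 0.5]))
            text = walk(N, int(rng.integers(2**31)), label="text")
            query = walk(m, int(rng.integers(2**31)), label="q")
            if trial % 2 == 0:
                text, truth = plant_random(rng, text, query, k, noise_sigma=c / 4)
            params = SearchParams(c=c, k=k)
            got, _ = search(text, query, params)
            expected = naive_search(text, query, params)
            assert [report_key(r) for r in got] == [report_key(r) for r in expected]

    def test_fallback_for_short_queries(self, caplog):
        text = walk(60, 19, label="text")
        query = Chain(text.coords[9:16], "q")  # m=7 < 2*(3k+2) for k=2
        params = SearchParams(c=0.2, k=2)
        with caplog.at_level("WARNING"):
            matches, stats = search(text, query, params)
        assert stats.fallback and stats.engine == "naive-fallback"
        expected = naive_search(text, query, params)
        assert [report_key(r) for r in matches] == [report_key(r) for r in expected]
        assert 10 in {m.position for m in matches}

    def test_multichain_database_and_boundaries(self):
        """Matches are local to their structure; boundary-crossing windows die."""
        a = walk(80, 20, label="A")
        b = walk(90, 21, label="B")
        query = Chain(b.coords[14:34], "q")
        db = StructureDatabase.from_chains([a, b])
        matches, _ = search(db, query, SearchParams(c=0.2, k=1))
        # with k=1 the one-residue-shifted positions also match exactly
        assert {(m.structure_id, m.position) for m in matches if m.rmsd < 1e-9} == {
            ("B", 14),
            ("B", 15),
            ("B", 16),
        }
        # windows must fit inside their source structure
        for m in matches:
            L = len(query) - m.k_prime + m.k_double_prime
            limit = len(a) if m.structure_id == "A" else len(b)
            assert 1 <= m.position and m.position + L - 1 <= limit

    def test_boundary_crossing_match_is_ignored(self):
        """A copy of the query straddling two concatenated structures is not
        a match, even though the concatenated text contains it verbatim."""
        a = walk(50, 22, label="A")
        b = walk(40, 23, label="B")
        # query = last 6 residues of A followed by first 9 residues of B
        query = Chain(np.vstack([a.coords[44:], b.coords[:9]]), "q")
        db = StructureDatabase.from_chains([a, b])
        matches, _ = search(db, query, SearchParams(c=0.05, k=0))
        assert matches == []
        # sanity: the same window in one long chain IS a match
        merged = Chain(np.vstack([a.coords, b.coords]), "AB")
        matches2, _ = search(merged, query, SearchParams(c=0.05, k=0))
        assert 45 in {m.position for m in matches2}
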