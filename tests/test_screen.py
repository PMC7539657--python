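"""Homology screening: threshold semantics, oracle equality, iteration."""

import numpy as np
import pytest

from rcdprofiler import (
    HomologyHit,
    RcdError,
    ScreenParams,
    expand_baits,
    filter_hits,
    iterate_search,
)
from rcdprofiler.model import SearchError


def make_hit(query="q", subject="s", pident=50.0, qlen_span=(1, 95),
             evalue=1e-20):
    qs, qe = qlen_span
    return HomologyHit(
        query_id=query, subject_id=subject, pct_identity=pident,
        aln_length=qe - qs + 1, mismatch=0, gapopen=0,
        q_start=qs, q_end=qe, s_start=1, s_end=qe - qs + 1,
        e_value=evalue, bit_score=100.0,
    )


LEN = {"q": 100}


class TestFilterHits:
    def test_clearing_all_thresholds_kept(self):
        assert filter_hits([make_hit(pident=45.0)], LEN) != []

    def test_identity_just_below_threshold_dropped(self):
        assert filter_hits([make_hit(pident=29.9)], LEN) == []

    def test_identity_exactly_30_kept(self):
        assert filter_hits([make_hit(pident=30.0)], LEN) != []

    def test_coverage_exactly_080_kept(self):
        assert filter_hits([make_hit(qlen_span=(1, 80))], LEN) != []

    def test_coverage_below_080_dropped(self):
        assert filter_hits([make_hit(qlen_span=(1, 79))], LEN) == []

    def test_evalue_exactly_cutoff_dropped(self):
        assert filter_hits([make_hit(evalue=1e-5)], LEN) == []

    def test_missing_query_length_names_query(self):
        with pytest.raises(RcdError, match="mystery"):
            filter_hits([make_hit(query="mystery")], LEN)

    def _random_hits(self, rng, n):
        hits, lengths = [], {}
        for i in range(n):
            q = f"q{rng.integers(20)}"
            lengths.setdefault(q, int(rng.integers(50, 300)))
            qs = int(rng.integers(1, 30))
            qe = qs + int(rng.integers(10, lengths[q]))
            hits.append(
                HomologyHit(
                    query_id=q, subject_id=f"s{i}",
                    pct_identity=float(np.round(rng.uniform(0, 100), 1)),
                    aln_length=qe - qs + 1, mismatch=0, gapopen=0,
                    q_start=qs, q_end=qe, s_start=1, s_end=qe - qs + 1,
                    e_value=float(10.0 ** -rng.uniform(0, 12)),
                    bit_score=50.0,
                )
            )
        return hits, lengths

    def test_matches_naive_three_condition_scan(self):
        rng = np.random.default_rng(42)
        params = ScreenParams()
        hits, lengths = self._random_hits(rng, 2000)
        kept = filter_hits(hits, lengths, params)
        naive = [
            h for h in hits
            if h.e_value < params.e_max
            and h.pct_identity >= params.id_min
            and (h.q_end - h.q_start + 1) / lengths[h.query_id] >= params.cov_min
        ]
        assert kept == naive

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        hits, lengths = self._random_hits(rng, 500)
        strict = set(
            id(h) for h in filter_hits(hits, lengths, ScreenParams())
        )
        relaxed = set(
            id(h)
            for h in filter_hits(
                hits, lengths,
                ScreenParams(e_max=1e-3, id_min=10, cov_min=0.5),
            )
        )
        assert strict <= relaxed

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(2)
        hits, lengths = self._random_hits(rng, 500)
        kept = filter_hits(hits, lengths)
        assert filter_hits(kept, lengths) == kept
        assert set(id(h) for h in kept) <= set(id(h) for h in hits)


class TestExpandBaits:
    def test_fixed_point_without_new_subjects(self):
        baits = frozenset({"a", "s"})
        assert expand_baits([make_hit(subject="s")], baits) == baits

    def test_grows_by_new_subjects(self):
        got = expand_baits(
            [make_hit(subject="x"), make_hit(subject="y")], {"a"}
        )
        assert got == {"a", "x", "y"}


class TestIterateSearch:
    def test_chain_reaches_transitive_closure(self):
        edges = {"a": "b", "b": "c"}

        def search(baits):
            return [
                make_hit(query="q", subject=edges[b])
                for b in sorted(baits) if b in edges
            ]

        final, log = iterate_search(search, {"a"}, ScreenParams(max_rounds=3))
        assert final == {"a", "b", "c"}

    def test_terminates_when_no_growth(self):
        def search(baits):
            return [make_hit(subject="b")]

        final, log = iterate_search(search, {"a"}, ScreenParams(max_rounds=5))
        assert final == {"a", "b"}
        assert len(log) == 2  # growth round then fixed-point round

    def test_max_rounds_one_runs_single_round(self):
        calls = []

        def search(baits):
            calls.append(set(baits))
            return [make_hit(subject=f"n{len(calls)}")]

        final, log = iterate_search(search, {"a"}, ScreenParams(max_rounds=1))
        assert len(calls) == 1 and len(log) == 1

    def test_bait_sets_monotone_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            nodes = [f"n{i}" for i in range(8)]
            edges = {
                n: [m for m in nodes if rng.random() < 0.3] for n in nodes
            }

            def search(baits):
                return [
                    make_hit(query="q", subject=m)
                    for b in sorted(baits) for m in edges.get(b, [])
                ]

            seen = []

            def logging_search(baits):
                seen.append(frozenset(baits))
                return search(baits)

            final, _ = iterate_search(
                logging_search, {"n0"}, ScreenParams(max_rounds=10)
            )
            for a, b in zip(seen, seen[1:]):
                assert a <= b
            # fixed point equals graph closure from the seed
            closure = {"n0"}
            while True:
                new = closure | {
                    m for b in closure for m in edges.get(b, [])
                }
                if new == closure:
                    break
                closure = new
            assert final == closure

    def test_backend_failure_reports_round(self):
        def search(baits):
            raise RuntimeError("backend down")

        with pytest.raises(SearchError, match="round 1"):
            iterate_search(search, {"a"})
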