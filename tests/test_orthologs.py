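"""Reciprocal-best-hit orthology: filters, pairing, paralogs, agreement."""

import itertools

import numpy as np
import pytest

from tradis_essentia import (
    OrthologPair,
    best_hits,
    compare_essentiality,
    exclude_paralogs,
    filter_hits,
    reciprocal_pairs,
)
from tradis_essentia.io_formats import TabularHit


def hit(q, s, bitscore=200.0, evalue=1e-50, pident=90.0, qcov=100.0,
        scov=100.0, qlen=100, slen=100):
    q_end = max(1, int(round(qlen * qcov / 100)))
    s_end = max(1, int(round(slen * scov / 100)))
    return TabularHit(
        query_id=q, subject_id=s, percent_identity=pident,
        alignment_length=max(q_end, s_end), mismatches=0, gap_opens=0,
        q_start=1, q_end=q_end, s_start=1, s_end=s_end,
        evalue=evalue, bitscore=bitscore, q_len=qlen, s_len=slen,
    )


class TestFilterHits:
    def test_evalue_ceiling_is_inclusive_cut(self):
        assert filter_hits([hit("a", "b", evalue=1e-4)]) == []
        assert len(filter_hits([hit("a", "b", evalue=1e-5)])) == 1

    def test_coverage_floor_is_inclusive(self):
        assert filter_hits([hit("a", "b", qcov=69.9, qlen=1000)]) == []
        assert len(filter_hits([hit("a", "b", qcov=70.0, qlen=1000)])) == 1

    def test_subject_coverage_also_enforced(self):
        assert filter_hits([hit("a", "b", scov=50.0)]) == []

    def test_self_hits_dropped(self):
        assert filter_hits([hit("a", "a", evalue=0.0)]) == []

    def test_monotone_under_tightening(self):
        rng = np.random.default_rng(11)
        hits = [
            hit(f"a{i}", f"b{rng.integers(5)}",
                evalue=float(10.0 ** -rng.integers(3, 12)),
                qcov=float(rng.uniform(40, 100)),
                scov=float(rng.uniform(40, 100)))
            for i in range(60)
        ]
        for ev1, ev2 in [(1e-4, 1e-6)]:
            k1 = {(h.query_id, h.subject_id) for h in filter_hits(hits, ev1)}
            k2 = {(h.query_id, h.subject_id) for h in filter_hits(hits, ev2)}
            assert k2 <= k1
        for cov1, cov2 in [(50.0, 80.0)]:
            k1 = {(h.query_id, h.subject_id)
                  for h in filter_hits(hits, min_qcov=cov1, min_scov=cov1)}
            k2 = {(h.query_id, h.subject_id)
                  for h in filter_hits(hits, min_qcov=cov2, min_scov=cov2)}
            assert k2 <= k1


class TestBestHits:
    def test_single_hit_wins(self):
        b = best_hits([hit("a", "b")])
        assert b["a"].subject_id == "b"

    def test_higher_bitscore_wins(self):
        b = best_hits([hit("a", "b1", bitscore=150), hit("a", "b2", bitscore=200)])
        assert b["a"].subject_id == "b2"

    def test_full_tie_breaks_lexicographically(self):
        b = best_hits([hit("a", "b2"), hit("a", "b1")])
        assert b["a"].subject_id == "b1"
        # brute-force confirmation of the documented sort order
        ranked = sorted(
            [hit("a", "b2"), hit("a", "b1")],
            key=lambda h: (-h.bitscore, h.evalue, -h.percent_identity,
                           h.subject_id),
        )
        assert b["a"] == ranked[0]


class TestReciprocalPairs:
    def test_mutual_best_pairs(self):
        pairs = reciprocal_pairs(best_hits([hit("a1", "b1")]),
                                 best_hits([hit("b1", "a1")]))
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]

    def test_one_sided_best_is_no_pair(self):
        pairs = reciprocal_pairs(
            best_hits([hit("a1", "b1")]),
            best_hits([hit("b1", "a2", bitscore=500), hit("b1", "a1")]),
        )
        assert pairs == []

    def _enumerate_oracle(self, hits_ab, hits_ba):
        """Exhaustive reciprocal-best enumeration, independent of the
        dict-based implementation."""

        def best_for(query, hits):
            cands = [h for h in hits if h.query_id == query]
            if not cands:
                return None
            return min(cands, key=lambda h: (-h.bitscore, h.evalue,
                                             -h.percent_identity, h.subject_id))

        queries_a = {h.query_id for h in hits_ab}
        queries_b = {h.query_id for h in hits_ba}
        pairs = set()
        for a, b in itertools.product(queries_a, queries_b):
            ha = best_for(a, hits_ab)
            hb = best_for(b, hits_ba)
            if ha and hb and ha.subject_id == b and hb.subject_id == a:
                pairs.add((a, b))
        return pairs

    def test_matches_exhaustive_enumeration_on_random_tables(self):
        rng = np.random.default_rng(2025)
        for rep in range(100):
            na, nb = rng.integers(2, 21), rng.integers(2, 21)
            hits_ab, hits_ba = [], []
            for _ in range(int(rng.integers(1, 60))):
                hits_ab.append(hit(
                    f"a{rng.integers(na)}", f"b{rng.integers(nb)}",
                    bitscore=float(rng.integers(50, 400)),
                    evalue=float(10.0 ** -rng.integers(6, 30)),
                ))
            for _ in range(int(rng.integers(1, 60))):
                hits_ba.append(hit(
                    f"b{rng.integers(nb)}", f"a{rng.integers(na)}",
                    bitscore=float(rng.integers(50, 400)),
                    evalue=float(10.0 ** -rng.integers(6, 30)),
                ))
            got = {(p.gene_a, p.gene_b)
                   for p in reciprocal_pairs(best_hits(hits_ab),
                                             best_hits(hits_ba))}
            assert got == self._enumerate_oracle(hits_ab, hits_ba)

    def test_symmetry_of_directions(self):
        rng = np.random.default_rng(8)
        hits_ab = [hit(f"a{i}", f"b{rng.integers(6)}",
                       bitscore=float(rng.integers(50, 300))) for i in range(12)]
        hits_ba = [hit(f"b{i}", f"a{rng.integers(6)}",
                       bitscore=float(rng.integers(50, 300))) for i in range(12)]
        fwd = {(p.gene_a, p.gene_b)
               for p in reciprocal_pairs(best_hits(hits_ab), best_hits(hits_ba))}
        rev = {(p.gene_b, p.gene_a)
               for p in reciprocal_pairs(best_hits(hits_ba), best_hits(hits_ab))}
        assert fwd == rev


class TestExcludeParalogs:
    PAIRS = [OrthologPair("a1", "b1", 200, 200),
             OrthologPair("a2", "b2", 200, 200)]

    def test_within_proteome_partner_removes_pair(self):
        self_a = [hit("a1", "a9", pident=95.0)]
        kept = exclude_paralogs(self.PAIRS, self_a, [])
        assert [(p.gene_a, p.gene_b) for p in kept] == [("a2", "b2")]

    def test_pure_self_hit_is_not_a_paralog(self):
        self_a = [hit("a1", "a1", evalue=0.0)]
        kept = exclude_paralogs(self.PAIRS, self_a, [])
        assert len(kept) == 2

    def test_empty_self_tables_remove_nothing(self):
        assert exclude_paralogs(self.PAIRS, [], []) == self.PAIRS

    def test_subject_side_paralog_also_removed(self):
        self_b = [hit("b2", "b7")]
        kept = exclude_paralogs(self.PAIRS, [], self_b)
        assert [(p.gene_a, p.gene_b) for p in kept] == [("a1", "b1")]

    def test_below_threshold_within_hit_is_ignored(self):
        self_a = [hit("a1", "a9", evalue=1e-3)]  # fails the E-value filter
        assert len(exclude_paralogs(self.PAIRS, self_a, [])) == 2


class TestCompareEssentiality:
    @staticmethod
    def _pairs(n):
        return [OrthologPair(f"a{i}", f"b{i}", 100, 100) for i in range(n)]

    def test_toy_agreement_counts(self):
        pairs = self._pairs(4)
        calls_a = {"a0": "essential", "a1": "non_essential",
                   "a2": "unclear", "a3": "essential"}
        calls_b = {"b0": "essential", "b1": "non_essential",
                   "b2": "unclear", "b3": "non_essential"}
        cmp = compare_essentiality(pairs, calls_a, calls_b)
        assert cmp.n_agree == 3
        assert cmp.agreement_percent == 75
        assert cmp.counts["essential_vs_non_essential"] == 1

    def test_counts_partition_pair_list(self):
        rng = np.random.default_rng(4)
        n = 50
        pairs = self._pairs(n)
        states = ["essential", "non_essential", "unclear"]
        calls_a = {f"a{i}": states[rng.integers(3)] for i in range(n)}
        calls_b = {f"b{i}": states[rng.integers(3)] for i in range(n)}
        cmp = compare_essentiality(pairs, calls_a, calls_b)
        assert sum(cmp.counts.values()) == n
        assert cmp.n_agree + cmp.n_mismatch == n

    def test_missing_call_names_the_gene(self):
        with pytest.raises(KeyError, match="a0"):
            compare_essentiality(self._pairs(1), {}, {"b0": "essential"})
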