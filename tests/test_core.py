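"""Flanking-support scoring, best-pair resolution, classification, expansion."""
import random

import pytest

import syntelog as sl
from syntelog.core import (NONE, NONSYNTENIC_ORTHOLOG, SYNTENIC,
                           SyntenyParams, SyntenyResult,
                           classify_nonsyntenic_orthologs,
                           expand_tandem_synteny, flanking_support,
                           potential_syntenic_pairs, resolve_best_pairs)
from syntelog.homology import (CandidatePairSet, compute_best_hits)

from conftest import (collinear_pair, hit, make_genome,
                      oracle_flanking_count)


def best_map(hits):
    return compute_best_hits(hits, "Q", "R")


class TestFlankingSupport:
    def test_perfect_collinearity_gives_ratio_one(self):
        qg, rg, hits = collinear_pair(60)
        bm = best_map(hits)
        params = SyntenyParams(num_q=20, num_r=100)
        c = flanking_support("q030", "r030", qg, rg, bm, params)
        assert c.support_ratio == 1.0
        assert c.window_size == 40

    def test_chromosome_start_truncates_window(self):
        qg, rg, hits = collinear_pair(30)
        c = flanking_support("q000", "r000", qg, rg, best_map(hits),
                             SyntenyParams(num_q=20, num_r=100))
        assert c.window_size == 20  # no left flank

    def test_inverted_reference_block_supports_equally(self):
        qg, rg, hits = collinear_pair(60)
        # reverse ref genes 20..39 in place (coordinates swapped)
        genes = []
        for g in rg:
            if 20 <= g.rank < 40:
                mirror = 20 + 39 - g.rank
                genes.append(sl.Gene(g.gene_id, "R", g.chromosome,
                                     1 + mirror * 1000, 900 + mirror * 1000,
                                     "-"))
            else:
                genes.append(g)
        rg_inv = sl.GenomeIndex("R", genes)
        bm = best_map(hits)
        params = SyntenyParams(num_q=20, num_r=100)
        for i in (10, 25, 30, 45):
            a = flanking_support(f"q{i:03d}", f"r{i:03d}", qg, rg, bm, params)
            b = flanking_support(f"q{i:03d}", f"r{i:03d}", qg, rg_inv, bm,
                                 params)
            assert a.support_ratio == b.support_ratio == 1.0

    def test_missing_gene_raises(self):
        qg, rg, hits = collinear_pair(10)
        with pytest.raises(KeyError, match="redirect"):
            flanking_support("nope", "r001", qg, rg, best_map(hits),
                             SyntenyParams())

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_match_brute_force_recount(self, seed):
        rng = random.Random(seed)
        n = 120
        q_ids = [f"q{i:03d}" for i in range(n)]
        r_ids = [f"r{i:03d}" for i in range(n)]
        rng.shuffle(r_ids)
        qg = make_genome(q_ids, "Q")
        rg = make_genome(r_ids, "R")
        hits = [hit(f"q{i:03d}", f"r{rng.randrange(n):03d}",
                    bitscore=rng.randrange(100, 500)) for i in range(n)
                for _ in range(2)]
        bm = best_map(hits)
        params = SyntenyParams(num_q=7, num_r=15)
        for _ in range(100):
            q = f"q{rng.randrange(n):03d}"
            s = f"r{rng.randrange(n):03d}"
            got = flanking_support(q, s, qg, rg, bm, params)
            count, size = oracle_flanking_count(q, s, qg, rg, bm.map, 7, 15)
            assert (got.supporting_count, got.window_size) == (count, size)
            assert got.support_ratio == pytest.approx(
                count / size if size else 0.0)


class TestPotentialPairs:
    def _candidates(self, pairs, hits):
        cs = CandidatePairSet()
        by_pair = {(h.query_id, h.subject_id): h for h in hits}
        for p in pairs:
            cs.pairs[p] = by_pair[p]
        return cs

    def test_threshold_is_strict(self):
        # exactly at threshold -> excluded
        qg, rg, hits = collinear_pair(10)
        bm = best_map(hits)
        params = SyntenyParams(num_q=5, num_r=5, ratio_qr=1.0)
        cands = self._candidates([("q005", "r005")], hits)
        kept = potential_syntenic_pairs(cands, qg, rg, bm, params)
        assert kept == []  # ratio 1.0 not > 1.0
        params2 = SyntenyParams(num_q=5, num_r=5, ratio_qr=0.99)
        kept2 = potential_syntenic_pairs(cands, qg, rg, bm, params2)
        assert [c.subject_id for c in kept2] == ["r005"]

    def test_transposed_homolog_has_no_support(self):
        qg, rg, hits = collinear_pair(50)
        # q025 additionally hits r049's far neighbourhood partner
        extra = hit("q025", "r049", bitscore=350)
        cands = self._candidates([("q025", "r049")], hits + [extra])
        kept = potential_syntenic_pairs(cands, qg, rg,
                                        best_map(hits + [extra]),
                                        SyntenyParams(num_q=5, num_r=3))
        assert kept == []


class TestResolveBestPairs:
    def _cand(self, q, s, ratio, bitscore=400.0, evalue=1e-40):
        return sl.SyntenyCandidate(q, s, ratio, int(ratio * 40), 40,
                                   hit=hit(q, s, bitscore=bitscore,
                                           evalue=evalue))

    def test_dominant_ratio_wins(self):
        out = resolve_best_pairs([self._cand("q1", "rA", 0.9),
                                  self._cand("q1", "rB", 0.4)])
        assert [c.subject_id for c in out] == ["rA"]

    def test_near_tie_broken_by_bitscore(self):
        out = resolve_best_pairs([
            self._cand("q1", "rA", 0.62, bitscore=200),
            self._cand("q1", "rB", 0.60, bitscore=450)],
            ratio_tie_margin=0.05)
        assert [c.subject_id for c in out] == ["rB"]

    def test_outside_margin_homology_is_ignored(self):
        out = resolve_best_pairs([
            self._cand("q1", "rA", 0.62, bitscore=200),
            self._cand("q1", "rB", 0.50, bitscore=450)],
            ratio_tie_margin=0.05)
        assert [c.subject_id for c in out] == ["rA"]

    def test_subjects_may_recur_across_queries(self):
        out = resolve_best_pairs([self._cand("q1", "rA", 0.9),
                                  self._cand("q2", "rA", 0.8),
                                  self._cand("q3", "rA", 0.7)])
        assert [c.subject_id for c in out] == ["rA"] * 3
        assert len({c.query_id for c in out}) == 3


class TestClassification:
    def test_subject_coverage_failure_blocks(self):
        res = classify_nonsyntenic_orthologs(
            ["q1"], [hit("q1", "r1", pident=75, qcov=0.7, scov=0.5)])
        assert res[0].classification == NONE

    def test_marginal_pass(self):
        res = classify_nonsyntenic_orthologs(
            ["q1"], [hit("q1", "r1", pident=71, qcov=0.61, scov=0.61)])
        assert res[0].classification == NONSYNTENIC_ORTHOLOG
        assert res[0].subject_id == "r1"

    def test_unknown_coverage_disables_classification(self, caplog):
        with caplog.at_level("WARNING"):
            res = classify_nonsyntenic_orthologs(
                ["q1"], [hit("q1", "r1", pident=95, qcov=None, scov=None)])
        assert res[0].classification == NONE
        assert any("disabled" in m for m in caplog.messages)


class TestTandemExpansion:
    def test_members_inherit_syntenic_representative(self):
        rep = SyntenyResult("q1", SYNTENIC, subject_id="r1",
                            support_ratio=0.8)
        out = expand_tandem_synteny(
            [rep], {"q1_t1": "q1", "q1_t2": "q1", "q1_t3": "q1"})
        assert len(out) == 4
        expanded = [r for r in out if r.tandem_expanded]
        assert len(expanded) == 3
        assert all(r.subject_id == "r1" and r.classification == SYNTENIC
                   for r in expanded)

    def test_members_inherit_none_class_too(self):
        rep = SyntenyResult("q1", NONE)
        out = expand_tandem_synteny([rep], {"q1_t1": "q1"})
        assert all(r.classification == NONE for r in out)

    def test_unknown_representative_raises(self):
        with pytest.raises(KeyError, match="unknown"):
            expand_tandem_synteny([SyntenyResult("q1", NONE)],
                                  {"x": "not_there"})


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SyntenyParams(num_q=0)
        with pytest.raises(ValueError):
            SyntenyParams(ratio_qr=0.0)

    def test_num_r_below_num_q_warns(self, caplog):
        with caplog.at_level("WARNING"):
            SyntenyParams(num_q=50, num_r=10)
        assert any("num_r" in m for m in caplog.messages)
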