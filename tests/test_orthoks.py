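"""Alignment, RBH orthology, NG86 statistics, binning and dating."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import local_align_score, ng_counts
from carptrx import ng86
from carptrx.config import AlignmentScoring
from carptrx.io import TranscriptRecord
from carptrx.orthoks import (BestHit, all_pairs_best_hits,
                             build_codon_alignment, date_divergence,
                             ks_histogram, ortholog_ks_pipeline,
                             reciprocal_best_hits)
from carptrx.simulate import EvolverParams, evolve_ortholog_pair


class TestBestHits:
    def test_identical_query_scores_full_length(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(4, size=40))
        other = "".join("ACGT"[i] for i in rng.integers(4, size=40))
        hits = all_pairs_best_hits([TranscriptRecord("q", seq)],
                                   [TranscriptRecord("t1", seq),
                                    TranscriptRecord("t2", other)])
        assert hits["q"].target == "t1"
        assert hits["q"].score == len(seq)

    def test_matches_dp_oracle_3x3(self, rng):
        def mk(n):
            return "".join("ACGT"[i] for i in rng.integers(4, size=n))

        set_a = [TranscriptRecord(f"a{i}", mk(35)) for i in range(3)]
        set_b = [TranscriptRecord(f"b{i}", mk(35)) for i in range(3)]
        hits = all_pairs_best_hits(set_a, set_b)
        for qa in set_a:
            scores = {tb.id: local_align_score(qa.seq, tb.seq)
                      for tb in set_b}
            assert hits[qa.id].score == max(scores.values())
            best = [t for t, s in scores.items() if s == max(scores.values())]
            assert hits[qa.id].target in best

    def test_tie_broken_by_longer_alignment(self):
        # two targets contain the same perfect 12-bp match; t2 additionally
        # extends it with a gapped continuation of equal score
        q = TranscriptRecord("q", "ACGTACGTACGTTTTTGGGCC")
        t1 = TranscriptRecord("t1", "ACGTACGTACGT")
        t2 = TranscriptRecord("t2", "ACGTACGTACGTCCCCC")
        hits = all_pairs_best_hits([q], [t1, t2])
        assert hits["q"].score == 12.0
        assert hits["q"].aln_length >= 12


class TestRBH:
    def _hits(self, pairs):
        return {q: BestHit(q, t, s, ln) for q, t, s, ln in pairs}

    def test_mutual_long_alignment_kept(self):
        ab = self._hits([("a", "b", 400, 350)])
        ba = self._hits([("b", "a", 400, 350)])
        assert reciprocal_best_hits(ab, ba, 300) == [("a", "b")]

    def test_short_alignment_dropped(self):
        ab = self._hits([("a", "b", 260, 250)])
        ba = self._hits([("b", "a", 260, 250)])
        assert reciprocal_best_hits(ab, ba, 300) == []

    def test_nonreciprocal_dropped(self):
        ab = self._hits([("a", "b", 400, 350)])
        ba = self._hits([("b", "a2", 420, 360)])
        assert reciprocal_best_hits(ab, ba, 300) == []

    def test_symmetry_under_set_swap(self, rng, random_cds):
        set_a = [TranscriptRecord(f"a{i}", random_cds(40)) for i in range(3)]
        # b-set: mutated copies so best hits are meaningful
        set_b = []
        for i, r in enumerate(set_a):
            seq = list(r.seq)
            for j in rng.integers(len(seq), size=4):
                seq[j] = "ACGT"[rng.integers(4)]
            set_b.append(TranscriptRecord(f"b{i}", "".join(seq)))
        ab = all_pairs_best_hits(set_a, set_b)
        ba = all_pairs_best_hits(set_b, set_a)
        fwd = set(reciprocal_best_hits(ab, ba, 30))
        rev = {(a, b) for b, a in reciprocal_best_hits(ba, ab, 30)}
        assert fwd == rev


class TestCodonAlignment:
    def test_identical_cds_no_gaps(self, random_cds):
        cds = random_cds(30)
        a, b = build_codon_alignment(cds, cds)
        assert a == b == cds

    def test_single_codon_insertion_one_gap(self, random_cds):
        cds = random_cds(30)
        ins = cds[:45] + "GAA" + cds[45:]
        a, b = build_codon_alignment(cds, ins)
        assert b == ins
        assert a.count("-") == 3
        gap_at = a.index("---")
        assert gap_at % 3 == 0

    def test_internal_stop_rejected(self, random_cds):
        cds = random_cds(20)
        bad = cds[:30] + "TAA" + cds[33:]
        with pytest.raises(ValueError, match="stop"):
            build_codon_alignment(cds, bad, id_b="seqB")

    def test_frame_violation_rejected(self, random_cds):
        with pytest.raises(ValueError, match="multiple of 3"):
            build_codon_alignment(random_cds(20), random_cds(20) + "AC")

    @given(st.integers(0, 10**6))
    def test_backthread_retranslates_to_protein_alignment(self, seed):
        from Bio.Seq import Seq

        r = np.random.default_rng(seed)
        cds = "".join(ng86.SENSE_CODONS[i]
                      for i in r.integers(61, size=25))
        # delete two codons and mutate a couple of bases
        cut = int(r.integers(1, 20))
        other = cds[: 3 * cut] + cds[3 * (cut + 2):]
        a, b = build_codon_alignment(cds, other)
        assert len(a) == len(b)
        for gapped, orig in ((a, cds), (b, other)):
            assert gapped.replace("-", "") == orig
            # re-translating gapped codons reproduces a protein alignment row
            prot = "".join(
                "-" if gapped[i:i + 3] == "---"
                else str(Seq(gapped[i:i + 3]).translate())
                for i in range(0, len(gapped), 3))
            assert prot.replace("-", "") == str(Seq(orig).translate())


class TestNG86:
    def test_identical_sequences_zero(self, random_cds):
        cds = random_cds(40)
        s = ng86.ng86_stats(cds, cds)
        assert s.Sd == s.Nd == 0
        assert s.Ks == 0 and s.Ka == 0
        assert s.S + s.N == pytest.approx(3 * 40)

    def test_symmetry(self, random_cds):
        for _ in range(10):
            a, b = random_cds(15), random_cds(15)
            sa = ng86.ng86_stats(a, b)
            sb = ng86.ng86_stats(b, a)
            assert sa == sb

    def test_all_single_codon_pairs_match_oracle(self):
        """Exhaustive 61x61 check of (S, N, Sd, Nd) against the brute-force
        site/pathway enumerator."""
        for c1 in ng86.SENSE_CODONS:
            for c2 in ng86.SENSE_CODONS:
                got = ng86.ng86_stats(c1, c2)
                S, N, Sd, Nd = ng_counts([c1], [c2])
                assert got.S == pytest.approx(S), (c1, c2)
                assert got.N == pytest.approx(N), (c1, c2)
                assert got.Sd == pytest.approx(Sd), (c1, c2)
                assert got.Nd == pytest.approx(Nd), (c1, c2)

    def test_random_three_codon_alignments_match_oracle(self, rng):
        for _ in range(300):
            idx = rng.integers(61, size=(2, 3))
            a = "".join(ng86.SENSE_CODONS[i] for i in idx[0])
            b = "".join(ng86.SENSE_CODONS[i] for i in idx[1])
            got = ng86.ng86_stats(a, b)
            S, N, Sd, Nd = ng_counts(
                [a[i:i + 3] for i in range(0, 9, 3)],
                [b[i:i + 3] for i in range(0, 9, 3)])
            assert (got.S, got.N) == pytest.approx((S, N))
            assert (got.Sd, got.Nd) == pytest.approx((Sd, Nd))

    def test_gap_and_n_columns_excluded(self):
        s = ng86.ng86_stats("ATG---GCT", "ATGAAAGCT")
        assert s.n_codons == 2
        s2 = ng86.ng86_stats("ATGANAGCT", "ATGAAAGCT")
        assert s2.n_codons == 2

    def test_saturation_flagged_undefined(self):
        # force pS >= 3/4 via a tiny saturated alignment: Leu codons
        # differing synonymously everywhere are hard to reach; check the
        # correction function directly plus a saturated proportion
        assert math.isnan(ng86.jukes_cantor(0.75))
        assert math.isnan(ng86.jukes_cantor(0.9))
        assert ng86.jukes_cantor(0.0) == 0.0

    def test_ks_monotone_in_ps(self):
        ps = np.linspace(0, 0.74, 50)
        ks = [ng86.jukes_cantor(p) for p in ps]
        assert all(x < y for x, y in zip(ks, ks[1:]))
        assert all(k >= p for k, p in zip(ks, ps))


class TestKsHistogram:
    def test_direct_binning(self):
        h = ks_histogram([0.0081, 0.0085, 0.0033], 0.002)
        assert h.counts == {0.008: 2, 0.002: 1}
        assert h.peak_ks == 0.008

    def test_empty_input(self):
        h = ks_histogram([], 0.002)
        assert h.counts == {}
        assert h.peak_ks is None
        assert h.n_pairs == 0

    def test_boundary_value_half_open(self):
        assert ks_histogram([0.008], 0.002).counts == {0.008: 1}
        assert ks_histogram([0.002], 0.002).counts == {0.002: 1}

    def test_undefined_excluded_and_counted(self):
        h = ks_histogram([0.001, float("nan"), None, 0.0015], 0.002)
        assert h.counts == {0.0: 2}
        assert h.n_undefined == 2
        assert sum(h.counts.values()) + h.n_undefined == h.n_pairs == 4

    def test_tie_resolved_to_lower_edge(self):
        h = ks_histogram([0.001, 0.005], 0.002)
        assert h.peak_ks == 0.0


class TestDating:
    def test_worked_example(self):
        res = date_divergence(0.008, 3.51e-9, (0.006, 0.01))
        assert res.t_my == 2.2
        assert res.t_low_my == 1.7
        assert res.t_high_my == 2.8

    def test_zero_divergence(self):
        assert date_divergence(0.0, 3.51e-9).t_my == 0.0

    def test_linearity_before_truncation(self):
        a = date_divergence(0.004, 3.51e-9)
        b = date_divergence(0.008, 3.51e-9)
        assert b.t_years == pytest.approx(2 * a.t_years)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            date_divergence(0.008, 0.0)


class TestPipeline:
    def test_simulated_pairs_recovered_end_to_end(self):
        # RBH + codon alignment + NG86 on a small simulated ortholog set
        set_a, set_b = [], []
        for i in range(4):
            _, (a, b), _ = evolve_ortholog_pair(
                EvolverParams(150, 0.02, 0.1, seed=100 + i))
            # add UTR-like padding and an ORF start/stop so catalog works
            set_a.append(TranscriptRecord(f"a{i}", "ATG" + a + "TAA"))
            set_b.append(TranscriptRecord(f"b{i}", "ATG" + b + "TAA"))
        pairs, hist = ortholog_ks_pipeline(set_a, set_b, min_orf_aa=50,
                                           min_aln=300)
        assert {(p.id_a, p.id_b) for p in pairs} == {
            (f"a{i}", f"b{i}") for i in range(4)}
        assert sum(hist.counts.values()) == 4
        for p in pairs:
            assert 0 <= p.stats.Ks < 0.1
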