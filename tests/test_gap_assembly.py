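"""Overlap alignment, bridge merging, ORF scanning, CDS classification."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement
from oracles import brute_force_longest_orf, brute_force_overlap

from unibridge import gap_assembly as ga
from unibridge import synthetic_data as sd


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestOverlapAlign:
    def test_exact_shared_overlap(self):
        rng = np.random.default_rng(0)
        s = _rand(rng, 200)
        aln = ga.overlap_align(_rand(rng, 100) + s, s + _rand(rng, 100))
        assert aln.columns == 200
        assert aln.identity == 1.0
        assert aln.a_start == 100
        assert aln.b_end == 200

    def test_two_substitutions_identity_99_percent(self):
        rng = np.random.default_rng(1)
        s = _rand(rng, 200)
        s_mut = s[:50] + ("A" if s[50] != "A" else "C") + s[51:120] \
            + ("G" if s[120] != "G" else "T") + s[121:]
        aln = ga.overlap_align(_rand(rng, 80) + s, s_mut + _rand(rng, 80))
        assert aln.columns == 200
        assert aln.identity == pytest.approx(0.99)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_scan(self, seed):
        """Planted substitution-only overlaps on 300-nt pairs: the DP
        finds the same offset and score as the exhaustive scan."""
        rng = np.random.default_rng(seed)
        for _ in range(20):
            k = int(rng.integers(40, 90))
            s = _rand(rng, k)
            n_sub = int(rng.integers(0, max(1, k // 25)))
            s_mut = list(s)
            for i in rng.choice(k, size=n_sub, replace=False):
                s_mut[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s_mut[i]]
            a = _rand(rng, 300 - k) + s
            b = "".join(s_mut) + _rand(rng, 300 - k)
            score, length = brute_force_overlap(a, b)
            aln = ga.overlap_align(a, b)
            assert aln.score == score
            assert aln.columns == length

    def test_thresholds(self):
        rng = np.random.default_rng(3)
        s = _rand(rng, 60)
        aln = ga.overlap_align(_rand(rng, 50) + s, s + _rand(rng, 50))
        assert aln.passes(min_overlap=40, min_identity=0.95)
        assert not aln.passes(min_overlap=61, min_identity=0.95)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ga.overlap_align("", "ACGT")


class TestMergeWithBridge:
    def _pair_seqs(self, truth, pair):
        f5 = truth.fragment_map[pair.five_prime_id]
        f3 = truth.fragment_map[pair.three_prime_id]
        T = truth.transcripts[pair.transcript_id].seq
        return T[: f5.end_nt], T[f3.start_nt - 1 :], T

    def test_reconstruction_identity(self, truth):
        """Error-free bridges with 250-nt flanks reproduce the original
        transcript exactly, for gapped and overlapping pairs alike."""
        for i, pair in enumerate(truth.true_pairs):
            seq5, seq3, T = self._pair_seqs(truth, pair)
            bridge = sd.simulate_bridge(truth, pair, 250, 0.0, seed=100 + i)
            result = ga.merge_with_bridge(seq5, seq3, bridge)
            assert result.assembled_seq == T
            assert result.assembled_length_nt <= len(seq5) + len(seq3) + len(bridge)
            assert result.assembled_length_nt >= max(len(seq5), len(seq3), len(bridge))

    def test_strand_symmetry(self, truth):
        pair = truth.true_pairs[1]
        seq5, seq3, _ = self._pair_seqs(truth, pair)
        bridge = sd.simulate_bridge(truth, pair, 200, 0.0, seed=5)
        a = ga.merge_with_bridge(seq5, seq3, bridge)
        b = ga.merge_with_bridge(seq5, seq3, reverse_complement(bridge))
        assert a.assembled_seq == b.assembled_seq

    def test_bridge_with_one_flank_refused(self, truth):
        pair = truth.true_pairs[1]
        seq5, _, _ = self._pair_seqs(truth, pair)
        rng = np.random.default_rng(9)
        bridge = seq5[-250:] + _rand(rng, 150)  # anchors only in the 5' member
        with pytest.raises(ga.MergeRefused, match="no second flank"):
            ga.merge_with_bridge(seq5, _rand(rng, 400), bridge)

    def test_unrelated_bridge_refused(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ga.MergeRefused):
            ga.merge_with_bridge(_rand(rng, 300), _rand(rng, 300), _rand(rng, 300))

    def test_bridge_errors_resolved_toward_unigene(self, truth):
        """Point errors inside the flank overlaps never reach the merged
        sequence when the unigene base is preferred."""
        pair = next(p for p in truth.true_pairs if p.gap_aa is not None)
        seq5, seq3, T = self._pair_seqs(truth, pair)
        bridge = sd.simulate_bridge(truth, pair, 250, 0.0, seed=6)
        # a few errors in the first and last 100 bases (inside the flanks)
        b = list(bridge)
        for i in list(range(0, 100, 25)) + list(range(len(b) - 100, len(b), 25)):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        result = ga.merge_with_bridge(seq5, seq3, "".join(b))
        assert result.assembled_seq[: len(seq5)] == seq5
        assert result.assembled_seq[-len(seq3):] == seq3


class TestOrfs:
    def test_hand_checkable_orf(self):
        (orf,) = [o for o in ga.find_orfs("ATGAAATGA") if o.frame == 1]
        assert orf.protein_length_aa == 2
        assert orf.has_terminal_stop
        assert not orf.has_upstream_inframe_stop
        assert (orf.start_nt, orf.end_nt) == (1, 9)

    def test_upstream_stop_flag(self):
        orf = ga.longest_orf("TAA" + "ATGAAAAAAAAAAAATGA")
        assert orf.has_upstream_inframe_stop
        assert orf.completeness == "complete"

    def test_no_atg_returns_empty(self):
        assert ga.find_orfs("CCCCCCCCC") == []
        assert ga.longest_orf("CCCCCCCCC") is None

    def test_orf_without_terminal_stop(self):
        orf = ga.longest_orf("ATGAAAAAA")
        assert not orf.has_terminal_stop
        assert orf.protein_length_aa == 3
        assert orf.completeness in ("partial_3prime", "internal")

    @pytest.mark.parametrize("seed", range(5))
    def test_longest_matches_six_frame_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            seq = _rand(rng, int(rng.integers(60, 2000)))
            expected = brute_force_longest_orf(seq)
            got = ga.longest_orf(seq)
            if expected is None:
                assert got is None
            else:
                assert got.protein_length_aa == expected

    def test_protein_length_invariant(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            seq = _rand(rng, 500)
            for orf in ga.find_orfs(seq):
                span = orf.end_nt - orf.start_nt + 1
                expected = span // 3 - 1 if orf.has_terminal_stop else span // 3
                assert orf.protein_length_aa == expected


class TestClassifyCds:
    @pytest.mark.parametrize(
        "aa,lo,hi,expected",
        [(626, 521, 636, True), (293, 521, 636, False), (534, 516, 542, True)],
    )
    def test_range_calls(self, aa, lo, hi, expected):
        orf = ga.OrfReport(10, 10 + 3 * (aa + 1) - 1, 1, aa, True, True)
        assert ga.classify_cds(orf, (lo, hi)) is expected

    def test_missing_termini_block_completeness(self):
        no_stop = ga.OrfReport(10, 100, 1, 30, True, False)
        assert not ga.classify_cds(no_stop, (1, 100))
        no_5prime = ga.OrfReport(1, 100, 1, 30, False, True)
        assert not ga.classify_cds(no_5prime, (1, 100))

    def test_monotone_in_range_width(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            aa = int(rng.integers(50, 700))
            lo = int(rng.integers(1, 600))
            hi = lo + int(rng.integers(0, 200))
            orf = ga.OrfReport(5, 5 + 3 * aa + 2, 1, aa, True, True)
            if ga.classify_cds(orf, (lo, hi)):
                assert ga.classify_cds(orf, (max(1, lo - 10), hi + 10))
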