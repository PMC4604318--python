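"""Span building, the gap rule, overlap consistency and pair enumeration."""

import dataclasses

import numpy as np
import pytest

from unibridge import datasets, pair_selection as ps
from unibridge.grouping import ExpressionGroup
from unibridge.io_tables import AlignmentRow, ReferenceInfo, UnigeneRecord


def _ref(lengths=None, ranges=None):
    return ReferenceInfo(lengths or {}, ranges or {})


def _span(uid, ref_id, start, end, seq="A" * 3000, offset=1, ref_len=600,
          covers5=None, covers3=None):
    return ps.ProteinSpan(
        uid, ref_id, start, end,
        covers5 if covers5 is not None else start <= ps.TERMINAL_TOLERANCE_AA,
        covers3 if covers3 is not None else end >= ref_len - ps.TERMINAL_TOLERANCE_AA,
        seq, offset, ref_len,
    )


class TestBuildSpan:
    def test_terminal_flags_from_reference_length(self):
        rec = UnigeneRecord("u1", "A" * 600)
        row = AlignmentRow("u1", "P1", 1, 177, 1, 531, 1)
        span = ps.build_span(row, rec, _ref({"P1": 600}))
        assert span.covers_5prime and not span.covers_3prime
        row2 = AlignmentRow("u1", "P1", 359, 600, 1, 600, 3)
        span2 = ps.build_span(row2, rec, _ref({"P1": 600}))
        assert span2.covers_3prime and not span2.covers_5prime

    def test_negative_frame_orients_reverse_complement(self):
        seq = "ATGGCCAAATTTGGGCCCTAA"
        from Bio.Seq import reverse_complement

        rec = UnigeneRecord("u1", reverse_complement(seq))
        row = AlignmentRow("u1", "P1", 1, 6, 1, 18, -1)
        span = ps.build_span(row, rec, _ref({"P1": 200}))
        assert span.oriented_seq == seq
        assert (span.start_aa, span.end_aa) == (1, 6)

    def test_aa_to_nt_codon_mapping(self):
        span = _span("u", "P", 10, 20, offset=7)
        assert span.aa_to_nt(10) == 7
        assert span.aa_to_nt(12) == 13
        with pytest.raises(ValueError):
            span.aa_to_nt(9)


class TestGapRule:
    @pytest.mark.parametrize(
        "end5,start3,expected",
        [(101, 208, 107), (157, 166, 9), (170, 164, None), (100, 100, None), (100, 101, 1)],
    )
    def test_gap_between_coords(self, end5, start3, expected):
        assert ps.gap_between_coords(end5, start3) == expected

    def test_gap_between_spans(self):
        s5 = _span("a", "P", 12, 101)
        s3 = _span("b", "P", 208, 600)
        assert ps.gap_between(s5, s3) == 107
        assert ps.overlap_aa_between(_span("a", "P", 1, 170), _span("b", "P", 164, 234)) == 7

    def test_cross_reference_spans_rejected(self):
        with pytest.raises(ValueError, match="different references"):
            ps.gap_between(_span("a", "P1", 1, 100), _span("b", "P2", 200, 300))


class TestReferenceLocation:
    @pytest.mark.parametrize(
        "loc,gap",
        [
            ("12-101+208-3'", 107),
            ("5'-177+359-3'", 182),
            ("5'-170+164-234", None),
            ("5′–157+166–3′", 9),  # typographic characters
        ],
    )
    def test_parse_and_gap(self, loc, gap):
        assert ps.parse_reference_location(loc).gap_aa == gap

    def test_published_location_strings_all_parse(self):
        for fam in ("NRT", "PHT"):
            for loc in datasets.candidate_pairs(fam)["reference_location"]:
                parsed = ps.parse_reference_location(loc)
                assert parsed.end5 >= 1 and parsed.start3 >= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_format_round_trips_through_parse(self, seed):
        rng = np.random.default_rng(seed)
        ref_len = 600
        s5_start = int(rng.integers(1, 50))
        s5_end = int(rng.integers(s5_start + 10, 300))
        s3_start = int(rng.integers(s5_end - 5, 450))
        s3_end = int(rng.integers(max(s3_start, s5_end) + 10, ref_len + 1))
        span5 = _span("a", "P", s5_start, s5_end, ref_len=ref_len)
        span3 = _span("b", "P", s3_start, s3_end, ref_len=ref_len)
        loc = ps.format_reference_location(span5, span3)
        parsed = ps.parse_reference_location(loc, reference_length_aa=ref_len)
        assert (parsed.start5, parsed.end5) == (span5.start_aa, span5.end_aa)
        assert (parsed.start3, parsed.end3) == (span3.start_aa, span3.end_aa)
        assert parsed.five_terminal == (span5.start_aa == 1)
        assert parsed.three_terminal == (span3.end_aa == ref_len)


def _spans_from_sequence(seq, split_end5_aa, split_start3_aa, ref_len):
    """Two spans cut from one coding sequence (codon 1 at position 1)."""
    five = ps.ProteinSpan("five", "P", 1, split_end5_aa, True, False,
                          seq[: 3 * split_end5_aa], 1, ref_len)
    start_nt = 3 * (split_start3_aa - 1)
    three = ps.ProteinSpan("three", "P", split_start3_aa, ref_len, False, True,
                           seq[start_nt:], 1, ref_len)
    return five, three


class TestOverlapConsistent:
    def test_identical_overlap_true(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        five, three = _spans_from_sequence(seq, 120, 100, 200)
        assert ps.overlap_consistent(five, three)

    def test_half_identity_false(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        five, three = _spans_from_sequence(seq, 120, 100, 200)
        # corrupt every other base of the three-prime copy's overlap
        corrupted = "".join(
            ("A" if c != "A" else "C") if i % 2 else c
            for i, c in enumerate(three.oriented_seq)
        )
        three_bad = dataclasses.replace(three, oriented_seq=corrupted)
        assert not ps.overlap_consistent(five, three_bad)

    def test_gap_pair_undefined(self):
        with pytest.raises(ValueError):
            ps.overlap_consistent(_span("a", "P", 1, 100), _span("b", "P", 150, 300))

    def test_generator_truth(self, truth, pipeline_result):
        """Overlapping planted fragments pass; diverged decoys fail."""
        spans = pipeline_result.spans
        for pair in truth.true_pairs:
            if pair.gap_aa is None:
                assert ps.overlap_consistent(
                    spans[pair.five_prime_id], spans[pair.three_prime_id]
                )
        decoys = [u for u, f in truth.fragment_map.items() if f.kind == "decoy"]
        assert decoys
        for d in decoys:
            tid = truth.fragment_map[d].transcript_id
            pair = next(p for p in truth.true_pairs if p.transcript_id == tid)
            five = spans[pair.five_prime_id]
            assert not ps.overlap_consistent(five, spans[d])


class TestEnumeratePairs:
    def test_single_gap_pair_emitted(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=1900))
        group = ExpressionGroup(["five", "three"], "NRT1/PTR", 0.0)
        five = ps.ProteinSpan("five", "P", 12, 101, True, False, seq[: 3 * 101], 34, 600)
        three = ps.ProteinSpan("three", "P", 208, 600, False, True, seq[621:], 1, 600)
        pairs, excl = ps.enumerate_pairs(group, {"five": five, "three": three})
        assert excl == []
        (pair,) = pairs
        assert (pair.five_prime_id, pair.three_prime_id) == ("five", "three")
        assert pair.gap_aa == 107

    def test_complete_members_excluded(self):
        group = ExpressionGroup(["a", "b"], "NRT2", 0.0)
        spans = {
            "a": _span("a", "P", 1, 595, covers5=True, covers3=True),
            "b": _span("b", "P", 2, 596, covers5=True, covers3=True),
        }
        pairs, excl = ps.enumerate_pairs(group, spans)
        assert pairs == []
        assert [e.reason for e in excl] == ["both_complete"]

    def test_same_end_and_containment_excluded(self):
        group = ExpressionGroup(["a", "b", "c"], "PHT1", 0.0)
        spans = {
            "a": _span("a", "P", 3, 200, covers5=True, covers3=False),
            "b": _span("b", "P", 10, 300, covers5=True, covers3=False),
            "c": _span("c", "P", 20, 150, covers5=False, covers3=False),
        }
        pairs, excl = ps.enumerate_pairs(group, spans)
        assert pairs == []
        reasons = {(e.first_id, e.second_id): e.reason for e in excl}
        assert reasons[("a", "b")] == "same_end"
        assert reasons[("a", "c")] == "containment"

    def test_partition_property(self, pipeline_result):
        """Considered combinations = emitted + excluded, per group."""
        n_considered = sum(
            len(g.member_ids) * (len(g.member_ids) - 1) // 2
            for g in pipeline_result.groups
        )
        assert n_considered == len(pipeline_result.pairs) + len(pipeline_result.exclusions)

    def test_planted_pairs_recovered_with_true_gap(self, truth, pipeline_result):
        got = {
            (p.five_prime_id, p.three_prime_id): (p.gap_aa, p.overlap_aa)
            for p in pipeline_result.pairs
        }
        want = {
            (t.five_prime_id, t.three_prime_id): (t.gap_aa, t.overlap_aa)
            for t in truth.true_pairs
        }
        assert got == want
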