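"""Position-based selection of unigene pairs that may share a transcript.

Within one expression group, each unigene's footprint on a reference
protein (from a translated alignment) is classified — reaching the 5′
terminus, the 3′ terminus, both, or neither. Ordered pairs
(5′-member, 3′-member) are then emitted when the two footprints either
leave a gap on the reference or overlap *consistently* at the
nucleotide level; everything else is excluded with a recorded reason.

The gap convention follows the source tables: for a 5′ member ending at
reference residue e₅ and a 3′ member starting at s₃,

    gap = s₃ − e₅   (in aa, when positive; otherwise the spans overlap).

Note this is one more than the count of strictly uncovered residues;
the convention is kept because every downstream size estimate
(estimated product = designed + 3·gap) is defined against it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .grouping import ExpressionGroup
from .io_tables import AlignmentRow, ReferenceInfo, UnigeneRecord

__all__ = [
    "TERMINAL_TOLERANCE_AA",
    "ProteinSpan",
    "CandidatePair",
    "ExclusionRecord",
    "LocationPair",
    "build_span",
    "gap_between",
    "gap_between_coords",
    "overlap_aa_between",
    "overlap_consistent",
    "enumerate_pairs",
    "parse_reference_location",
    "format_reference_location",
]

#: a span is called 5′-terminal if start_aa <= this, 3′-terminal if
#: end_aa >= reference length - this. Display-level only: pairing
#: depends on relative positions, never on these labels.
TERMINAL_TOLERANCE_AA = 15

#: minimum nucleotide identity over the full overlap for two
#: overlapping spans to be considered fragments of one transcript
DEFAULT_MIN_OVERLAP_IDENTITY = 0.95


@dataclass(frozen=True)
class ProteinSpan:
    """A unigene's footprint on a reference protein.

    ``oriented_seq`` is the unigene sequence on the coding strand;
    ``coding_offset_nt`` is the 1-based position in ``oriented_seq`` of
    the first base of codon ``start_aa``, so reference residue ``p``
    (start_aa <= p <= end_aa) maps to bases
    ``coding_offset_nt + 3*(p - start_aa) .. +2``.
    """

    unigene_id: str
    reference_id: str
    start_aa: int
    end_aa: int
    covers_5prime: bool
    covers_3prime: bool
    oriented_seq: str
    coding_offset_nt: int
    reference_length_aa: int | None = None

    def aa_to_nt(self, p: int) -> int:
        if not self.start_aa <= p <= self.end_aa:
            raise ValueError(f"residue {p} outside span {self.start_aa}-{self.end_aa}")
        return self.coding_offset_nt + 3 * (p - self.start_aa)


@dataclass(frozen=True)
class CandidatePair:
    """An ordered (5′-unigene, 3′-unigene) pair with gap or overlap."""

    five_prime_id: str
    three_prime_id: str
    reference_id: str
    reference_location: str
    gap_aa: int | None
    overlap_aa: int = 0

    def __post_init__(self) -> None:
        if self.gap_aa is not None and self.gap_aa <= 0:
            raise ValueError("gap_aa must be a positive integer or None")


EXCLUSION_REASONS = (
    "mismatched_overlap",
    "both_complete",
    "same_end",
    "containment",
    "cross_reference",
)


@dataclass(frozen=True)
class ExclusionRecord:
    """Why a considered combination was not emitted as a candidate pair."""

    first_id: str
    second_id: str
    reason: str
    detail: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


# ---------------------------------------------------------------------------
# Span construction

def build_span(
    row: AlignmentRow,
    unigene: UnigeneRecord,
    ref: ReferenceInfo | None = None,
    terminal_tolerance_aa: int = TERMINAL_TOLERANCE_AA,
) -> ProteinSpan:
    """Turn one alignment row into a protein-coordinate footprint.

    The unigene sequence is reverse-complemented when the frame is
    negative, so ``oriented_seq`` always reads in the coding direction.
    Terminal flags need the reference protein's length; if ``ref`` is
    None or does not know the protein, only the 5′ flag (which needs no
    length) is computed and the 3′ flag is False.
    """
    if row.query_id != unigene.id:
        raise ValueError(f"alignment row is for {row.query_id!r}, not {unigene.id!r}")
    row = row.normalized()
    if row.frame > 0:
        oriented = unigene.seq
        offset = row.query_start_nt
    else:
        oriented = reverse_complement(unigene.seq)
        offset = unigene.length_nt - row.query_end_nt + 1
    ref_len = None
    if ref is not None:
        ref_len = ref.protein_lengths.get(row.subject_id)
    covers5 = row.subject_start_aa <= terminal_tolerance_aa
    covers3 = ref_len is not None and row.subject_end_aa >= ref_len - terminal_tolerance_aa
    return ProteinSpan(
        unigene.id, row.subject_id,
        row.subject_start_aa, row.subject_end_aa,
        covers5, covers3, oriented, offset, ref_len,
    )


# ---------------------------------------------------------------------------
# Gap rule

def gap_between_coords(end5_aa: int, start3_aa: int) -> int | None:
    """Gap in aa between a 5′ span ending at ``end5_aa`` and a 3′ span
    starting at ``start3_aa``: ``start3 - end5`` when positive, else
    ``None`` (the spans overlap)."""
    g = start3_aa - end5_aa
    return g if g > 0 else None


def gap_between(span5: ProteinSpan, span3: ProteinSpan) -> int | None:
    """Gap in aa between two spans on the same reference protein."""
    if span5.reference_id != span3.reference_id:
        raise ValueError(
            f"spans on different references: {span5.reference_id!r} vs {span3.reference_id!r}"
        )
    if span5.start_aa >= span3.start_aa:
        raise ValueError("span5 must start before span3")
    return gap_between_coords(span5.end_aa, span3.start_aa)


def overlap_aa_between(span5: ProteinSpan, span3: ProteinSpan) -> int:
    """Overlap in aa (0 when a gap is present): ``end5 - start3 + 1``."""
    if gap_between(span5, span3) is not None:
        return 0
    return min(span5.end_aa, span3.end_aa) - span3.start_aa + 1


# ---------------------------------------------------------------------------
# Overlap consistency

def _overlap_subseq(span: ProteinSpan, lo_aa: int, hi_aa: int) -> str | None:
    """Nucleotide subsequence of the span covering residues lo..hi, or
    None when the mapping falls outside the unigene sequence."""
    start = span.aa_to_nt(lo_aa)
    end = span.aa_to_nt(hi_aa) + 2
    if start < 1 or end > len(span.oriented_seq):
        return None
    return span.oriented_seq[start - 1 : end]


def _global_identity(a: str, b: str) -> float:
    aligner = PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def overlap_consistent(
    span5: ProteinSpan,
    span3: ProteinSpan,
    min_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
) -> bool:
    """Do two overlapping spans agree at the nucleotide level?

    True iff the nucleotide sub-sequences under the shared aa interval
    align globally with identity >= ``min_identity`` over the full
    overlap. Windows containing N, or overlap intervals that map
    outside either unigene, return False.
    """
    if gap_between(span5, span3) is not None:
        raise ValueError("spans do not overlap; consistency is undefined")
    lo = span3.start_aa
    hi = min(span5.end_aa, span3.end_aa)
    a = _overlap_subseq(span5, lo, hi)
    b = _overlap_subseq(span3, lo, hi)
    if a is None or b is None:
        return False
    if "N" in a or "N" in b:
        return False
    return _global_identity(a, b) >= min_identity


# ---------------------------------------------------------------------------
# Reference-location strings

@dataclass(frozen=True)
class LocationPair:
    """Parsed form of a reference-location string like ``12-101+208-3'``.

    A literal 5′/3′ token marks a terminal end whose exact residue is
    not printed; ``start5``/``end3`` are then 1 / the reference length
    (or None when the length is unknown).
    """

    start5: int | None
    end5: int
    start3: int
    end3: int | None
    five_terminal: bool
    three_terminal: bool

    @property
    def gap_aa(self) -> int | None:
        return gap_between_coords(self.end5, self.start3)

    @property
    def overlap_aa(self) -> int:
        if self.gap_aa is not None:
            return 0
        hi = self.end5 if self.end3 is None else min(self.end5, self.end3)
        return hi - self.start3 + 1


def _norm_location(s: str) -> str:
    return (
        s.replace("′", "'")  # prime
        .replace("–", "-")   # en dash
        .replace("−", "-")   # minus sign
        .strip()
    )


_LOC_RE = re.compile(r"^(5'|\d+)-(\d+)\+(\d+)-(3'|\d+)$")


def parse_reference_location(s: str, reference_length_aa: int | None = None) -> LocationPair:
    """Parse a Table-style reference location into coordinates and flags.

    Accepts both typographic (en dash, prime) and ASCII characters.
    """
    m = _LOC_RE.match(_norm_location(s))
    if not m:
        raise ValueError(f"cannot parse reference location {s!r}")
    t5, e5, s3, t3 = m.groups()
    five_term = t5 == "5'"
    three_term = t3 == "3'"
    return LocationPair(
        start5=1 if five_term else int(t5),
        end5=int(e5),
        start3=int(s3),
        end3=reference_length_aa if three_term else int(t3),
        five_terminal=five_term,
        three_terminal=three_term,
    )


def format_reference_location(span5: ProteinSpan, span3: ProteinSpan) -> str:
    """Render two spans in the table style, e.g. ``5'-177+359-3'``.

    The literal 5′/3′ token is used only when the span actually starts
    at residue 1 / ends at the reference's last residue, so the string
    round-trips through :func:`parse_reference_location`.
    """
    left_start = "5'" if span5.start_aa == 1 else str(span5.start_aa)
    right_end = (
        "3'"
        if span3.reference_length_aa is not None
        and span3.end_aa == span3.reference_length_aa
        else str(span3.end_aa)
    )
    return f"{left_start}-{span5.end_aa}+{span3.start_aa}-{right_end}"


# ---------------------------------------------------------------------------
# Pair enumeration

def _is_complete(span: ProteinSpan, flags: Mapping[str, bool] | None) -> bool:
    if flags is not None and span.unigene_id in flags:
        return bool(flags[span.unigene_id])
    return span.covers_5prime and span.covers_3prime


def enumerate_pairs(
    group: ExpressionGroup,
    spans: Mapping[str, ProteinSpan],
    complete_cds_flags: Mapping[str, bool] | None = None,
    min_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
    max_pairs_per_group: int | None = None,
) -> tuple[list[CandidatePair], list[ExclusionRecord]]:
    """Consider every pair in a group; emit candidates, record exclusions.

    A combination is emitted when the ordered spans leave a gap, or
    overlap consistently at the nucleotide level. Exclusion reasons, in
    the order tested: ``cross_reference`` (different reference
    proteins), ``both_complete`` (either member already carries a
    complete CDS), ``containment`` (one footprint inside the other, or
    an overlap that maps outside a unigene), ``same_end`` (both
    footprints anchored at the same reference terminus),
    ``mismatched_overlap`` (overlapping but disagreeing sequences).
    Emissions and exclusions partition the considered combinations.
    """
    pairs: list[CandidatePair] = []
    excl: list[ExclusionRecord] = []
    members = [m for m in sorted(group.member_ids) if m in spans]
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = spans[members[i]], spans[members[j]]
            if a.reference_id != b.reference_id:
                excl.append(ExclusionRecord(a.unigene_id, b.unigene_id, "cross_reference"))
                continue
            if _is_complete(a, complete_cds_flags) or _is_complete(b, complete_cds_flags):
                excl.append(ExclusionRecord(a.unigene_id, b.unigene_id, "both_complete"))
                continue
            five, three = (a, b) if (a.start_aa, a.end_aa) <= (b.start_aa, b.end_aa) else (b, a)
            if five.start_aa == three.start_aa or three.end_aa <= five.end_aa:
                excl.append(ExclusionRecord(five.unigene_id, three.unigene_id, "containment"))
                continue
            if (five.covers_5prime and three.covers_5prime) or (
                five.covers_3prime and three.covers_3prime
            ):
                excl.append(ExclusionRecord(five.unigene_id, three.unigene_id, "same_end"))
                continue
            gap = gap_between(five, three)
            if gap is not None:
                pairs.append(
                    CandidatePair(
                        five.unigene_id, three.unigene_id, five.reference_id,
                        format_reference_location(five, three), gap, 0,
                    )
                )
                continue
            lo, hi = three.start_aa, min(five.end_aa, three.end_aa)
            if _overlap_subseq(five, lo, hi) is None or _overlap_subseq(three, lo, hi) is None:
                excl.append(
                    ExclusionRecord(
                        five.unigene_id, three.unigene_id, "containment",
                        detail="overlap maps outside a unigene",
                    )
                )
                continue
            if overlap_consistent(five, three, min_identity=min_identity):
                pairs.append(
                    CandidatePair(
                        five.unigene_id, three.unigene_id, five.reference_id,
                        format_reference_location(five, three), None,
                        overlap_aa_between(five, three),
                    )
                )
            else:
                excl.append(
                    ExclusionRecord(five.unigene_id, three.unigene_id, "mismatched_overlap")
                )
    if max_pairs_per_group is not None:
        # workload cap: keeps the first pairs in member-id order
        pairs = pairs[:max_pairs_per_group]
    return pairs, excl
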