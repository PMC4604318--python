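"""Merge a unigene pair with a bridging sequence; analyse ORF/CDS completeness.

The merge follows overlap-layout-consensus semantics at three-sequence
scale: the bridge (a sequenced PCR product spanning the gap) must align
suffix-to-prefix against the 5′ unigene and prefix-to-suffix against
the 3′ unigene, each flank meeting configurable overlap-length and
identity thresholds; the merged sequence is then stitched through the
bridge. Within a flank overlap, conflicts are resolved in favour of the
unigene base by default — unigenes derive from deep short-read
consensus whereas the bridge is typically a single Sanger read — which
concretely means the unigene sub-sequence is kept verbatim for the
overlap region (``prefer_bridge=True`` keeps the bridge instead).

The merged sequence is scanned in all six frames for open reading
frames; the longest ORF plus the family protein-length range decides
whether the result carries a complete CDS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

__all__ = [
    "OverlapAlignment",
    "MergeRefused",
    "AssemblyResult",
    "OrfReport",
    "overlap_align",
    "merge_with_bridge",
    "find_orfs",
    "longest_orf",
    "classify_cds",
]

DEFAULT_MIN_OVERLAP_NT = 40
DEFAULT_MIN_IDENTITY = 0.95

_MATCH, _MISMATCH, _GAP = 1, -1, -2

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


# ---------------------------------------------------------------------------
# Suffix-prefix overlap alignment

@dataclass(frozen=True)
class OverlapAlignment:
    """Best suffix(a)-prefix(b) alignment under +1/-1/-2 scoring.

    ``a_start``/``b_end`` are 0-based offsets: the overlap covers
    ``a[a_start:]`` and ``b[:b_end]``. ``columns`` counts aligned
    columns (including gap columns); ``identity`` is matches/columns.
    """

    a_start: int
    b_end: int
    score: int
    columns: int
    matches: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def passes(self, min_overlap: int, min_identity: float) -> bool:
        return self.columns >= min_overlap and self.identity >= min_identity


class MergeRefused(RuntimeError):
    """The bridge does not anchor acceptably in both unigenes."""


def overlap_align(a: str, b: str) -> OverlapAlignment:
    """Dynamic-programming overlap alignment of a suffix of ``a`` with a
    prefix of ``b`` (free end gaps on a's start and b's end).

    Match +1, mismatch -1, gap -2, linear. The DP rows are vectorised
    with a prefix-max trick: with linear gap costs, any run of
    horizontal moves originates at a cell last reached diagonally or
    vertically, so the row maximum over gap chains is a running maximum
    of (candidate + 2j) minus 2j.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    la, lb = len(a), len(b)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((la + 1, lb + 1), dtype=np.int32)
    j_idx = np.arange(lb + 1, dtype=np.int32)
    H[0] = -2 * j_idx
    two_j = 2 * j_idx
    for i in range(1, la + 1):
        prev = H[i - 1]
        sub = np.where(b_arr == a_arr[i - 1], _MATCH, _MISMATCH).astype(np.int32)
        M = np.empty(lb + 1, dtype=np.int32)
        M[0] = 0  # free leading gap in a
        np.maximum(prev[:-1] + sub, prev[1:] + _GAP, out=M[1:])
        H[i] = np.maximum.accumulate(M + two_j) - two_j
    last = H[la]
    best = int(last.max())
    # prefer the longest overlap among equal-scoring end points
    j = int(lb - np.argmax(last[::-1]))
    # traceback
    i, cols, matches = la, 0, 0
    while j > 0:
        h = int(H[i, j])
        if i > 0 and h == H[i - 1, j - 1] + (
            _MATCH if a[i - 1] == b[j - 1] else _MISMATCH
        ):
            cols += 1
            matches += a[i - 1] == b[j - 1]
            i -= 1
            j -= 1
        elif i > 0 and h == H[i - 1, j] + _GAP:
            cols += 1
            i -= 1
        elif h == H[i, j - 1] + _GAP:
            cols += 1
            j -= 1
        elif i > 0 and h == H[i - 1, j]:  # free column (i row boundary M[0]=0 path)
            i -= 1
        else:  # pragma: no cover - defensive
            raise AssertionError("traceback failed")
    return OverlapAlignment(a_start=i, b_end=int(lb - np.argmax(last[::-1])), score=best,
                            columns=cols, matches=matches)


# ---------------------------------------------------------------------------
# Three-sequence merge

@dataclass(frozen=True)
class OrfReport:
    """The longest open reading frame of a merged sequence.

    Coordinates are 1-based on the scanned strand (for negative frames,
    on the reverse complement). ``protein_length_aa`` excludes the stop
    codon. ``has_upstream_inframe_stop`` is the 5′-completeness signal:
    a stop codon in frame upstream of the ATG proves no longer protein
    can start further 5′.
    """

    start_nt: int
    end_nt: int
    frame: int
    protein_length_aa: int
    has_upstream_inframe_stop: bool
    has_terminal_stop: bool

    @property
    def completeness(self) -> str:
        if self.has_terminal_stop and self.has_upstream_inframe_stop:
            return "complete"
        if self.has_terminal_stop:
            return "partial_5prime"
        if self.has_upstream_inframe_stop:
            return "partial_3prime"
        return "internal"


@dataclass
class AssemblyResult:
    """A merged (5′ unigene + bridge + 3′ unigene) sequence with its report."""

    assembly_id: str
    five_prime_id: str
    three_prime_id: str
    five_prime_length_nt: int
    three_prime_length_nt: int
    bridge_length_nt: int
    assembled_seq: str
    annotation: str = ""
    orf: OrfReport | None = None
    complete_cds: bool | None = None

    @property
    def assembled_length_nt(self) -> int:
        return len(self.assembled_seq)


def merge_with_bridge(
    seq5: str,
    seq3: str,
    bridge: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP_NT,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    prefer_bridge: bool = False,
    assembly_id: str = "assembly",
    five_prime_id: str = "five_prime",
    three_prime_id: str = "three_prime",
    annotation: str = "",
) -> AssemblyResult:
    """Merge two unigenes through a bridging sequence of unknown strand.

    Both bridge orientations are tried; the one whose two flank
    alignments both pass the thresholds with the higher combined score
    wins. Raises :class:`MergeRefused` when no orientation anchors in
    both unigenes ("no second flank" when only one flank ever aligns).
    """
    attempts = []
    for oriented in (bridge, reverse_complement(bridge)):
        aln5 = overlap_align(seq5, oriented)
        aln3 = overlap_align(oriented, seq3)
        ok5 = aln5.passes(min_overlap, min_identity)
        ok3 = aln3.passes(min_overlap, min_identity)
        attempts.append((ok5 + ok3, aln5.score + aln3.score, oriented, aln5, aln3, ok5, ok3))
    attempts.sort(key=lambda t: (t[0], t[1]), reverse=True)
    n_ok, _, oriented, aln5, aln3, ok5, ok3 = attempts[0]
    if n_ok < 2:
        if n_ok == 1:
            missing = "3'" if ok5 else "5'"
            raise MergeRefused(
                f"no second flank: bridge anchors only in the "
                f"{'5' if ok5 else '3'}' unigene (best {missing} flank: "
                f"{aln3.columns if ok5 else aln5.columns} nt at "
                f"{(aln3 if ok5 else aln5).identity:.1%} identity)"
            )
        raise MergeRefused(
            f"bridge aligns to neither unigene (best flanks {aln5.columns} nt "
            f"at {aln5.identity:.1%} and {aln3.columns} nt at {aln3.identity:.1%})"
        )
    j1 = aln5.b_end        # bridge prefix consumed by the 5' flank
    p0 = aln3.a_start      # bridge offset where the 3' flank begins
    if prefer_bridge:
        assembled = seq5[: aln5.a_start] + oriented + seq3[aln3.b_end :]
    elif p0 >= j1:
        assembled = seq5 + oriented[j1:p0] + seq3
    else:
        # flank regions collide on the bridge: the unigenes themselves
        # overlap by j1 - p0 bridge bases
        trim = min(j1 - p0, len(seq3))
        assembled = seq5 + seq3[trim:]
    return AssemblyResult(
        assembly_id, five_prime_id, three_prime_id,
        len(seq5), len(seq3), len(bridge), assembled, annotation,
    )


# ---------------------------------------------------------------------------
# ORF analysis

_FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def find_orfs(seq: str) -> list[OrfReport]:
    """Scan all six frames for open reading frames.

    An ORF runs from the first ATG of a stop-delimited frame segment to
    the next in-frame stop codon, or to the sequence end (then
    ``has_terminal_stop`` is False). Returns the empty list when no
    frame contains an ATG.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    orfs: list[OrfReport] = []
    rc = reverse_complement(seq)
    for frame in _FRAME_ORDER:
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        codons = [s[k : k + 3] for k in range(off, len(s) - 2, 3)]
        seen_stop = False
        start_idx: int | None = None
        for idx, codon in enumerate(codons):
            if codon in STOP_CODONS:
                if start_idx is not None:
                    orfs.append(
                        OrfReport(
                            start_nt=off + 3 * start_idx + 1,
                            end_nt=off + 3 * (idx + 1),
                            frame=frame,
                            protein_length_aa=idx - start_idx,
                            has_upstream_inframe_stop=seen_stop,
                            has_terminal_stop=True,
                        )
                    )
                    start_idx = None
                seen_stop = True
            elif codon == START_CODON and start_idx is None:
                start_idx = idx
        if start_idx is not None:
            orfs.append(
                OrfReport(
                    start_nt=off + 3 * start_idx + 1,
                    end_nt=off + 3 * len(codons),
                    frame=frame,
                    protein_length_aa=len(codons) - start_idx,
                    has_upstream_inframe_stop=seen_stop,
                    has_terminal_stop=False,
                )
            )
    return orfs


def longest_orf(seq: str) -> OrfReport | None:
    """Longest ORF by protein length; ties broken by leftmost start,
    then by frame order +1, +2, +3, -1, -2, -3."""
    orfs = find_orfs(seq)
    if not orfs:
        return None
    frame_rank = {f: k for k, f in enumerate(_FRAME_ORDER)}
    return min(orfs, key=lambda o: (-o.protein_length_aa, o.start_nt, frame_rank[o.frame]))


def classify_cds(
    orf: OrfReport | None,
    family_range: tuple[int, int],
    length_tolerance_aa: int = 0,
) -> bool:
    """Is the ORF a complete CDS for its family?

    Requires a terminal stop codon, 5′ evidence (an upstream in-frame
    stop, or failing that an ORF that starts at least 1 nt into the
    sequence so a 5′ UTR exists), and a protein length inside the
    family's range, optionally widened by ``length_tolerance_aa``.
    """
    lo, hi = family_range
    if lo > hi:
        raise ValueError(f"invalid family range {lo}-{hi}")
    if orf is None:
        return False
    if not orf.has_terminal_stop:
        return False
    if not (orf.has_upstream_inframe_stop or orf.start_nt >= 2):
        return False
    return lo - length_tolerance_aa <= orf.protein_length_aa <= hi + length_tolerance_aa
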