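"""Bridging-primer design and product-size arithmetic.

For each candidate pair a forward primer is placed on the 5′ unigene
and a reverse primer on the 3′ unigene. Two sizes are reported:

* *designed* size — the product length on the hypothetical gapless
  template obtained by butting the two unigenes together (minus any
  reference-level overlap):
  ``(len5 - forward_start + 1) + reverse_end - 3*overlap_aa``;
* *estimated* size — the designed size inflated by the reference-level
  gap, ``designed + 3*gap_aa`` (identity for gapless pairs). This is
  the band size expected on a gel if the pair really shares a
  transcript, and is what the gap convention was defined for.

The placement constraint is that the product must cover at least
200 bp of *each* unigene, so a successful product unambiguously
anchors in both.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import reverse_complement
from Bio.SeqUtils import MeltingTemp

from .pair_selection import CandidatePair

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "InfeasiblePrimers",
    "designed_size",
    "estimated_size",
    "pick_primers",
]

MIN_PRODUCT_UNIGENE_OVERLAP_BP = 200


@dataclass(frozen=True)
class PrimerConstraints:
    """Tunable primer-quality rules; defaults are deliberately wide."""

    min_length: int = 17
    max_length: int = 24
    min_gc: float = 0.35
    max_gc: float = 0.65
    max_mononucleotide_run: int = 4
    tm_min_c: float = 50.0
    tm_max_c: float = 65.0
    tm_method: str = "nn"  # "nn": nearest-neighbor, 50 mM Na+, 250 nM primer; "wallace": 2(A+T)+4(G+C)
    min_product_overlap_bp: int = MIN_PRODUCT_UNIGENE_OVERLAP_BP


@dataclass(frozen=True)
class PrimerPair:
    """A chosen forward/reverse primer pair with product sizes.

    ``forward_start_nt`` is the 5′-most template base of the forward
    primer on the 5′ unigene; ``reverse_end_nt`` the 3′-most template
    base of the reverse primer site on the 3′ unigene (both 1-based on
    the coding strand). ``reverse_seq`` is the reverse complement of
    its template site.
    """

    forward_seq: str
    reverse_seq: str
    forward_start_nt: int
    reverse_end_nt: int
    tm_forward_c: float
    tm_reverse_c: float
    designed_size_bp: int
    estimated_size_bp: int


@dataclass(frozen=True)
class InfeasiblePrimers:
    """Returned when no primer pair satisfies the constraints."""

    violated_constraint: str


def designed_size(
    pair: CandidatePair,
    forward_start_nt: int,
    reverse_end_nt: int,
    len5: int,
    overlap_nt: int | None = None,
) -> int:
    """Product size on the gapless butted template.

    ``overlap_nt`` defaults to ``3 * pair.overlap_aa`` (0 for gapped
    pairs): the overlapping stretch is present once, not twice, in the
    butted template.
    """
    if not 1 <= forward_start_nt <= len5:
        raise ValueError("forward primer start outside the 5' unigene")
    if reverse_end_nt < 1:
        raise ValueError("reverse primer end outside the 3' unigene")
    if overlap_nt is None:
        overlap_nt = 3 * pair.overlap_aa
    size = (len5 - forward_start_nt + 1) + reverse_end_nt - overlap_nt
    if size <= 0:
        raise ValueError("non-positive product size: primers in wrong orientation")
    return size


def estimated_size(designed_size_bp: int, gap_aa: int | None) -> int:
    """Expected band size: ``designed + 3*gap`` (identity when gapless)."""
    if designed_size_bp <= 0:
        raise ValueError("designed size must be positive")
    if gap_aa is None:
        return designed_size_bp
    return designed_size_bp + 3 * gap_aa


# ---------------------------------------------------------------------------
# Primer search

def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def _tm(seq: str, method: str) -> float:
    if method == "wallace":
        return float(MeltingTemp.Tm_Wallace(seq))
    return float(MeltingTemp.Tm_NN(seq, Na=50, dnac1=250, dnac2=0))


def _window_ok(seq: str, c: PrimerConstraints) -> bool:
    if "N" in seq:
        return False
    if not c.min_gc <= _gc_fraction(seq) <= c.max_gc:
        return False
    return _max_run(seq) <= c.max_mononucleotide_run


def _candidate_sites(
    seq: str, starts: range, c: PrimerConstraints
) -> list[tuple[float, int, int]]:
    """(tm, start_1based, length) for every acceptable primer window."""
    out = []
    for start in starts:
        for length in range(c.min_length, c.max_length + 1):
            window = seq[start - 1 : start - 1 + length]
            if len(window) < length:
                continue
            if not _window_ok(window, c):
                continue
            tm = _tm(window, c.tm_method)
            if c.tm_min_c <= tm <= c.tm_max_c:
                out.append((tm, start, length))
    return out


def pick_primers(
    pair: CandidatePair,
    seq5: str,
    seq3: str,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair | InfeasiblePrimers:
    """Exhaustively search both unigenes for the best bridging primer pair.

    Feasible forward sites leave >= ``min_product_overlap_bp`` of the 5′
    unigene inside the product; feasible reverse sites likewise on the
    3′ unigene. Among all feasible combinations the pair minimising
    |Tm_f − Tm_r| is chosen, ties broken by larger product–unigene
    overlap, then by leftmost coordinates — fully deterministic.
    """
    c = constraints or PrimerConstraints()
    len5, len3 = len(seq5), len(seq3)
    if len5 < c.min_product_overlap_bp or len3 < c.min_product_overlap_bp:
        return InfeasiblePrimers(
            f"min {c.min_product_overlap_bp} bp product overlap"
        )
    # forward: product spans forward_start..len5, so start <= len5 - 199
    fwd_sites = _candidate_sites(
        seq5, range(1, len5 - c.min_product_overlap_bp + 2), c
    )
    # reverse: product spans 1..reverse_end on the 3' unigene, end >= 200
    rev_sites = []
    rev_start_min = max(1, c.min_product_overlap_bp - c.max_length + 1)
    for tm, start, length in _candidate_sites(seq3, range(rev_start_min, len3 + 1), c):
        end = start + length - 1
        if end >= c.min_product_overlap_bp and end <= len3:
            rev_sites.append((tm, end, length))
    if not fwd_sites or not rev_sites:
        return InfeasiblePrimers("no primer window satisfies Tm/GC/run constraints")

    fwd_sites.sort()
    rev_sites.sort()
    # two-pointer sweep over Tm-sorted candidate lists for min |dTm|
    best_key = None
    best: tuple | None = None
    j = 0
    for tm_f, f_start, f_len in fwd_sites:
        while j + 1 < len(rev_sites) and rev_sites[j + 1][0] <= tm_f:
            j += 1
        for k in (j, j + 1):
            if k >= len(rev_sites):
                continue
            tm_r, r_end, r_len = rev_sites[k]
            cov = (len5 - f_start + 1) + r_end
            key = (abs(tm_f - tm_r), -cov, f_start, r_end, f_len, r_len)
            if best_key is None or key < best_key:
                best_key = key
                best = (tm_f, f_start, f_len, tm_r, r_end, r_len)
    assert best is not None
    tm_f, f_start, f_len, tm_r, r_end, r_len = best
    d = designed_size(pair, f_start, r_end, len5)
    return PrimerPair(
        forward_seq=seq5[f_start - 1 : f_start - 1 + f_len],
        reverse_seq=reverse_complement(seq3[r_end - r_len : r_end]),
        forward_start_nt=f_start,
        reverse_end_nt=r_end,
        tm_forward_c=tm_f,
        tm_reverse_c=tm_r,
        designed_size_bp=d,
        estimated_size_bp=estimated_size(d, pair.gap_aa),
    )
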