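"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route from the
implementation it checks: naive agglomeration instead of scipy linkage,
an exhaustive suffix/prefix scan instead of the overlap DP, and
Biopython six-frame translation instead of the codon-walk ORF scanner.
"""

import itertools

import numpy as np
from Bio.Seq import Seq, reverse_complement

from unibridge.expression import profile_distance


def naive_upgma(profiles, metric="correlation"):
    """O(n^3) agglomeration: repeatedly merge the closest cluster pair
    under average linkage over the original distances, ties broken by
    the lexicographically least member id. Returns [(member_set,
    height), ...] in merge order."""
    ids = [p.unigene_id for p in profiles]
    d = {
        frozenset((a.unigene_id, b.unigene_id)): profile_distance(a, b, metric)
        for a, b in itertools.combinations(profiles, 2)
    }
    clusters = {frozenset([i]) for i in ids}
    merges = []
    while len(clusters) > 1:
        best = None
        for c1, c2 in itertools.combinations(sorted(clusters, key=sorted), 2):
            dist = sum(d[frozenset((x, y))] for x in c1 for y in c2) / (len(c1) * len(c2))
            key = (dist, min(min(c1), min(c2)))
            if best is None or key < best[0]:
                best = (key, c1, c2)
        (dist, _), c1, c2 = best
        clusters -= {c1, c2}
        clusters.add(c1 | c2)
        merges.append((c1 | c2, dist))
    return merges


def brute_force_overlap(a: str, b: str):
    """Exhaustive gapless suffix/prefix scan with +1/-1 per column.

    Returns (best_score, best_overlap_length); (0, 0) when no positive-
    scoring overlap exists. A valid oracle for the DP whenever the
    optimal alignment is substitution-only."""
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    best_score, best_k = 0, 0
    for k in range(1, min(len(a), len(b)) + 1):
        eq = int((a_arr[-k:] == b_arr[:k]).sum())
        score = 2 * eq - k
        if score > best_score:
            best_score, best_k = score, k
    return best_score, best_k


def brute_force_longest_orf(seq: str):
    """Longest ORF protein length (aa) via Biopython translation of all
    six frames; None when no frame contains a start codon."""
    best = None
    for s in (seq, reverse_complement(seq)):
        for off in range(3):
            trimmed = s[off : len(s) - (len(s) - off) % 3]
            if len(trimmed) < 3:
                continue
            prot = str(Seq(trimmed).translate())
            for segment in prot.split("*"):
                m = segment.find("M")
                if m != -1:
                    aa = len(segment) - m
                    if best is None or aa > best:
                        best = aa
    return best
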