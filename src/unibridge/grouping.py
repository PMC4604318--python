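"""Hierarchical clustering of expression profiles into small candidate groups.

Unigenes of one annotation family are clustered by their expression
pattern across samples; the tree is then cut into *groups* of two to
five members — the unit within which pairwise position analysis is
done. The grouping rule formalises box-drawing on a clustered heatmap:
a group is a maximal subtree whose leaf count lies in [min_size,
max_size]. Families are always clustered separately; cross-family
pairs are never formed.

Determinism: profiles are sorted lexicographically by unigene id before
clustering, so the output is invariant to input order; on equal merge
distances the linkage's internal order applied to the sorted ids breaks
ties reproducibly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionProfile, profile_distance

__all__ = ["Dendrogram", "ExpressionGroup", "cluster_family", "extract_groups"]


@dataclass
class Dendrogram:
    """Binary merge tree over unigene ids with non-negative merge heights.

    ``linkage`` is a scipy linkage matrix over ``leaf_ids`` (which are
    sorted lexicographically). ``merges`` lists, for each merge in
    order, the frozenset of leaf ids of the merged cluster and its
    height — convenient for oracle comparison and group extraction.
    """

    leaf_ids: list[str]
    linkage: np.ndarray
    family: str = ""

    @property
    def merges(self) -> list[tuple[frozenset, float]]:
        n = len(self.leaf_ids)
        clusters: dict[int, frozenset] = {
            i: frozenset([self.leaf_ids[i]]) for i in range(n)
        }
        out = []
        for k, (i, j, h, _) in enumerate(self.linkage):
            merged = clusters[int(i)] | clusters[int(j)]
            clusters[n + k] = merged
            out.append((merged, float(h)))
        return out


@dataclass
class ExpressionGroup:
    """2–5 unigenes of one family with a shared expression pattern."""

    member_ids: list[str]
    family: str
    max_height: float

    def __post_init__(self) -> None:
        self.member_ids = sorted(self.member_ids)


def cluster_family(
    profiles: Sequence[ExpressionProfile],
    metric: str = "correlation",
    linkage: str = "average",
    family: str = "",
) -> Dendrogram | None:
    """Agglomeratively cluster one family's expression profiles.

    Returns ``None`` with a warning when fewer than two profiles are
    given (a single unigene cannot be grouped). Average linkage (UPGMA)
    on the configured profile distance by default.
    """
    if len(profiles) < 2:
        warnings.warn(
            f"family {family or '<unnamed>'}: need >= 2 profiles to cluster, "
            f"got {len(profiles)}",
            stacklevel=2,
        )
        return None
    ordered = sorted(profiles, key=lambda p: p.unigene_id)
    ids = [p.unigene_id for p in ordered]
    n = len(ordered)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = profile_distance(ordered[i], ordered[j], metric=metric)
            dm[i, j] = dm[j, i] = d
    Z = hierarchy.linkage(squareform(dm, checks=False), method=linkage)
    return Dendrogram(ids, Z, family=family)


def extract_groups(
    dendrogram: Dendrogram | None,
    min_size: int = 2,
    max_size: int = 5,
    max_height: float | None = None,
) -> list[ExpressionGroup]:
    """Cut a dendrogram into maximal subtrees with 2–5 leaves.

    Walking down from the root, a node becomes a group as soon as its
    leaf count falls within [min_size, max_size] (and, if
    ``max_height`` is given, its merge height does not exceed it);
    descent stops there, so groups are maximal and disjoint. Leaves in
    no qualifying subtree stay ungrouped.
    """
    if dendrogram is None:
        return []
    Z = dendrogram.linkage
    ids = dendrogram.leaf_ids
    n = len(ids)

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        i, j = int(Z[node - n][0]), int(Z[node - n][1])
        return leaves(i) + leaves(j)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n][2])

    groups: list[ExpressionGroup] = []

    def walk(node: int) -> None:
        k = 1 if node < n else int(Z[node - n][3])
        if min_size <= k <= max_size and (max_height is None or height(node) <= max_height):
            groups.append(
                ExpressionGroup(
                    [ids[i] for i in leaves(node)], dendrogram.family, height(node)
                )
            )
            return
        if node < n:
            return  # singleton below min_size: ungrouped
        walk(int(Z[node - n][0]))
        walk(int(Z[node - n][1]))

    walk(2 * n - 2)
    groups.sort(key=lambda g: g.member_ids)
    return groups
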