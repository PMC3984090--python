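"""Identity distance, UPGMA tree construction and haplogroup partitioning.

The genetic distance between two samples over a region is the proportion
of mismatched symbols among the SNP positions where both samples have
data; positions where either symbol is missing (``-`` or ``N``) are
excluded.  No evolutionary correction (Kimura, gap penalties) is applied:
the mismatch proportion itself is the distance.

Trees are built with textbook UPGMA (unweighted pair group method with
arithmetic mean): repeatedly merge the pair of clusters with minimal
average inter-cluster distance, placing the merge node at half that
distance, with cluster-cluster distances maintained as size-weighted
averages over all member pairs.  Ties and child order are resolved
deterministically so that identical inputs always give identical trees.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .core import (
    DataError,
    DistanceMatrix,
    HaplogroupPartition,
    HaploTree,
    Region,
    SNPMatrix,
    TreeNode,
    slice_region,
)

__all__ = [
    "ZeroOverlapWarning",
    "pairwise_distance",
    "distance_matrix",
    "upgma",
    "partition_haplogroups",
]


class ZeroOverlapWarning(UserWarning):
    """Two samples share no informative position; distance set to 1.0."""


_MISSING = np.array(["N", "-"], dtype="<U1")


def pairwise_distance(a: Sequence[str], b: Sequence[str]) -> tuple[float, int]:
    """Mismatch-proportion distance between two symbol columns.

    Positions where either symbol is missing are excluded.  Returns
    ``(d, compared)`` where ``compared`` is the number of retained
    positions.  A pair with zero informative overlap gets ``d = 1.0``
    (conservative maximal separation) and a :class:`ZeroOverlapWarning`.
    """
    aa = np.asarray(a, dtype="<U1")
    bb = np.asarray(b, dtype="<U1")
    if aa.shape != bb.shape:
        raise DataError(
            f"column length mismatch: {aa.shape} vs {bb.shape}"
        )
    keep = ~(np.isin(aa, _MISSING) | np.isin(bb, _MISSING))
    compared = int(keep.sum())
    if compared == 0:
        warnings.warn(
            "no informative positions shared by the pair; "
            "distance set to 1.0",
            ZeroOverlapWarning,
            stacklevel=2,
        )
        return 1.0, 0
    mismatches = int((aa[keep] != bb[keep]).sum())
    return mismatches / compared, compared


def distance_matrix(
    m: SNPMatrix, region: Optional[Region] = None
) -> DistanceMatrix:
    """All-pairs identity distances over a matrix (optionally sliced).

    Requires at least two samples.  The result is symmetric with a zero
    diagonal; ``compared[i, i]`` counts sample *i*'s non-missing cells.
    """
    if region is not None:
        m = slice_region(m, region)
    n = m.n_samples
    if n < 2:
        raise DataError("distance matrix requires at least 2 samples")
    informative = ~np.isin(m.calls, _MISSING)  # (pos, sample)
    d = np.zeros((n, n), dtype=float)
    compared = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(compared, informative.sum(axis=0))
    zero_overlap_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            keep = informative[:, i] & informative[:, j]
            c = int(keep.sum())
            if c == 0:
                dij = 1.0
                zero_overlap_pairs.append((m.samples[i], m.samples[j]))
            else:
                dij = float((m.calls[keep, i] != m.calls[keep, j]).sum()) / c
            d[i, j] = d[j, i] = dij
            compared[i, j] = compared[j, i] = c
    if zero_overlap_pairs:
        warnings.warn(
            f"{len(zero_overlap_pairs)} sample pair(s) share no informative "
            f"positions (first: {zero_overlap_pairs[0]}); their distance "
            "was set to 1.0",
            ZeroOverlapWarning,
            stacklevel=2,
        )
    return DistanceMatrix(samples=m.samples, d=d, compared=compared)


def upgma(dm: DistanceMatrix) -> HaploTree:
    """UPGMA tree from a distance matrix.

    Each merge joins the two clusters with minimal average distance at a
    node of height ``distance / 2``; the distance from the merged cluster
    to any other is the size-weighted average of its parts.  Determinism:

    * among tied minimal pairs, the pair whose (smaller, larger) signature
      of smallest original sample indices is lexicographically least is
      merged first;
    * within a merge node, the child containing the lexicographically
      smallest leaf name comes first.
    """
    n = dm.n_samples
    if n < 2:
        raise DataError("UPGMA requires at least 2 samples")
    if np.isnan(dm.d).any():
        raise DataError("distance matrix contains NaN")

    # Active clusters: id -> (node, size, signature = min original index).
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, name=dm.samples[i]) for i in range(n)
    }
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    sigs: dict[int, int] = {i: i for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(dm.d[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_id = n

    while len(nodes) > 1:
        # Minimal-distance pair with deterministic tie-break.
        best_key = min(
            dist,
            key=lambda k: (
                dist[k],
                tuple(sorted(sigs[c] for c in k)),
            ),
        )
        i, j = sorted(best_key, key=lambda c: sigs[c])
        d_ij = dist.pop(best_key)
        child_a, child_b = nodes.pop(i), nodes.pop(j)
        if min(child_b.leaf_names()) < min(child_a.leaf_names()):
            child_a, child_b = child_b, child_a
        merged = TreeNode(height=d_ij / 2.0, children=(child_a, child_b))
        size_i, size_j = sizes.pop(i), sizes.pop(j)
        sig = min(sigs.pop(i), sigs.pop(j))
        for k in list(nodes):
            d_ik = dist.pop(frozenset((i, k)))
            d_jk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                size_i * d_ik + size_j * d_jk
            ) / (size_i + size_j)
        nodes[next_id] = merged
        sizes[next_id] = size_i + size_j
        sigs[next_id] = sig
        next_id += 1

    (root,) = nodes.values()
    return HaploTree(root=root, samples=dm.samples)


def partition_haplogroups(
    t: HaploTree, reference: str, tier: int = 1
) -> HaplogroupPartition:
    """Cut the tree at a branching tier into haplogroups.

    Groups are the leaf sets of the maximal subtrees rooted at depth
    ``tier`` (the root has depth 0); a leaf shallower than ``tier`` forms
    its own group.  Tier 1 therefore yields the two root-child clades,
    one of which contains the reference sample (the reference-like
    haplogroup).  Increasing the tier refines the partition.
    """
    if tier < 1:
        raise DataError("tier must be >= 1")
    if not t.contains(reference):
        raise DataError(f"reference sample {reference!r} is not in the tree")

    groups: list[frozenset[str]] = []

    def walk(node: TreeNode, depth: int) -> None:
        if depth == tier or node.is_leaf:
            groups.append(frozenset(node.leaf_names()))
            return
        for child in node.children:
            walk(child, depth + 1)

    walk(t.root, 0)
    ref_index = next(
        idx for idx, g in enumerate(groups) if reference in g
    )
    return HaplogroupPartition(
        tier=tier, groups=tuple(groups), reference_group_index=ref_index
    )
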