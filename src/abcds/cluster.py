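"""Agglomerative hierarchical clustering of (ADL, BPSD, CF) score vectors.

Patients within one CDR stratum are clustered on their raw three-domain
scores (no standardization) with Euclidean distances.  The merge sequence
is produced by the Lance-Williams recurrence for the three supported
linkages:

* ``ward``     -- minimal increase in within-cluster sum of squares.  The
  recurrence runs on squared distances and reported heights are the square
  roots, so heights live on the distance scale (the modern, documented-
  correct Ward criterion).  ``ward_flavor="legacy"`` instead applies the
  Ward coefficients to unsquared distances, matching the historical
  variant some environments shipped under the same name.
* ``complete`` -- maximum inter-cluster pair distance.
* ``average``  -- size-weighted mean inter-cluster pair distance (UPGMA).

All three linkages are inversion-free, so merge heights are non-decreasing
and a dendrogram cut is well defined at every k.

Ties are broken deterministically: among pairs attaining the minimal
distance, the pair with the lexicographically smallest (older node id,
newer node id) is merged.  Node ids number leaves 0..n-1 in input order
and internal nodes n, n+1, ... in creation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "pairwise_distances",
    "linkage",
    "cut",
    "select_k_largest_gap",
    "LINKAGE_METHODS",
]

LINKAGE_METHODS = ("ward", "complete", "average")


@dataclass(frozen=True)
class Dendrogram:
    """Full merge history of one agglomeration run.

    ``merges[i] = (left, right, height, size)`` creates node ``n_leaves + i``
    by joining the clusters rooted at nodes ``left`` and ``right`` (left <
    right) at the given height; ``size`` is the member count of the new
    cluster.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float, int], ...]
    leaf_ids: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges], dtype=float)


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering obtained by cutting a dendrogram at k clusters."""

    k: int
    labels: tuple[int, ...]  # per-leaf cluster index, 1..k
    stratum: float | None = None


def pairwise_distances(points: Sequence[Sequence[float]]) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def linkage(
    points: Sequence[Sequence[float]],
    method: str = "ward",
    leaf_ids: Sequence[str] | None = None,
    ward_flavor: str = "distance",
) -> Dendrogram:
    """Agglomerate points into a full dendrogram.

    Parameters
    ----------
    points
        n x d coordinate array (domain-score vectors).
    method
        One of ``ward``, ``complete``, ``average``.
    leaf_ids
        Optional per-point labels (e.g. patient ids), kept in input order.
    ward_flavor
        ``"distance"`` (default; squared-distance recurrence, square-rooted
        heights) or ``"legacy"`` (recurrence applied to raw distances).
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}")
    if ward_flavor not in ("distance", "legacy"):
        raise ValueError(f"unknown ward_flavor {ward_flavor!r}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    ids = tuple(str(i) for i in range(n)) if leaf_ids is None else tuple(map(str, leaf_ids))
    if len(ids) != n:
        raise ValueError("leaf_ids length mismatch")
    if n == 1:
        return Dendrogram(n_leaves=1, merges=(), leaf_ids=ids)

    squared = method == "ward" and ward_flavor == "distance"
    dist = pairwise_distances(pts)
    work = dist**2 if squared else dist.copy()
    np.fill_diagonal(work, np.inf)

    node_ids = list(range(n))  # ascending by creation order throughout
    sizes = [1] * n
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        m = work.shape[0]
        # Row-major argmin over the upper triangle: with node_ids ascending
        # this realizes the (older id, newer id) lexicographic tie-break.
        tri = np.where(np.triu(np.ones((m, m), dtype=bool), k=1), work, np.inf)
        flat = int(np.argmin(tri))
        i, j = divmod(flat, m)
        dij = work[i, j]
        height = float(np.sqrt(dij)) if squared else float(dij)
        ni, nj, nk = sizes[i], sizes[j], np.array(
            [sizes[t] for t in range(m) if t != i and t != j], dtype=float
        )
        keep = [t for t in range(m) if t != i and t != j]
        di, dj = work[i, keep], work[j, keep]
        if method == "ward":
            new = ((ni + nk) * di + (nj + nk) * dj - nk * dij) / (ni + nj + nk)
        elif method == "complete":
            new = np.maximum(di, dj)
        else:  # average
            new = (ni * di + nj * dj) / (ni + nj)

        merges.append((node_ids[i], node_ids[j], height, ni + nj))
        # rebuild working matrix with the merged node appended last
        sub = work[np.ix_(keep, keep)]
        m2 = len(keep) + 1
        nxt = np.full((m2, m2), np.inf)
        nxt[:-1, :-1] = sub
        nxt[-1, :-1] = new
        nxt[:-1, -1] = new
        work = nxt
        node_ids = [node_ids[t] for t in keep] + [n + step]
        sizes = [sizes[t] for t in keep] + [ni + nj]

    heights = [m[2] for m in merges]
    if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
        raise AssertionError("height inversion: linkage produced decreasing merge heights")
    return Dendrogram(n_leaves=n, merges=tuple(merges), leaf_ids=ids)


def cut(dend: Dendrogram, k: int, stratum: float | None = None) -> ClusterAssignment:
    """Cut a dendrogram into k flat clusters by undoing the last k-1 merges.

    Labels are renumbered 1..k by order of first leaf appearance, so the
    leftmost patient of each cluster determines its index.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx in range(n - k):
        left, right, _, _ = dend.merges[idx]
        new = n + idx
        parent[find(left)] = new
        parent[find(right)] = new

    labels: list[int] = []
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels.append(seen[root])
    return ClusterAssignment(k=k, labels=tuple(labels), stratum=stratum)


def select_k_largest_gap(dend: Dendrogram, k_min: int = 2, k_max: int | None = None) -> int:
    """Choose the cluster count at the largest merge-height gap.

    With non-decreasing merge heights h_1 <= ... <= h_{n-1}, the cut into k
    clusters sits between merges n-k and n-k+1; the selected k in
    [k_min, k_max] maximizes h_{n-k+1} - h_{n-k}, i.e. the height jump one
    would cross by merging further down to k-1 clusters.  Ties go to the
    smallest k.
    """
    n = dend.n_leaves
    if k_max is None:
        k_max = min(n - 1, 8)
    if n < k_min + 1:
        raise ValueError(f"need at least k_min + 1 = {k_min + 1} leaves, got {n}")
    if not (2 <= k_min <= k_max < n):
        raise ValueError(f"require 2 <= k_min <= k_max < n_leaves; got {k_min}, {k_max}, n={n}")
    h = dend.heights
    best_k, best_gap = k_min, -np.inf
    for k in range(k_min, k_max + 1):  # ascending, so ties keep the smallest k
        gap = h[n - k] - h[n - k - 1]
        if gap > best_gap + 1e-12:
            best_k, best_gap = k, gap
    return best_k
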