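"""Agglomerative hierarchical clustering of structure ensembles and
generic distance matrices, with medoid extraction.

The agglomerator is a deterministic Lance-Williams implementation:
among equal-distance merge candidates the lexicographically smallest
cluster-id pair wins, so results are reproducible across runs and input
partitionings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterReport",
    "agglomerate",
    "cut",
    "cluster_ensemble",
    "read_distance_matrix",
    "write_distance_matrix",
]

LINKAGES = ("single", "complete", "average")


@dataclass
class DistanceMatrix:
    """Symmetric all-pairs dissimilarity with zero diagonal."""

    values: np.ndarray
    labels: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.all(np.abs(np.diag(v)) == 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if not self.labels:
            self.labels = [str(i) for i in range(v.shape[0])]
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, ij: Tuple[int, int]) -> float:
        return float(self.values[ij])


@dataclass
class Dendrogram:
    """Merge history: leaves are clusters 0..n-1, merge k creates n+k."""

    merges: List[Tuple[int, int, float]]
    n_leaves: int
    source: Optional[DistanceMatrix] = None

    def leaves_of(self, cluster_id: int) -> List[int]:
        if cluster_id < self.n_leaves:
            return [cluster_id]
        a, b, _ = self.merges[cluster_id - self.n_leaves]
        return self.leaves_of(a) + self.leaves_of(b)

    def to_newick(self) -> str:
        """Ultrametric Newick: leaf-to-node path length = height / 2."""
        heights = {i: 0.0 for i in range(self.n_leaves)}

        def label(i: int) -> str:
            if self.source is not None:
                return self.source.labels[i]
            return str(i)

        def render(cluster_id: int) -> str:
            if cluster_id < self.n_leaves:
                return label(cluster_id)
            a, b, h = self.merges[cluster_id - self.n_leaves]
            heights[cluster_id] = h
            la = render(a)
            lb = render(b)
            ba = max(h / 2.0 - heights[a] / 2.0, 0.0)
            bb = max(h / 2.0 - heights[b] / 2.0, 0.0)
            return f"({la}:{ba:.6g},{lb}:{bb:.6g})"

        root = self.n_leaves + len(self.merges) - 1
        return render(root) + ";"


@dataclass
class ClusterReport:
    assignments: List[int]  # leaf index -> cluster id (0-based, dense)
    medoids: Dict[int, int]  # cluster id -> leaf index
    sizes: Dict[int, int]
    labels: List[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, cluster_id: int) -> List[int]:
        return [i for i, c in enumerate(self.assignments) if c == cluster_id]

    def to_tsv(self) -> str:
        lines = ["#item\tlabel\tcluster\tis_medoid"]
        medoid_set = set(self.medoids.values())
        for i, c in enumerate(self.assignments):
            label = self.labels[i] if self.labels else str(i)
            lines.append(f"{i}\t{label}\t{c}\t{int(i in medoid_set)}")
        return "\n".join(lines) + "\n"


def _linkage_distance(linkage: str, d_ak: float, d_bk: float, na: int, nb: int) -> float:
    if linkage == "single":
        return min(d_ak, d_bk)
    if linkage == "complete":
        return max(d_ak, d_bk)
    # average (UPGMA)
    return (na * d_ak + nb * d_bk) / (na + nb)


def agglomerate(d: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Hierarchical agglomeration under single/complete/average linkage."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = d.n
    if n < 2:
        raise ValueError("at least 2 items are required")
    # active cluster id -> (size, {other id -> distance})
    dist: Dict[Tuple[int, int], float] = {}
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[(i, j)]

    merges: List[Tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i_pos in range(len(active)):
            for j_pos in range(i_pos + 1, len(active)):
                a, b = active[i_pos], active[j_pos]
                key = (min(a, b), max(a, b))
                cand = (dist[key], key[0], key[1])
                if best is None or cand < best:
                    best = cand
        h, a, b = best
        merges.append((a, b, h))
        new_sizes = sizes[a] + sizes[b]
        active = [c for c in active if c not in (a, b)]
        for c in active:
            d_ak = dist[(min(a, c), max(a, c))]
            d_bk = dist[(min(b, c), max(b, c))]
            dist[(min(next_id, c), max(next_id, c))] = _linkage_distance(
                linkage, d_ak, d_bk, sizes[a], sizes[b]
            )
        sizes[next_id] = new_sizes
        active.append(next_id)
        next_id += 1
    return Dendrogram(merges=merges, n_leaves=n, source=d)


def cut(
    dendrogram: Dendrogram,
    k: Optional[int] = None,
    height: Optional[float] = None,
) -> ClusterReport:
    """Partition the leaves by undoing the last ``k - 1`` merges, or by
    applying only merges at or below ``height``.  Exactly one of ``k`` and
    ``height`` must be given.  Medoid = member minimizing summed
    intra-cluster distance (requires the dendrogram's source matrix)."""
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k and height")
    n = dendrogram.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        applied = dendrogram.merges[: n - k]
    else:
        if height < 0:
            raise ValueError("height must be non-negative")
        # heights are non-decreasing for the supported linkages, so the
        # merges at or below the threshold form a prefix
        n_applied = 0
        for m in dendrogram.merges:
            if m[2] <= height:
                n_applied += 1
            else:
                break
        applied = dendrogram.merges[:n_applied]

    parent = {}

    def find(x: int) -> int:
        while x in parent:
            x = parent[x]
        return x

    # map each applied merge's children to the new cluster node
    for step, (a, b, _) in enumerate(dendrogram.merges[: len(applied)]):
        new = n + step
        parent[a] = new
        parent[b] = new

    roots: Dict[int, int] = {}
    assignments: List[int] = []
    for leaf in range(n):
        root = find(leaf)
        if root not in roots:
            roots[root] = len(roots)
        assignments.append(roots[root])

    sizes: Dict[int, int] = {}
    for c in assignments:
        sizes[c] = sizes.get(c, 0) + 1

    medoids: Dict[int, int] = {}
    d = dendrogram.source
    if d is not None:
        for cid in sizes:
            members = [i for i, c in enumerate(assignments) if c == cid]
            sums = [sum(d[(i, j)] for j in members) for i in members]
            medoids[cid] = members[int(np.argmin(sums))]
    labels = d.labels if d is not None else [str(i) for i in range(n)]
    return ClusterReport(
        assignments=assignments, medoids=medoids, sizes=sizes, labels=list(labels)
    )


def cluster_ensemble(structures, linkage: str = "average", k: int = 2) -> ClusterReport:
    """crmsd matrix -> agglomerate -> cut; medoid structures addressable
    via the report's leaf indices."""
    from .calc_structural import pairwise_crmsd_matrix

    d = pairwise_crmsd_matrix(structures)
    dendro = agglomerate(d, linkage=linkage)
    return cut(dendro, k=k)


def write_distance_matrix(d: DistanceMatrix, path: Union[str, Path]) -> None:
    lines = [" ".join(f"{v:.6f}" for v in row) for row in d.values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_matrix(path: Union[str, Path]) -> DistanceMatrix:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"empty distance matrix file: {path}")
    return DistanceMatrix(values=np.array(rows, dtype=float))
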