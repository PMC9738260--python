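"""Minkowski distances and Ward agglomeration of antigen feature vectors.

Each bead's standardized column — its response profile across patients —
is treated as a feature vector for that antigen, and antigenic distances
between beads are order-p Minkowski distances of those vectors.  Beads are
then agglomerated bottom-up with Ward's minimum-variance method, giving a
dendrogram whose main branches are the antibody-response groups.

The Ward variant applies the Lance-Williams update with Ward coefficients
to *squared* dissimilarities and reports merge heights on the original
(unsquared) scale — the behaviour commonly labelled "ward.D2".  A "D"
variant (update applied to raw dissimilarities) is available for
sensitivity checks.  Tie-breaking is deterministic: among equal-minimum
pairs, the pair whose (smaller node id, larger node id) is lexicographically
least merges first, so runs are reproducible across platforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .panel import StandardizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ClusteringError",
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "antigen_features",
    "minkowski_distances",
    "ward_linkage",
    "cut_tree",
    "to_newick",
]


class ClusteringError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # square symmetric, zero diagonal
    p: float  # Minkowski order

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ClusteringError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ClusteringError("distance matrix is not symmetric")
        if (d < 0).any():
            raise ClusteringError("distance matrix has negative entries")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ClusteringError("distance matrix diagonal is not zero")
        self.d = d


@dataclass
class Dendrogram:
    """Binary merge tree.

    Leaves are numbered ``0..n-1`` in label order; the node created by merge
    ``i`` (0-based) is ``n + i``.  Each merge records its two children, the
    merge height, and the size of the new cluster.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_heights(self) -> dict[int, float]:
        h = {i: 0.0 for i in range(self.n_leaves)}
        for i, (_, _, height, _) in enumerate(self.merges):
            h[self.n_leaves + i] = height
        return h


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]  # label -> group id (1-based)
    k: int


def antigen_features(m: StandardizedMatrix) -> pd.DataFrame:
    """Transpose the standardized matrix: rows become per-antigen vectors."""
    return m.data.T


def minkowski_distances(features: pd.DataFrame, p: float = 2.0) -> DistanceMatrix:
    """All-pairs Minkowski distances between feature-vector rows."""
    if p < 1:
        raise ClusteringError(f"Minkowski order must be >= 1, got {p}")
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ClusteringError("feature matrix contains non-finite values")
    d = squareform(pdist(X, metric="minkowski", p=p))
    return DistanceMatrix(labels=list(features.index), d=d, p=float(p))


def ward_linkage(dm: DistanceMatrix, variant: str = "D2") -> Dendrogram:
    """Agglomerate with Ward's method via the Lance-Williams recursion.

    ``variant="D2"`` (default) squares the dissimilarities before the
    recursion and reports unsquared heights; ``variant="D"`` runs the
    recursion on the raw dissimilarities.
    """
    if variant not in {"D2", "D"}:
        raise ClusteringError(f"Ward variant must be 'D2' or 'D', got {variant!r}")
    n = len(dm.labels)
    if n < 2:
        raise ClusteringError("need at least 2 items to cluster")
    if variant == "D2" and dm.p != 2.0:
        log.info(
            "Ward update applied to non-Euclidean (p=%g) dissimilarities; "
            "treated as a heuristic",
            dm.p,
        )

    # working dissimilarity between active nodes, keyed (a, b) with a < b
    work: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            v = dm.d[i, j]
            work[(i, j)] = v * v if variant == "D2" else v
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        best_pair, best_val = None, math.inf
        for pair in sorted(work):  # lexicographic scan => deterministic ties
            if work[pair] < best_val:
                best_val = work[pair]
                best_pair = pair
        assert best_pair is not None
        a, b = best_pair
        height = math.sqrt(best_val) if variant == "D2" else best_val
        new = n + step
        sa, sb = size[a], size[b]
        merges.append((a, b, height, sa + sb))
        active.discard(a)
        active.discard(b)
        for k in active:
            sk = size[k]
            dak = work[(min(a, k), max(a, k))]
            dbk = work[(min(b, k), max(b, k))]
            updated = ((sa + sk) * dak + (sb + sk) * dbk - sk * best_val) / (
                sa + sb + sk
            )
            work[(k, new)] = updated
        work = {
            (x, y): v for (x, y), v in work.items() if x not in (a, b) and y not in (a, b)
        }
        size[new] = sa + sb
        active.add(new)

    return Dendrogram(merges=merges, labels=list(dm.labels))


def cut_tree(t: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into k groups by removing the k-1 highest merges.

    Groups are numbered 1..k by the lexicographically smallest member label,
    so the numbering is deterministic.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ClusteringError(f"k must be in 1..{n}, got {k}")
    parent = list(range(n + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _, _) in enumerate(t.merges[: n - k]):
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node

    clusters: dict[int, list[str]] = {}
    for leaf in range(n):
        clusters.setdefault(find(leaf), []).append(t.labels[leaf])
    groups = sorted(clusters.values(), key=lambda members: min(members))
    assignment = {
        label: gid for gid, members in enumerate(groups, start=1) for label in members
    }
    return ClusterAssignment(assignment=assignment, k=k)


def _newick_label(label: str) -> str:
    # labels with Newick metacharacters (bead ids contain ':') must be quoted
    if any(c in label for c in "():;,'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t: Dendrogram) -> str:
    """Serialize as rooted binary Newick with ultrametric branch lengths.

    Each child's branch length is its parent's merge height minus its own
    height (leaves sit at height 0), so leaf depths equal the root height.
    Children are ordered by the lexicographically smallest leaf label in
    their subtree; labels containing Newick metacharacters are single-quoted.
    """
    n = t.n_leaves
    heights = t.node_heights()
    rendered: dict[int, str] = {}
    min_label: dict[int, str] = {}
    for leaf in range(n):
        rendered[leaf] = _newick_label(t.labels[leaf])
        min_label[leaf] = t.labels[leaf]
    for i, (a, b, height, _) in enumerate(t.merges):
        node = n + i
        if min_label[b] < min_label[a]:
            a, b = b, a
        la = height - heights[a]
        lb = height - heights[b]
        rendered[node] = f"({rendered[a]}:{la!r},{rendered[b]}:{lb!r})"
        min_label[node] = min(min_label[a], min_label[b])
    root = n + len(t.merges) - 1
    return rendered[root] + ";"


def distances_frame(dm: DistanceMatrix) -> pd.DataFrame:
    """Square distance matrix as a labelled DataFrame (for CSV export)."""
    return pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels)
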