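"""Distance metrics, UPGMA hierarchical clustering, tree cutting, Newick export.

Two metrics drive the two stages: correlation distance 1 - r (Pearson) on
real-valued interaction profiles, with range [0, 2], and Tanimoto distance
1 - |X&Y|/|X|Y| on binary atom-pair descriptors, with range [0, 1]. Trees
are built by UPGMA (average linkage): the distance between two clusters is
the unweighted mean of all cross-pair leaf distances, and each merge is
recorded at that height. UPGMA is implemented here rather than delegated
so that tie-breaking is fully specified and platform-independent; tests
cross-check it against SciPy's average linkage.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation of two equal-length real vectors, in [0, 2].

    Zero-variance convention: two identical constant vectors are at
    distance 0; any other pairing with a constant vector is at distance 1
    (correlation taken as 0), keeping the metric total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 components")
    if np.array_equal(x, y) and np.ptp(x) > 0:
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0 if np.array_equal(x, y) else 1.0
    r = float(np.clip(np.dot(xc, yc) / (nx * ny), -1.0, 1.0))
    return 1.0 - r


def tanimoto_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - |X&Y|/|X|Y| on binary vectors, in [0, 1]; both-empty -> 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if not (np.all((x == 0) | (x == 1)) and np.all((y == 0) | (y == 1))):
        raise ValueError("tanimoto distance requires binary vectors")
    xb = x.astype(bool)
    yb = y.astype(bool)
    union = int(np.sum(xb | yb))
    if union == 0:
        return 0.0
    inter = int(np.sum(xb & yb))
    return 1.0 - inter / union


METRICS = {"correlation": correlation_distance, "tanimoto": tanimoto_distance}


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if np.any(self.d < 0) or not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric and non-negative")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    def __len__(self) -> int:
        return len(self.ids)


def pairwise_distances(
    rows: np.ndarray, metric: str, ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Apply a named metric to every unordered row pair."""
    rows = np.asarray(rows)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need a 2-d array with at least 2 rows")
    try:
        fn = METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    n = rows.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(rows[i], rows[j])
    labels = list(ids) if ids is not None else [str(i) for i in range(n)]
    return DistanceMatrix(ids=labels, d=d)


@dataclass
class ClusterTree:
    """UPGMA merge tree.

    Leaves are numbered 0..n-1 in the order of ``ids``; the k-th merge
    creates node n+k and joins ``merges[k] = (node_a, node_b, height)``.
    """

    ids: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a tree over n leaves needs n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices under a node (a leaf is under itself)."""
        n = self.n_leaves
        if node < n:
            return [node]
        a, b, _ = self.merges[node - n]
        return sorted(self.leaves_under(a) + self.leaves_under(b))

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


@dataclass
class ClusterAssignment:
    """Flat cluster labels from a height cut.

    Labels are the smallest member item id of each cluster, which makes
    labelling deterministic under input permutation.
    """

    labels: dict[str, str]
    cut_height: float

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for item, lab in self.labels.items():
            out.setdefault(lab, []).append(item)
        return {lab: sorted(members) for lab, members in sorted(out.items())}

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def upgma(dm: DistanceMatrix) -> ClusterTree:
    """Agglomerative average-linkage (UPGMA) clustering.

    At every step the pair of clusters with the smallest unweighted mean of
    all cross-pair leaf distances is merged at that mean height. Equal
    minimal distances are broken by the lexicographically smallest pair of
    cluster representatives (each cluster represented by its smallest leaf
    id), so the tree is identical across platforms and input orderings.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 items")
    d = dm.d
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, str] = {i: dm.ids[i] for i in range(n)}
    # cached cluster-cluster distances, each computed as the plain mean of
    # the cross-pair block of the original leaf matrix
    cd: dict[tuple[int, int], float] = {}
    active = sorted(leaves)
    for i in range(n):
        for j in range(i + 1, n):
            cd[(i, j)] = float(d[i, j])
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dist = cd[(min(a, b), max(a, b))]
                tie = tuple(sorted((rep[a], rep[b])))
                cand = (dist, tie, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        height = cd[(min(a, b), max(a, b))]
        merges.append((a, b, height))
        new = next_node
        next_node += 1
        leaves[new] = sorted(leaves[a] + leaves[b])
        rep[new] = min(rep[a], rep[b])
        active = [c for c in active if c not in (a, b)]
        for c in active:
            # canonical orientation (smaller node id gives the rows) so the
            # mean is bit-identical to a from-scratch recomputation
            lo, hi = min(new, c), max(new, c)
            block = d[np.ix_(sorted(leaves[lo]), sorted(leaves[hi]))]
            cd[(lo, hi)] = float(np.mean(block))
        active.append(new)
    return ClusterTree(ids=list(dm.ids), merges=merges)


def cut_tree(tree: ClusterTree, t: float) -> ClusterAssignment:
    """Flat clusters after removing merges with height > t."""
    if t < 0:
        raise ValueError("cut height must be non-negative")
    n = tree.n_leaves
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b, h in tree.merges:
        if h > t:
            continue
        la = tree.leaves_under(a)[0]
        lb = tree.leaves_under(b)[0]
        ra, rb = find(la), find(lb)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(tree.ids[i])
    labels: dict[str, str] = {}
    for members in groups.values():
        lab = min(members)
        for m in members:
            labels[m] = lab
    return ClusterAssignment(labels=labels, cut_height=float(t))


def to_newick(tree: ClusterTree) -> str:
    """Ultrametric Newick string: a node merged at height h sits at h/2.

    Children are emitted smallest-leaf-label first, so the string is a
    canonical form of the tree.
    """
    n = tree.n_leaves

    def node_height(node: int) -> float:
        return 0.0 if node < n else tree.merges[node - n][2] / 2.0

    def min_leaf(node: int) -> str:
        return min(tree.ids[i] for i in tree.leaves_under(node))

    def children(node: int) -> tuple[int, int]:
        a, b, _ = tree.merges[node - n]
        return tuple(sorted((a, b), key=min_leaf))

    def render(node: int, parent_height: float) -> str:
        length = parent_height - node_height(node)
        if node < n:
            return f"{tree.ids[node]}:{length:.10g}"
        h = tree.merges[node - n][2]
        inner = ",".join(render(c, h / 2.0) for c in children(node))
        return f"({inner}):{length:.10g}"

    if n == 1:
        return f"{tree.ids[0]}:0;"
    root = n + len(tree.merges) - 1
    h = tree.merges[-1][2]
    inner = ",".join(render(c, h / 2.0) for c in children(root))
    return f"({inner});"
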