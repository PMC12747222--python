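"""Population-structure summaries: outgroup-f3 distance matrices, classical
multidimensional scaling, neighbor-joining trees, and hierarchical
clustering of Fst matrices.

Outgroup-f3(P1, P2; O) measures the shared drift of P1 and P2 since their
split from an outgroup O, so its inverse behaves as a genetic distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .fstats import f3, hudson_fst
from .genotypes import AlleleCountTable

__all__ = [
    "DistanceMatrix",
    "outgroup_f3_distance",
    "fst_distance",
    "classical_mds",
    "neighbor_joining",
    "fst_hclust",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if np.nanmax(np.abs(v - v.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.nanmax(np.abs(np.diag(v))) > 1e-12:
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v


def outgroup_f3_distance(
    counts: AlleleCountTable, labels: list[str], outgroup: str
) -> DistanceMatrix:
    """D[i, j] = 1 / f3(i, j; outgroup). Requires all pairwise f3 > 0."""
    k = len(labels)
    d = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        # apex at the outgroup: shared drift of the pair since their split
        res = f3(counts, outgroup, labels[i], labels[j], outgroup_mode=True)
        if res.estimate <= 0:
            raise ValueError(
                f"non-positive outgroup-f3 for ({labels[i]}, {labels[j]}): "
                "the chosen outgroup is unsuitable"
            )
        d[i, j] = d[j, i] = 1.0 / res.estimate
    return DistanceMatrix(labels=list(labels), values=d, provenance="1/f3")


def fst_distance(
    counts: AlleleCountTable, labels: list[str], min_snps: int = 5000
) -> DistanceMatrix:
    """Pairwise Hudson Fst matrix (inbreed-aware), enforcing the SNP floor."""
    k = len(labels)
    d = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        res = hudson_fst(counts, labels[i], labels[j], min_snps=min_snps)
        d[i, j] = d[j, i] = max(res.estimate, 0.0)
    return DistanceMatrix(labels=list(labels), values=d, provenance="fst")


def classical_mds(dist: DistanceMatrix, k: int = 2) -> dict:
    """Classical (Torgerson) MDS, the cmdscale algorithm.

    Double-centers -D^2/2, eigendecomposes, and returns the top-k
    coordinates scaled by the square root of the eigenvalues. Axes with
    non-positive eigenvalues are suppressed (with a warning flag in the
    result); each returned axis is sign-fixed so its largest-magnitude
    coordinate is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = dist.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int(np.sum(evals > 1e-10 * max(abs(evals[0]), 1.0)))
    k_eff = min(k, n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(np.maximum(evals[:k_eff], 0.0))
    for a in range(k_eff):
        i_max = np.argmax(np.abs(coords[:, a]))
        if coords[i_max, a] < 0:
            coords[:, a] = -coords[:, a]
    return {
        "coordinates": coords,
        "eigenvalues": evals,
        "labels": list(dist.labels),
        "truncated": k_eff < k,
    }


# ---------------------------------------------------------------------------
# Neighbor joining


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (node, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.17g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dist: DistanceMatrix, root_at: str | None = None) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Ties on the Q criterion break toward the lexicographically smallest
    label pair. Negative branch lengths are clamped to zero with the
    deficit moved to the sibling branch (the pairwise path length is
    preserved). With ``root_at``, the unrooted tree is rooted on that
    leaf's edge, making it the outgroup.
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if root_at is not None and root_at not in labels:
        raise KeyError(f"root label {root_at!r} not in matrix")
    d = dist.values.astype(float).copy()
    nodes = [_Node(name=l) for l in labels]
    names = list(labels)  # sort key for tie-breaks

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        dn = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dn[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # final three-way join: closed-form branch lengths
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    center = _Node(children=[
        (nodes[0], max(l0, 0.0)), (nodes[1], max(l1, 0.0)),
        (nodes[2], max(l2, 0.0)),
    ])
    if root_at is not None:
        center = _reroot_at_leaf(center, root_at)
    return center.newick() + ";"


def _reroot_at_leaf(center: _Node, leaf_name: str) -> _Node:
    """Re-root an unrooted (trifurcating) tree on the edge of a leaf."""

    def find_path(node: _Node, target: str, path):
        if node.name == target:
            return path + [(node, 0.0)]
        for child, bl in node.children:
            res = find_path(child, target, path + [(node, bl)])
            if res:
                return res
        return None

    path = find_path(center, leaf_name, [])
    if path is None:
        raise KeyError(leaf_name)
    # reverse parent pointers along the path from the leaf back to `center`
    # (the edge length parent->child is stored with the parent entry)
    for k in range(len(path) - 1, 0, -1):
        parent, bl = path[k - 1]
        child = path[k][0]
        parent.children = [(c, l) for c, l in parent.children if c is not child]
        child.children = child.children + [(parent, bl)]
    leaf = path[-1][0]
    # split the leaf's edge: root has the leaf on one side, the rest on the other
    (rest, bl) = leaf.children[0]
    leaf.children = []
    return _Node(children=[(leaf, 0.0), (rest, bl)])


# ---------------------------------------------------------------------------
# Fst hierarchical clustering


def fst_hclust(
    fst_matrix: DistanceMatrix,
    method: str = "average",
    cut_height: float | None = None,
) -> dict:
    """Agglomerative clustering of an Fst matrix.

    Returns the scipy linkage matrix, flat clusters at ``cut_height``
    (default: 70% of the maximum merge height), and a Newick rendering of
    the dendrogram. Pairs below the SNP floor must already be excluded;
    NaN cells are rejected.
    """
    v = fst_matrix.values
    if np.isnan(v).any():
        raise ValueError("Fst matrix contains NaN cells")
    z = hierarchy.linkage(squareform(v, checks=False), method=method)
    if cut_height is None:
        cut_height = 0.7 * z[:, 2].max() if len(z) else 0.0
    flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    tree = hierarchy.to_tree(z)

    def newick(node, parent_height):
        bl = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{fst_matrix.labels[node.id]}:{bl:.10g}"
        inner = ",".join(
            newick(c, node.dist) for c in (node.left, node.right)
        )
        return f"({inner}):{bl:.10g}"

    return {
        "linkage": z,
        "clusters": dict(zip(fst_matrix.labels, flat.tolist())),
        "newick": f"({','.join(newick(c, tree.dist) for c in (tree.left, tree.right))});"
        if not tree.is_leaf()
        else f"({fst_matrix.labels[tree.id]});",
    }
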