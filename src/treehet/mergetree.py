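"""Merge trees: the per-patient dendrogram representation.

A merge tree here is a rooted, unordered, edge-weighted tree with a height
attached to every vertex.  Heights weakly increase from the leaves towards
the single root, and the weight of a vertex is the length of the edge to its
father, ``w(v) = h(parent(v)) - h(v)``.  Dendrograms produced by
agglomerative clustering are merge trees with all leaves at height 0 and
internal vertices at the agglomeration heights.

The module provides construction from point clouds via average linkage,
the pruning operator ``P_eps`` that collapses homogeneous phenotypes,
height rescaling, height-count curves and Newick round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import (
    DataError,
    IntegrityError,
    NewickParseError,
    ScalingError,
)

__all__ = [
    "MergeTree",
    "PointCloud",
    "HeightCurve",
    "patient_point_cloud",
    "lesion_distance_matrix",
    "average_linkage_dendrogram",
    "rescale_heights",
    "height_count_curve",
    "prune",
    "to_newick",
    "from_newick",
]

_HEIGHT_TOL = 1e-9


@dataclass
class MergeTree:
    """Rooted, unordered, edge-weighted tree with vertex heights.

    Parameters
    ----------
    parent
        Integer array; ``parent[v]`` is the father of ``v``, ``-1`` at the
        single root.
    height
        Float array of vertex heights; ``height[parent[v]] >= height[v]``.
    labels
        Optional per-vertex labels (lesion ids on leaves, ``None`` inside).
    """

    parent: np.ndarray
    height: np.ndarray
    labels: list | None = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.height = np.asarray(self.height, dtype=float)
        if self.parent.shape != self.height.shape or self.parent.ndim != 1:
            raise IntegrityError("parent and height must be 1-d arrays of equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise IntegrityError(f"merge tree must have exactly one root, found {len(roots)}")
        nonroot = self.parent >= 0
        if np.any(self.height[self.parent[nonroot]] < self.height[nonroot] - _HEIGHT_TOL):
            raise IntegrityError("heights must weakly increase from leaf to root")
        if self.labels is None:
            self.labels = [None] * len(self.parent)

    # -- basic structure -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch

    def leaves(self) -> list[int]:
        has_child = np.zeros(self.n_vertices, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return [v for v in range(self.n_vertices) if not has_child[v]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def weights(self) -> np.ndarray:
        """Edge weight to the father per vertex; 0 at the root."""
        w = np.zeros(self.n_vertices)
        nonroot = self.parent >= 0
        w[nonroot] = self.height[self.parent[nonroot]] - self.height[nonroot]
        return np.maximum(w, 0.0)

    def total_weight(self) -> float:
        return float(self.weights().sum())

    @property
    def root_height(self) -> float:
        return float(self.height[self.root])

    def copy(self) -> "MergeTree":
        return MergeTree(self.parent.copy(), self.height.copy(), list(self.labels))

    # -- canonicalisation helpers ----------------------------------------
    def ghost_reduced(self) -> "MergeTree":
        """Remove every non-root order-2 vertex, merging its two edges.

        Ghosting is cost-free in the edit calculus: the child keeps its
        height and is re-attached to the grandfather, so the two edge
        weights sum automatically.
        """
        ch = self.children()
        keep = np.ones(self.n_vertices, dtype=bool)
        parent = self.parent.copy()
        for v in range(self.n_vertices):
            if parent[v] >= 0 and len(ch[v]) == 1:
                keep[v] = False
        # reattach across removed chains
        new_parent = parent.copy()
        for v in range(self.n_vertices):
            p = parent[v]
            while p >= 0 and not keep[p]:
                p = parent[p]
            new_parent[v] = p
        idx = np.flatnonzero(keep)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[idx] = np.arange(len(idx))
        par = np.where(new_parent[idx] >= 0, remap[new_parent[idx]], -1)
        return MergeTree(par, self.height[idx], [self.labels[i] for i in idx])

    def canonical_form(self, tol_decimals: int = 12) -> str:
        """Total-order string encoding, invariant under sibling permutation.

        Order-2 vertices are ghosted first, so two trees compare equal
        exactly when they are isomorphic as rooted unordered weighted trees
        modulo ghosting.  Weights are rounded to ``tol_decimals`` decimals.
        """
        t = self.ghost_reduced()
        ch = t.children()
        w = t.weights()

        def enc(v: int) -> str:
            inner = ",".join(sorted(enc(c) for c in ch[v]))
            if t.parent[v] < 0:
                return f"({inner})" if inner else "()"
            return f"({inner}){round(w[v] + 0.0, tol_decimals):.{tol_decimals}f}"

        return enc(t.root)


@dataclass
class PointCloud:
    """All lesions of one patient as points in the reduced radiomic space."""

    patient_id: object
    points: np.ndarray
    lesion_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1:
            raise DataError(f"patient {self.patient_id!r} has no lesions")
        if np.isnan(self.points).any():
            raise DataError(f"patient {self.patient_id!r} has missing coordinates")
        if not self.lesion_ids:
            self.lesion_ids = list(range(self.points.shape[0]))

    @property
    def n_lesions(self) -> int:
        return self.points.shape[0]


@dataclass
class HeightCurve:
    """Number of internal vertices above each threshold of a grid."""

    grid: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(np.diff(self.grid) < 0):
            raise DataError("height-curve grid must be ascending")
        if np.any(np.diff(self.counts) > 0):
            raise IntegrityError("height-curve counts must be non-increasing")


# ---------------------------------------------------------------------------
# construction


def patient_point_cloud(reduced, patient_id) -> PointCloud:
    """Extract one patient's lesions from a reduced matrix as a point cloud."""
    mask = np.asarray(reduced.patient_id) == patient_id
    if not mask.any():
        raise KeyError(f"unknown patient {patient_id!r}")
    return PointCloud(
        patient_id,
        np.asarray(reduced.scores)[mask],
        [lid for lid, m in zip(reduced.lesion_id, mask) if m],
    )


def lesion_distance_matrix(cloud: PointCloud) -> np.ndarray:
    """Pairwise Euclidean distances between a patient's lesion vectors."""
    diff = cloud.points[:, None, :] - cloud.points[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _check_square_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise IntegrityError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise IntegrityError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise IntegrityError("distance matrix must have a zero diagonal")
    return 0.5 * (D + D.T)


def average_linkage_dendrogram(D: np.ndarray, labels: Sequence | None = None) -> MergeTree:
    """Unweighted average-linkage (UPGMA-update) dendrogram as a merge tree.

    Leaves sit at height 0; each internal vertex sits at the height at which
    its two child clusters were agglomerated; the root is the final merge.
    """
    D = _check_square_distance(D)
    n = D.shape[0]
    labels = list(labels) if labels is not None else list(range(n))
    if n == 1:
        return MergeTree(np.array([-1]), np.array([0.0]), [labels[0]])
    Z = linkage(squareform(D, checks=False), method="average")
    parent = -np.ones(2 * n - 1, dtype=np.int64)
    height = np.zeros(2 * n - 1)
    for i, (a, b, h, _) in enumerate(Z):
        v = n + i
        parent[int(a)] = v
        parent[int(b)] = v
        height[v] = max(h, 0.0)
    # guard against tiny non-monotone steps from floating error
    for i in range(1, n - 1):
        height[n + i] = max(height[n + i], height[n + i - 1])
    return MergeTree(parent, height, labels + [None] * (n - 1))


def rescale_heights(trees: Iterable[MergeTree], mode: str = "global") -> list[MergeTree]:
    """Divide all heights by the highest merge value.

    ``global`` divides every tree by the cohort-wide maximum root height
    (preserving between-patient scale ratios); ``per_tree`` divides each
    tree by its own root height, mapping every root to 1.
    """
    trees = list(trees)
    if mode not in ("global", "per_tree"):
        raise ValueError(f"unknown rescale mode {mode!r}")
    if mode == "global":
        m = max((t.root_height for t in trees), default=0.0)
        if m <= 0:
            raise ScalingError("cannot rescale: all root heights are zero")
        return [MergeTree(t.parent.copy(), t.height / m, list(t.labels)) for t in trees]
    out = []
    for t in trees:
        m = t.root_height
        if m <= 0:
            raise ScalingError("cannot rescale a tree whose heights are all zero")
        out.append(MergeTree(t.parent.copy(), t.height / m, list(t.labels)))
    return out


def height_count_curve(tree: MergeTree, grid: Sequence[float]) -> HeightCurve:
    """Count internal vertices with height strictly above each threshold."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise DataError("grid must be ascending")
    ch = tree.children()
    internal = np.array([tree.height[v] for v in range(tree.n_vertices) if ch[v]])
    if internal.size == 0:
        return HeightCurve(grid, np.zeros(len(grid), dtype=np.int64))
    counts = (internal[None, :] > grid[:, None]).sum(axis=1)
    return HeightCurve(grid, counts)


# ---------------------------------------------------------------------------
# pruning


def _prune_alive(tree: MergeTree, eps: float, rng: np.random.Generator) -> np.ndarray:
    """Run the pruning iteration; return the boolean mask of kept vertices.

    Dead vertices are either deleted leaves or ghosted order-2 fathers;
    the surviving structure is read off by skipping dead vertices, so edge
    weights aggregate automatically (heights never change).
    """
    n = tree.n_vertices
    parent = tree.parent
    height = tree.height
    alive = np.ones(n, dtype=bool)
    nchild = np.zeros(n, dtype=np.int64)
    for p in parent:
        if p >= 0:
            nchild[p] += 1
    root = tree.root

    def eff_parent(v: int) -> int:
        p = parent[v]
        while p >= 0 and not alive[p]:
            p = parent[p]
        return int(p)

    while alive.sum() > 1:
        leaves = [v for v in range(n) if alive[v] and nchild[v] == 0 and v != root]
        cand: dict[int, list[int]] = {}
        wts: dict[int, float] = {}
        for v in leaves:
            p = eff_parent(v)
            w = height[p] - height[v]
            if w <= eps:
                cand.setdefault(p, []).append(v)
                wts[v] = w
        if not cand:
            break
        doomed: list[int] = []
        for father, vs in cand.items():
            if len(vs) < nchild[father]:
                # a sibling survives: delete every candidate leaf
                doomed.extend(vs)
            else:
                # all children are candidate leaves: keep the heaviest
                wmax = max(wts[v] for v in vs)
                best = sorted(v for v in vs if wts[v] >= wmax - 1e-12)
                keep = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
                doomed.extend(v for v in vs if v != keep)
        if not doomed:
            break
        for v in doomed:
            alive[v] = False
            p = eff_parent(v)
            nchild[p] -= 1
            # ghost fathers left with a single child (never the root)
            while p != root and nchild[p] == 1:
                alive[p] = False
                p = eff_parent(p)
    return alive


def _subtree_from_alive(tree: MergeTree, alive: np.ndarray) -> MergeTree:
    idx = np.flatnonzero(alive)
    remap = -np.ones(tree.n_vertices, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    par = np.empty(len(idx), dtype=np.int64)
    for i, v in enumerate(idx):
        p = tree.parent[v]
        while p >= 0 and not alive[p]:
            p = tree.parent[p]
        par[i] = remap[p] if p >= 0 else -1
    return MergeTree(par, tree.height[idx], [tree.labels[i] for i in idx])


def prune(tree: MergeTree, eps: float, rng_seed: int | np.random.Generator | None = 0) -> MergeTree:
    """Pruning operator ``P_eps``.

    Recursively deletes leaves whose father-child edge weighs at most
    ``eps``.  When *all* children of a father are such candidate leaves,
    only the heaviest is kept (a seeded uniform choice among ties); the
    father then has a single child and is ghosted, so the kept leaf's edge
    absorbs the father's edge.  The iteration stops when no deletable leaf
    remains; the final tree always retains at least one leaf.  ``P_eps`` is
    idempotent up to canonical form.
    """
    if eps < 0:
        raise ValueError(f"pruning threshold must be nonnegative, got {eps}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return _subtree_from_alive(tree, _prune_alive(tree, eps, rng))


# ---------------------------------------------------------------------------
# Newick I/O


def to_newick(tree: MergeTree) -> str:
    """Serialize with branch lengths equal to edge weights."""
    ch = tree.children()
    w = tree.weights()

    def name(v: int) -> str:
        lab = tree.labels[v]
        return str(lab) if lab is not None else (f"L{v}" if not ch[v] else "")

    def enc(v: int) -> str:
        if not ch[v]:
            body = name(v)
        else:
            body = "(" + ",".join(enc(c) for c in ch[v]) + ")" + name(v)
        if tree.parent[v] < 0:
            return body
        return f"{body}:{w[v]:.17g}"

    return enc(tree.root) + ";"


def from_newick(s: str) -> MergeTree:
    """Parse a Newick string with branch lengths into a merge tree.

    Vertex heights are reconstructed by placing the root at the maximum
    root-to-leaf path weight, so ultrametric inputs recover leaves at 0.
    """
    try:
        dt = dendropy.Tree.get(data=s, schema="newick", suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    nodes = list(dt.preorder_node_iter())
    if not nodes:
        raise NewickParseError("empty Newick string")
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    depth = np.zeros(len(nodes))
    labels: list = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            w = nd.edge.length
            if w is None:
                raise NewickParseError(f"edge into {labels[i] or i} lacks a branch length")
            if w < 0:
                raise NewickParseError(f"negative branch length {w} into {labels[i] or i}")
            depth[i] = depth[p] + float(w)
    root_height = float(depth.max())
    return MergeTree(parent, root_height - depth, labels)
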