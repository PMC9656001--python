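"""Approximate kNN via a priority-search k-means tree.

The reference set is recursively clustered (Lloyd's algorithm with
deterministic farthest-point initialization).  A query descends to the leaf
of the closest centroid while pushing sibling branches onto a priority queue
keyed by centroid distance, and keeps popping branches until at least B
candidate points have been examined.  Because only a subset of the reference
set is searched, every approximate kNN distance is an over-estimate of the
exact one (never an under-estimate); with B >= N2 the search is exhaustive
and agrees with the exact backend bit for bit.

Per-query cost is O(B * d * log N2 / log C) for branching factor C, versus
O(N2 * d) for an exact scan.
"""
from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

from .errors import InvalidConfigurationError


@dataclass
class _Node:
    centroid: np.ndarray
    children: list = field(default_factory=list)
    indices: np.ndarray | None = None  # set on leaves only

    @property
    def is_leaf(self) -> bool:
        return self.indices is not None


def _farthest_point_kmeans(points: np.ndarray, C: int, max_iters: int,
                           rng: np.random.Generator):
    """Lloyd's k-means with farthest-point init.

    Returns (centroids, groups) where groups is a list of index arrays into
    `points`; empty clusters are dropped.  Deterministic given rng state:
    the first center is an rng draw, subsequent centers maximize the minimum
    distance to chosen centers (ties to the lowest index), and assignment
    ties go to the lowest centroid index.
    """
    n = points.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    min_d = np.linalg.norm(points - points[first], axis=1)
    for _ in range(C - 1):
        nxt = int(np.argmax(min_d))
        if min_d[nxt] == 0.0:
            break  # remaining points coincide with existing centers
        chosen.append(nxt)
        np.minimum(min_d, np.linalg.norm(points - points[nxt], axis=1), out=min_d)
    centroids = points[chosen].copy()
    assign = None
    for _ in range(max_iters):
        D = euclidean_distances(points, centroids)
        new_assign = np.argmin(D, axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(centroids.shape[0]):
            mask = assign == j
            if mask.any():
                centroids[j] = points[mask].mean(axis=0)
    groups = []
    kept_centroids = []
    for j in range(centroids.shape[0]):
        members = np.flatnonzero(assign == j)
        if members.size:
            groups.append(members)
            kept_centroids.append(centroids[j])
    return np.asarray(kept_centroids), groups


class KMeansTree:
    """Hierarchical k-means index over a reference matrix.

    Every reference row index appears in exactly one leaf.  A node becomes a
    leaf when it holds at most `leaf_size` points or fewer points than the
    branching factor C.
    """

    def __init__(self, reference: np.ndarray, branching: int = 100,
                 max_iters: int = 10, leaf_size: int = 32, seed: int = 0):
        if branching < 2:
            raise InvalidConfigurationError(f"branching must be >= 2, got {branching}")
        self.reference = np.asarray(reference, dtype=np.float64)
        if self.reference.ndim != 2 or self.reference.shape[0] < 1:
            raise InvalidConfigurationError("reference must be a nonempty 2-D matrix")
        self.branching = branching
        self.max_iters = max_iters
        self.leaf_size = leaf_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.root = self._build(np.arange(self.reference.shape[0]), rng)
        self.last_examined = 0  # candidates examined by the most recent search

    def _build(self, indices: np.ndarray, rng: np.random.Generator) -> _Node:
        pts = self.reference[indices]
        centroid = pts.mean(axis=0)
        if indices.size <= self.leaf_size or indices.size < self.branching:
            return _Node(centroid=centroid, indices=indices)
        cents, groups = _farthest_point_kmeans(pts, self.branching,
                                               self.max_iters, rng)
        if len(groups) < 2:  # degenerate clustering (e.g. identical points)
            return _Node(centroid=centroid, indices=indices)
        node = _Node(centroid=centroid)
        for c, g in zip(cents, groups):
            child = self._build(indices[g], rng)
            child.centroid = c
            node.children.append(child)
        return node

    def depth(self) -> int:
        def rec(node):
            if node.is_leaf:
                return 1
            return 1 + max(rec(c) for c in node.children)
        return rec(self.root)

    def leaves(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(node.children)

    def search(self, query: np.ndarray, k: int, budget: int):
        """Approximate kNN by priority search.

        Returns (dist, idx): the k smallest distances found among at least
        ``budget`` examined candidates (or the whole reference set if it is
        smaller), with ties broken by reference row index.
        """
        if budget < k:
            raise InvalidConfigurationError(
                f"search budget must be >= k, got {budget} < {k}")
        query = np.asarray(query, dtype=np.float64).reshape(1, -1)
        counter = itertools.count()
        heap = [(0.0, next(counter), self.root)]
        cand: list[np.ndarray] = []
        examined = 0
        while heap and (examined < budget or examined < k):
            _, _, node = heapq.heappop(heap)
            if node.is_leaf:
                cand.append(node.indices)
                examined += node.indices.size
            else:
                cd = euclidean_distances(query, np.asarray(
                    [c.centroid for c in node.children]))[0]
                for dist_c, child in zip(cd, node.children):
                    heapq.heappush(heap, (float(dist_c), next(counter), child))
        self.last_examined = examined
        cand_idx = np.sort(np.concatenate(cand))
        D = euclidean_distances(query, self.reference[cand_idx])[0]
        if k < cand_idx.size:
            part = np.argpartition(D, k - 1)[:k]
            part.sort()  # ascending candidate position == ascending index
            order = part[np.argsort(D[part], kind="stable")]
        else:
            order = np.argsort(D, kind="stable")
        sel = order[:k]
        return D[sel], cand_idx[sel]


def build_tree(reference: np.ndarray, C: int = 100, Imax: int = 10,
               leaf_size: int = 32, seed: int = 0) -> KMeansTree:
    """Construct a priority-search k-means tree over `reference`."""
    return KMeansTree(reference, branching=C, max_iters=Imax,
                      leaf_size=leaf_size, seed=seed)


def priority_search(tree: KMeansTree, query: np.ndarray, k: int, B: int):
    """k approximate nearest-neighbor distances (and indices) within budget B."""
    return tree.search(query, k, B)
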