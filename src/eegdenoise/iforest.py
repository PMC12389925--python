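"""Extended isolation forest for scaleogram-slice anomaly detection.

Anomalous time slices are assumed to be rare and geometrically separable, so
they are isolated by random recursive partitioning: each tree is grown on a
random subsample, branching on random hyperplanes (slope drawn from a standard
normal per dimension, intercept uniform within the node's bounding box; a
point goes left iff ``(x - intercept) . slope <= 0``) until a point is
isolated or the depth limit ``ceil(log2(subsample))`` is reached.  The anomaly
score of a query is

    s(x) = 2 ** ( -E[h(x)] / a(psi) )

where ``E[h(x)]`` is the mean path length over the forest (leaf depth plus the
average-unsuccessful-BST-search adjustment ``a(leaf population)``) and
``a(psi)`` normalizes by the expected path length in a subsample of size
``psi``.  Scores near 1 mark anomalies; below 0.5, ordinary points.

The recursive kernels are compiled with numba; the first call in a process
pays a one-off compilation cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "EULER_GAMMA",
    "harmonic_number",
    "avg_path_normalizer",
    "ExtendedIsolationForest",
    "IsoTree",
    "path_length",
    "score_from_mean_path",
    "detect_anomalies",
]

#: Euler–Mascheroni constant, limit of H(n) - ln(n).
EULER_GAMMA = 0.5772156649015329

_EXACT_HARMONIC_LIMIT = 10_000


def harmonic_number(i: int) -> float:
    """H(i) = sum_{j<=i} 1/j; exact summation up to 1e4, ln(i) + gamma above."""
    if i < 0:
        raise ValueError("harmonic number defined for nonnegative arguments")
    if i <= _EXACT_HARMONIC_LIMIT:
        return float(np.sum(1.0 / np.arange(1, i + 1)))
    return math.log(i) + EULER_GAMMA


def avg_path_normalizer(size: int) -> float:
    """Average unsuccessful-BST-search path length a(size).

    0 for ``size < 2``, 1 for ``size == 2`` and
    ``2 H(size - 1) - 2 (size - 1) / size`` above.
    """
    if size < 1:
        raise ValueError("size must be a positive integer")
    if size < 2:
        return 0.0
    if size == 2:
        return 1.0
    return 2.0 * harmonic_number(size - 1) - 2.0 * (size - 1) / size


def _normalizer_table(max_size: int) -> np.ndarray:
    """a(c) for c = 0..max_size, via one cumulative harmonic sum."""
    table = np.zeros(max_size + 1)
    if max_size >= 2:
        h = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, max_size))])
        sizes = np.arange(2, max_size + 1)
        table[2:] = 2.0 * h[sizes - 1] - 2.0 * (sizes - 1) / sizes
        table[2] = 1.0
    return table


@njit(cache=True)
def _build_forest(X, subsample, n_trees, depth_limit, seed):  # pragma: no cover
    n, d = X.shape
    # internal nodes carry >= 2 points each, disjoint per depth level, so the
    # node count is bounded well below 3 * subsample even with empty children
    max_nodes = 3 * subsample + 3
    slopes = np.zeros((n_trees, max_nodes, d))
    intercepts = np.zeros((n_trees, max_nodes, d))
    left = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    right = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    leaf_count = np.zeros((n_trees, max_nodes), dtype=np.int32)
    node_depth = np.zeros((n_trees, max_nodes), dtype=np.int32)
    n_nodes = np.zeros(n_trees, dtype=np.int32)

    np.random.seed(seed)
    stack_cap = 4 * subsample + 8
    st_node = np.empty(stack_cap, dtype=np.int32)
    st_lo = np.empty(stack_cap, dtype=np.int32)
    st_hi = np.empty(stack_cap, dtype=np.int32)
    st_depth = np.empty(stack_cap, dtype=np.int32)
    mn = np.empty(d)
    mx = np.empty(d)
    slope = np.empty(d)
    inter = np.empty(d)

    for t in range(n_trees):
        work = np.random.permutation(n)[:subsample]
        nc = 1
        top = 0
        st_node[0] = 0
        st_lo[0] = 0
        st_hi[0] = subsample
        st_depth[0] = 0
        while top >= 0:
            node = st_node[top]
            lo = st_lo[top]
            hi = st_hi[top]
            depth = st_depth[top]
            top -= 1
            node_depth[t, node] = depth
            count = hi - lo
            if count <= 1 or depth >= depth_limit:
                leaf_count[t, node] = count
                continue
            for dd in range(d):
                lo_v = X[work[lo], dd]
                hi_v = lo_v
                for i in range(lo + 1, hi):
                    v = X[work[i], dd]
                    if v < lo_v:
                        lo_v = v
                    elif v > hi_v:
                        hi_v = v
                mn[dd] = lo_v
                mx[dd] = hi_v
            degenerate = True
            for dd in range(d):
                if mx[dd] > mn[dd]:
                    degenerate = False
                    break
            if degenerate:  # duplicated points cannot be separated
                leaf_count[t, node] = count
                continue
            for dd in range(d):
                slope[dd] = np.random.standard_normal()
                if mx[dd] > mn[dd]:
                    inter[dd] = np.random.uniform(mn[dd], mx[dd])
                else:
                    inter[dd] = mn[dd]
            i = lo
            j = hi - 1
            while i <= j:
                proj = 0.0
                p = work[i]
                for dd in range(d):
                    proj += (X[p, dd] - inter[dd]) * slope[dd]
                if proj <= 0.0:
                    i += 1
                else:
                    work[i] = work[j]
                    work[j] = p
                    j -= 1
            split = i
            lid = nc
            rid = nc + 1
            nc += 2
            for dd in range(d):
                slopes[t, node, dd] = slope[dd]
                intercepts[t, node, dd] = inter[dd]
            left[t, node] = lid
            right[t, node] = rid
            top += 1
            st_node[top] = lid
            st_lo[top] = lo
            st_hi[top] = split
            st_depth[top] = depth + 1
            top += 1
            st_node[top] = rid
            st_lo[top] = split
            st_hi[top] = hi
            st_depth[top] = depth + 1
        n_nodes[t] = nc
    return slopes, intercepts, left, right, leaf_count, node_depth, n_nodes


@njit(cache=True)
def _mean_path_lengths(Q, slopes, intercepts, left, right, leaf_count, node_depth, a_table):  # pragma: no cover
    n_trees = slopes.shape[0]
    nq, d = Q.shape
    out = np.zeros(nq)
    for t in range(n_trees):
        for i in range(nq):
            node = 0
            while left[t, node] >= 0:
                proj = 0.0
                for dd in range(d):
                    proj += (Q[i, dd] - intercepts[t, node, dd]) * slopes[t, node, dd]
                if proj <= 0.0:
                    node = left[t, node]
                else:
                    node = right[t, node]
            out[i] += node_depth[t, node] + a_table[leaf_count[t, node]]
    return out / n_trees


@dataclass(frozen=True)
class IsoTree:
    """Read-only view of one tree of a fitted forest (tests and inspection)."""

    slopes: np.ndarray
    intercepts: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_count: np.ndarray
    node_depth: np.ndarray
    n_nodes: int
    depth_limit: int

    @property
    def dim(self) -> int:
        return self.slopes.shape[1]

    def is_leaf(self, node: int) -> bool:
        return self.left[node] < 0


def path_length(tree: IsoTree, point: np.ndarray) -> float:
    """Edges traversed from root to leaf, plus a(leaf population)."""
    point = np.asarray(point, dtype=np.float64)
    if point.shape != (tree.dim,):
        raise ValueError(f"point dimension {point.shape} != training dimension ({tree.dim},)")
    node = 0
    while not tree.is_leaf(node):
        proj = float((point - tree.intercepts[node]) @ tree.slopes[node])
        node = int(tree.left[node] if proj <= 0.0 else tree.right[node])
    return float(tree.node_depth[node]) + avg_path_normalizer(max(int(tree.leaf_count[node]), 1))


def score_from_mean_path(mean_path: float, subsample: int) -> float:
    """Anomaly score 2 ** (-E[h] / a(subsample))."""
    return float(2.0 ** (-mean_path / avg_path_normalizer(subsample)))


class ExtendedIsolationForest:
    """Ensemble of random-hyperplane isolation trees.

    Parameters
    ----------
    n_trees:
        Number of trees (IFt).
    subsample:
        Training points per tree, drawn without replacement (IFS).
    seed:
        Seed for the tree-growing randomness; fits are fully deterministic.
    """

    def __init__(self, n_trees: int = 100, subsample: int = 256, seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if subsample < 2:
            raise ValueError("subsample must be >= 2")
        self.n_trees = int(n_trees)
        self.subsample = int(subsample)
        self.seed = int(seed)
        self._fitted = False

    def fit(self, X: np.ndarray) -> "ExtendedIsolationForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("training data must be 2-D (points x dimensions)")
        if X.shape[0] < self.subsample:
            raise ValueError(
                f"subsample ({self.subsample}) exceeds the number of training points ({X.shape[0]})"
            )
        self.dim_ = X.shape[1]
        self.depth_limit_ = int(math.ceil(math.log2(self.subsample)))
        (
            self._slopes,
            self._intercepts,
            self._left,
            self._right,
            self._leaf_count,
            self._node_depth,
            self._n_nodes,
        ) = _build_forest(X, self.subsample, self.n_trees, self.depth_limit_, self.seed)
        self._a_table = _normalizer_table(self.subsample)
        self._a_sub = avg_path_normalizer(self.subsample)
        self._fitted = True
        return self

    def _check(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("forest is not fitted")
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.dim_:
            raise ValueError(f"query dimension {X.shape[1]} != training dimension {self.dim_}")
        return X

    def mean_path_length(self, X: np.ndarray) -> np.ndarray:
        """E[h(x)] over the forest, one value per query row."""
        X = self._check(X)
        return _mean_path_lengths(
            X,
            self._slopes,
            self._intercepts,
            self._left,
            self._right,
            self._leaf_count,
            self._node_depth,
            self._a_table,
        )

    def score(self, X: np.ndarray) -> np.ndarray:
        """Anomaly scores in (0, 1], one per query row."""
        eh = self.mean_path_length(X)
        return 2.0 ** (-eh / self._a_sub)

    def tree(self, t: int) -> IsoTree:
        if not self._fitted:
            raise RuntimeError("forest is not fitted")
        nn = int(self._n_nodes[t])
        return IsoTree(
            slopes=self._slopes[t, :nn],
            intercepts=self._intercepts[t, :nn],
            left=self._left[t, :nn],
            right=self._right[t, :nn],
            leaf_count=self._leaf_count[t, :nn],
            node_depth=self._node_depth[t, :nn],
            n_nodes=nn,
            depth_limit=self.depth_limit_,
        )


def detect_anomalies(forest: ExtendedIsolationForest, slices: np.ndarray, ta: float) -> np.ndarray:
    """Indices of slice vectors whose anomaly score strictly exceeds ``ta``."""
    if not 0.0 < ta < 1.0:
        raise ValueError("anomaly threshold must lie in (0, 1)")
    scores = forest.score(slices)
    return np.flatnonzero(scores > ta)
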