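"""Nearest- and second-nearest-neighbour search over 128-d descriptors.

Exact search is a brute-force Euclidean scan.  The approximate path builds a
KD-tree (split dimension = dimension of maximum spread at the node, split
value = median) and runs best-bin-first (BBF) search: branches not taken are
queued by their axis distance to the query and explored in that order until
the queue empties or a fixed leaf-visit budget is spent.  With an unlimited
budget and the usual pruning, BBF returns the exact 2-NN; a budget of 200
leaf visits trades a small accuracy loss for bounded search cost.

All ties break toward the lower descriptor index, so results are
deterministic and independent of insertion order when distances differ.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KdTree",
    "NeighborPair",
    "build_kdtree",
    "bbf_knn",
    "brute_force_knn",
    "match_descriptors",
]

DEFAULT_NODE_BUDGET = 200
LEAF_SIZE = 8


@dataclass(frozen=True)
class NeighborPair:
    """Nearest (q) and second-nearest (qbar) neighbours of a query."""

    q: int
    d1: float
    qbar: int
    d2: float

    def __post_init__(self):
        if self.q == self.qbar:
            raise ValueError("nearest and second-nearest must differ")
        if self.d1 > self.d2 + 1e-12:
            raise ValueError("nearest distance exceeds second-nearest")


@dataclass
class _Node:
    split_dim: int = -1
    split_val: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    indices: np.ndarray | None = None  # leaf payload

    @property
    def is_leaf(self) -> bool:
        return self.indices is not None


@dataclass
class KdTree:
    root: _Node
    data: np.ndarray  # (n, d) descriptors
    n_leaves: int

    def __len__(self) -> int:
        return len(self.data)

    def leaf_indices(self) -> list[np.ndarray]:
        """All leaves' descriptor indices, left-to-right (test hook)."""
        out: list[np.ndarray] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.indices)
            else:
                stack.append(node.right)
                stack.append(node.left)
        return out


def build_kdtree(descriptors, leaf_size: int = LEAF_SIZE) -> KdTree:
    """Build a KD-tree over a set of descriptors.

    At each node the split dimension is the one with maximum spread and the
    split value is the median along it; points with coordinate <= median go
    left.  Degenerate spreads (identical descriptors) produce a valid tree
    by splitting the index range in half.
    """
    data = np.asarray(descriptors, dtype=float)
    if data.ndim != 2:
        raise ValueError("descriptors must form an (n, d) matrix")
    if len(data) < 2:
        raise ValueError("need >= 2 descriptors; use brute force for fewer")

    n_leaves = 0

    def rec(idx: np.ndarray) -> _Node:
        nonlocal n_leaves
        if len(idx) <= leaf_size:
            n_leaves += 1
            return _Node(indices=np.sort(idx))
        pts = data[idx]
        spread = pts.max(axis=0) - pts.min(axis=0)
        dim = int(np.argmax(spread))
        vals = pts[:, dim]
        med = float(np.median(vals))
        left_mask = vals <= med
        # a heavily tied median can put everything on one side; fall back to
        # an index-order halving so the tree always makes progress
        if left_mask.all() or not left_mask.any():
            half = len(idx) // 2
            order = np.argsort(vals, kind="stable")
            left_idx, right_idx = idx[order[:half]], idx[order[half:]]
            med = float(vals[order[half - 1]])
        else:
            left_idx, right_idx = idx[left_mask], idx[~left_mask]
        node = _Node(split_dim=dim, split_val=med)
        node.left = rec(left_idx)
        node.right = rec(right_idx)
        return node

    root = rec(np.arange(len(data)))
    return KdTree(root=root, data=data, n_leaves=n_leaves)


def _best_two(dists: np.ndarray, indices: np.ndarray) -> NeighborPair:
    order = np.argsort(dists, kind="stable")
    return NeighborPair(
        q=int(indices[order[0]]),
        d1=float(dists[order[0]]),
        qbar=int(indices[order[1]]),
        d2=float(dists[order[1]]),
    )


def brute_force_knn(descriptors, query, k: int = 2) -> NeighborPair:
    """Exact Euclidean 2-NN by full scan; ties go to the lower index."""
    if k != 2:
        raise ValueError("only k=2 supported (nearest + second-nearest)")
    data = np.asarray(descriptors, dtype=float)
    if data.ndim != 2 or len(data) < 2:
        raise ValueError("need an (n >= 2, d) descriptor matrix")
    q = np.asarray(query, dtype=float)
    d = np.sqrt(((data - q) ** 2).sum(axis=1))
    return _best_two(d, np.arange(len(data)))


def bbf_knn(
    tree: KdTree,
    query,
    k: int = 2,
    node_budget: int | None = DEFAULT_NODE_BUDGET,
) -> NeighborPair:
    """Best-bin-first 2-NN search with a leaf-visit budget.

    Leaves are visited in order of the axis distance from the query to the
    unexplored half-space; the search stops when the priority queue is empty,
    every remaining bin is provably farther than the current second-nearest
    (exact pruning), or ``node_budget`` leaves have been examined.  Pass
    ``node_budget=None`` for an unlimited budget (exact search).
    """
    if k != 2:
        raise ValueError("only k=2 supported (nearest + second-nearest)")
    if len(tree) < 2:
        raise ValueError("tree holds < 2 descriptors")
    q = np.asarray(query, dtype=float)
    budget = np.inf if node_budget is None else int(node_budget)

    best_d = np.array([np.inf, np.inf])
    best_i = np.array([-1, -1])
    visits = 0
    counter = 0  # FIFO tiebreak for equal heap keys
    heap: list[tuple[float, int, _Node]] = [(0.0, counter, tree.root)]

    while heap and visits < budget:
        bound, _, node = heapq.heappop(heap)
        if bound >= best_d[1]:
            break  # every remaining bin is at least this far: exact stop
        while not node.is_leaf:
            diff = q[node.split_dim] - node.split_val
            if diff <= 0:
                near, far = node.left, node.right
            else:
                near, far = node.right, node.left
            counter += 1
            heapq.heappush(heap, (abs(diff), counter, far))
            node = near
        visits += 1
        idx = node.indices
        d = np.sqrt(((tree.data[idx] - q) ** 2).sum(axis=1))
        for dist, i in sorted(zip(d, idx), key=lambda t: (t[0], t[1])):
            i = int(i)
            if i == best_i[0] or i == best_i[1]:
                continue
            if dist < best_d[0] or (dist == best_d[0] and i < best_i[0]):
                best_d[1], best_i[1] = best_d[0], best_i[0]
                best_d[0], best_i[0] = dist, i
            elif dist < best_d[1] or (dist == best_d[1] and i < best_i[1]):
                best_d[1], best_i[1] = dist, i

    if best_i[1] < 0:
        raise RuntimeError("budget too small to find two neighbours")
    return NeighborPair(
        q=int(best_i[0]), d1=float(best_d[0]), qbar=int(best_i[1]), d2=float(best_d[1])
    )


def match_descriptors(
    queries: np.ndarray,
    targets: np.ndarray,
    node_budget: int | None = DEFAULT_NODE_BUDGET,
    use_tree: bool = True,
) -> list[NeighborPair]:
    """2-NN matches of every query descriptor against a target set.

    Uses KD-tree BBF search when ``use_tree`` (and >= 2 targets); falls back
    to the exact brute-force scan otherwise.
    """
    targets = np.asarray(targets, dtype=float)
    queries = np.asarray(queries, dtype=float)
    if len(targets) < 2 or len(queries) == 0:
        return []
    if use_tree:
        tree = build_kdtree(targets)
        return [bbf_knn(tree, qv, node_budget=node_budget) for qv in queries]
    return [brute_force_knn(targets, qv) for qv in queries]
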