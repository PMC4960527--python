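"""Indexed binary max-heap over node scores.

The adaptive attacks repeatedly (a) pop the node with the largest score,
(b) lower the scores of a handful of nearby nodes after a removal.  Both are
O(log N) with a binary heap that keeps a node -> slot index, so a changed
slot can be re-heapified locally instead of rebuilding the heap.

The array kernels are numba-jitted and shared verbatim by the attack loops,
so the heap the tests exercise is the heap the attacks run on.

Score updates after a removal can only decrease on locally tree-like
structure, but on loopy graphs with large radii an increase is conceivable;
a sift-up fallback handles it rather than silently violating the invariant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["IndexedMaxHeap"]


@njit(cache=True)
def _higher(sa, na, sb, nb, det):  # pragma: no cover - jitted
    """True if slot a has strictly higher priority than slot b."""
    if sa != sb:
        return sa > sb
    if det:
        return na < nb  # deterministic ties: smaller node id wins
    return False


@njit(cache=True)
def _swap(scores, nodes, pos, a, b):  # pragma: no cover - jitted
    sa, na = scores[a], nodes[a]
    scores[a], nodes[a] = scores[b], nodes[b]
    scores[b], nodes[b] = sa, na
    pos[nodes[a]] = a
    pos[nodes[b]] = b


@njit(cache=True)
def _sift_down(scores, nodes, pos, size, slot, det):  # pragma: no cover
    while True:
        left = 2 * slot + 1
        if left >= size:
            return
        best = left
        right = left + 1
        if right < size and _higher(scores[right], nodes[right], scores[left], nodes[left], det):
            best = right
        if _higher(scores[best], nodes[best], scores[slot], nodes[slot], det):
            _swap(scores, nodes, pos, slot, best)
            slot = best
        else:
            return


@njit(cache=True)
def _sift_up(scores, nodes, pos, slot, det):  # pragma: no cover - jitted
    while slot > 0:
        parent = (slot - 1) // 2
        if _higher(scores[slot], nodes[slot], scores[parent], nodes[parent], det):
            _swap(scores, nodes, pos, slot, parent)
            slot = parent
        else:
            return


@njit(cache=True)
def _build(scores, nodes, pos, size, det):  # pragma: no cover - jitted
    """Bottom-up heapification: sift down every internal slot, deepest first."""
    for slot in range(size // 2 - 1, -1, -1):
        _sift_down(scores, nodes, pos, size, slot, det)


@njit(cache=True)
def _pop(scores, nodes, pos, size, det):  # pragma: no cover - jitted
    """Pop the root: return (node, score, new_size)."""
    node = nodes[0]
    score = scores[0]
    pos[node] = -1
    size -= 1
    if size > 0:
        scores[0] = scores[size]
        nodes[0] = nodes[size]
        pos[nodes[0]] = 0
        _sift_down(scores, nodes, pos, size, 0, det)
    return node, score, size


@njit(cache=True)
def _update(scores, nodes, pos, size, node, new_score, det):  # pragma: no cover
    slot = pos[node]
    old = scores[slot]
    scores[slot] = new_score
    if new_score < old:
        _sift_down(scores, nodes, pos, size, slot, det)
    elif new_score > old:
        _sift_up(scores, nodes, pos, slot, det)
    elif det:
        # equal score: position may still be fine; nothing to do
        pass


class IndexedMaxHeap:
    """Binary max-heap over ``(node, score)`` with a node -> slot index.

    Parameters
    ----------
    scores : array-like of float
        Score per node id ``0..n-1``; nodes with ``mask[i]`` False are left
        out of the heap.
    mask : ndarray of bool, optional
        Which nodes to include (default all).
    deterministic_ties : bool
        Break equal scores by smallest node id, making pop order a total
        deterministic order (used for oracle-equivalence tests).
    """

    def __init__(self, scores, mask=None, deterministic_ties: bool = False):
        scores = np.asarray(scores, dtype=np.float64)
        n = scores.size
        if mask is None:
            mask = np.ones(n, dtype=np.bool_)
        ids = np.flatnonzero(mask).astype(np.int64)
        self._scores = np.empty(n, dtype=np.float64)
        self._nodes = np.empty(n, dtype=np.int64)
        self._pos = np.full(n, -1, dtype=np.int64)
        self._size = ids.size
        self._scores[:ids.size] = scores[ids]
        self._nodes[:ids.size] = ids
        self._pos[ids] = np.arange(ids.size)
        self.deterministic_ties = bool(deterministic_ties)
        if not np.all(np.isfinite(self._scores[:self._size])):
            raise ValueError("scores must be finite")
        _build(self._scores, self._nodes, self._pos, self._size, self.deterministic_ties)

    @classmethod
    def from_dict(cls, mapping: dict, deterministic_ties: bool = False) -> "IndexedMaxHeap":
        n = max(mapping) + 1 if mapping else 0
        scores = np.zeros(n, dtype=np.float64)
        mask = np.zeros(n, dtype=np.bool_)
        for node, s in mapping.items():
            scores[node] = s
            mask[node] = True
        return cls(scores, mask=mask, deterministic_ties=deterministic_ties)

    def __len__(self) -> int:
        return self._size

    def __contains__(self, node: int) -> bool:
        return 0 <= node < self._pos.size and self._pos[node] >= 0

    def peek(self) -> tuple[int, float]:
        if self._size == 0:
            raise IndexError("peek from an empty heap")
        return int(self._nodes[0]), float(self._scores[0])

    def pop_max(self) -> tuple[int, float]:
        """Remove and return the (node, score) with the largest score."""
        if self._size == 0:
            raise IndexError("pop from an empty heap")
        node, score, self._size = _pop(
            self._scores, self._nodes, self._pos, self._size, self.deterministic_ties
        )
        return int(node), float(score)

    def update(self, node: int, new_score: float) -> None:
        """Write a new score at a node's slot and restore the heap property.

        A decrease sifts the slot down its sub-tree (the common case after a
        removal); an increase sifts up.
        """
        if node not in self:
            raise KeyError(f"node {node} not in heap")
        _update(self._scores, self._nodes, self._pos, self._size, node,
                float(new_score), self.deterministic_ties)

    # spec name for the decrease path
    decrease_and_fix = update

    def score_of(self, node: int) -> float:
        if node not in self:
            raise KeyError(f"node {node} not in heap")
        return float(self._scores[self._pos[node]])

    def is_valid(self) -> bool:
        """Full-scan check of the max-heap property and the position index."""
        s, nd, size = self._scores, self._nodes, self._size
        for slot in range(size):
            for child in (2 * slot + 1, 2 * slot + 2):
                if child < size and s[child] > s[slot]:
                    return False
            if self._pos[nd[slot]] != slot:
                return False
        return True
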