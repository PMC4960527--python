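"""Greedy reinsertion of removed nodes, minimizing G(q) below the threshold.

Starting from the attacked (fragmented) state, removed nodes are added back
in batches; each batch takes the candidates that would join the *fewest
distinct clusters* among their present neighbors — cluster sizes are
deliberately ignored.  Reinserting a node restores only its edges to present
neighbors, so after full reinsertion the original graph is recovered
exactly.  The rebuilt G(q) curve is the attack's budget-limited answer for
q below the percolation point: what to remove if only q N removals are
affordable.

Cluster membership is tracked with union-find; candidate counts are
recomputed from scratch each batch (simple and unambiguous at desk scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .graph_core import Graph, GraphError

__all__ = ["ReinsertionConfig", "reinsert"]


@dataclass
class ReinsertionConfig:
    """Batch size and tie handling for the reinsertion pass.

    ``batch_fraction`` is the fraction of N reinserted per step (default
    0.2%; smaller fractions do not change the resulting curves).  Ties on
    equal cluster counts are broken by smallest node id (deterministic) or
    uniformly at random.
    """

    batch_fraction: float = 0.002
    tie_rule: str = "smallest_id"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.batch_fraction <= 1.0:
            raise GraphError("batch_fraction must be in (0, 1]")
        if self.tie_rule not in ("smallest_id", "random"):
            raise GraphError(f"unknown tie_rule {self.tie_rule!r}")


@njit(cache=True)
def _find(parent, x):  # pragma: no cover - jitted
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        parent[x], x = root, parent[x]
    return root


@njit(cache=True)
def _union(parent, size, a, b):  # pragma: no cover - jitted
    ra = _find(parent, a)
    rb = _find(parent, b)
    if ra == rb:
        return ra
    if size[ra] < size[rb]:
        ra, rb = rb, ra
    parent[rb] = ra
    size[ra] += size[rb]
    return ra


@njit(cache=True)
def _count_clusters(indptr, indices, present, parent, removed_ids,
                    roots_scratch):  # pragma: no cover - jitted
    """Distinct clusters among present neighbors, per removed candidate."""
    counts = np.empty(removed_ids.size, np.int64)
    for idx in range(removed_ids.size):
        i = removed_ids[idx]
        nr = 0
        for p in range(indptr[i], indptr[i + 1]):
            v = indices[p]
            if present[v]:
                r = _find(parent, v)
                dup = False
                for t in range(nr):
                    if roots_scratch[t] == r:
                        dup = True
                        break
                if not dup:
                    roots_scratch[nr] = r
                    nr += 1
        counts[idx] = nr
    return counts


@njit(cache=True)
def _attach(indptr, indices, present, parent, size, i):  # pragma: no cover
    present[i] = True
    parent[i] = i
    size[i] = 1
    for p in range(indptr[i], indptr[i + 1]):
        v = indices[p]
        if present[v]:
            _union(parent, size, i, v)


def reinsert(graph: Graph, removed_set, config: ReinsertionConfig | None = None,
             forward_trace=None) -> list[tuple[float, float]]:
    """Reinsert all removed nodes, fewest-joined-clusters first, in batches.

    Parameters
    ----------
    graph : Graph
        In the attacked state; mutated back to the original graph.
    removed_set : sequence of int
        The nodes removed by the attack (order irrelevant).
    forward_trace : AttackTrace, optional
        Unused by the algorithm; accepted for CLI convenience.

    Returns
    -------
    list of (q, giant) pairs, one after each batch, with q the removed
    fraction still out of the network and giant the largest-cluster size as
    a fraction of N.  q decreases along the sequence down to 0.
    """
    config = config or ReinsertionConfig()
    removed = np.unique(np.asarray(list(removed_set), dtype=np.int64))
    if removed.size == 0:
        raise GraphError("removed_set is empty")
    if np.any(graph.present[removed]):
        raise GraphError("removed_set contains present nodes")
    n = graph.n_nodes
    rng = np.random.default_rng(config.seed)

    # union-find over the present nodes
    parent = np.arange(n, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    src = np.repeat(np.arange(n), np.diff(graph.indptr))
    both_present = graph.present[src] & graph.present[graph.indices] & (src < graph.indices)
    for a, b in zip(src[both_present], graph.indices[both_present]):
        _union(parent, size, a, b)

    batch = max(1, int(round(config.batch_fraction * n)))
    roots_scratch = np.empty(int(graph._degree0.max()) + 1, np.int64)
    curve: list[tuple[float, float]] = []
    still_out = removed
    while still_out.size:
        counts = _count_clusters(graph.indptr, graph.indices, graph.present,
                                 parent, still_out, roots_scratch)
        take = min(batch, still_out.size)
        if config.tie_rule == "random":
            jitter = rng.random(still_out.size)
            order = np.lexsort((jitter, counts))
        else:
            order = np.lexsort((still_out, counts))  # smallest id on ties
        chosen = still_out[order[:take]]
        for i in chosen:
            graph.restore_node(int(i))  # mask + live degrees, edges to present only
            _attach(graph.indptr, graph.indices, graph.present, parent, size, int(i))
        keep = np.ones(still_out.size, np.bool_)
        keep[order[:take]] = False
        still_out = still_out[keep]
        giant = _giant_from_uf(parent, size, graph.present)
        curve.append((still_out.size / n, giant / n))
    return curve


@njit(cache=True)
def _giant_from_uf_kernel(parent, size, present):  # pragma: no cover - jitted
    giant = 0
    for i in range(present.size):
        if present[i] and parent[i] == i and size[i] > giant:
            giant = size[i]
    return giant


def _giant_from_uf(parent, size, present) -> int:
    return int(_giant_from_uf_kernel(parent, size, present))
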