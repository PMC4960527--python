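"""Collective Influence adaptive attack and the high-degree-adaptive baseline.

The CI score of node i at radius l is

    CI_l(i) = (k_i - 1) * sum_{j in dB(i,l)} (k_j - 1)

where dB(i, l) is the frontier of the ball of radius l around i (present
nodes at shortest-path distance exactly l) and all degrees are live degrees
in the current masked graph.  The attack removes the highest-CI node one by
one, which greedily lowers the largest eigenvalue of the non-backtracking
matrix and hence dismantles the giant component with few removals.

Keeping the run near O(N log N):

* scores live in an indexed max-heap (pop and local re-heapify are O(log N));
* after removing node i only nodes within distance l+1 of i change score.
  Nodes at distance <= l are recomputed by a fresh depth-l BFS; a node j on
  the outer layer (distance exactly l+1) loses (k_j - 1) for *each* neighbor
  of i sitting on j's l-frontier — exactly (k_j - 1) on a tree, and counting
  the multiplicity keeps the update exact on loopy graphs as well;
* the stopping rule monitors

      lambda(l; q) = [ sum_i CI_l(i) / (N <k>) ]^(1/(l+1))

  with N <k> the *live* degree sum (twice the surviving edge count), both
  maintained incrementally from running sums.  lambda estimates the
  remnant's kappa - 1 (the leading non-backtracking eigenvalue of tree-like
  graphs); the network is dismantled when it reaches 1, which avoids an
  O(N) component check per removal.  At q = 0 on tree-like random graphs
  lambda = kappa - 1 with kappa = <k^2>/<k>.

The high-degree-adaptive (HDA) baseline removes the current highest-degree
node with the same heap machinery; it is the l = 0 analogue of CI and needs
an explicit (thinned) component check to stop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .graph_core import Graph, GraphError, _components_kernel
from .heap import IndexedMaxHeap, _build, _pop, _update
from .trace import AttackTrace

__all__ = [
    "CIConfig",
    "frontier",
    "ci_value",
    "compute_all_ci",
    "lambda_monitor",
    "remove_and_update",
    "ci_attack",
    "hda_attack",
    "reference_ci_attack",
]


# ---------------------------------------------------------------------------
# BFS kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ci_value_kernel(indptr, indices, present, degree, src, ell,
                     mark, dist, queue, stamp):  # pragma: no cover - jitted
    if degree[src] <= 1:
        return 0.0
    stamp[0] += 1
    s = stamp[0]
    mark[src] = s
    dist[src] = 0
    queue[0] = src
    head, tail = 0, 1
    acc = 0.0
    while head < tail:
        u = queue[head]
        head += 1
        du = dist[u]
        if du >= ell:
            continue
        for p in range(indptr[u], indptr[u + 1]):
            v = indices[p]
            if present[v] and mark[v] != s:
                mark[v] = s
                dist[v] = du + 1
                queue[tail] = v
                tail += 1
                if du + 1 == ell:
                    acc += degree[v] - 1.0
    return (degree[src] - 1.0) * acc


@njit(cache=True)
def _ball_kernel(indptr, indices, present, src, radius,
                 mark, dist, queue, stamp):  # pragma: no cover - jitted
    """BFS up to ``radius``; returns the number of visited nodes (in queue)."""
    stamp[0] += 1
    s = stamp[0]
    mark[src] = s
    dist[src] = 0
    queue[0] = src
    head, tail = 0, 1
    while head < tail:
        u = queue[head]
        head += 1
        du = dist[u]
        if du >= radius:
            continue
        for p in range(indptr[u], indptr[u + 1]):
            v = indices[p]
            if present[v] and mark[v] != s:
                mark[v] = s
                dist[v] = du + 1
                queue[tail] = v
                tail += 1
    return tail


@njit(cache=True)
def _all_ci_kernel(indptr, indices, present, degree, ell):  # pragma: no cover
    n = present.size
    mark = np.zeros(n, np.int64)
    dist = np.zeros(n, np.int64)
    queue = np.empty(n, np.int64)
    stamp = np.zeros(1, np.int64)
    ci = np.zeros(n, np.float64)
    for i in range(n):
        if present[i]:
            ci[i] = _ci_value_kernel(indptr, indices, present, degree, i, ell,
                                     mark, dist, queue, stamp)
    return ci


@njit(cache=True)
def _remove_and_update_kernel(indptr, indices, present, degree, removed, ell,
                              ci, hscores, hnodes, hpos, hsize, det, recompute_all,
                              markA, distA, queueA, markB, distB, queueB,
                              stamp):  # pragma: no cover - jitted
    """Mask out ``removed`` and refresh the CI of every perturbed node.

    Distances for the update set are measured in the graph just before the
    removal.  Returns the net change of the total CI sum (excluding the
    removed node's own score, which the caller subtracts at pop time).
    """
    # BFS of depth l+1 from the removed node, pre-removal state
    stamp[0] += 1
    sA = stamp[0]
    markA[removed] = sA
    distA[removed] = 0
    queueA[0] = removed
    head, tail = 0, 1
    while head < tail:
        u = queueA[head]
        head += 1
        du = distA[u]
        if du >= ell + 1:
            continue
        for p in range(indptr[u], indptr[u + 1]):
            v = indices[p]
            if present[v] and markA[v] != sA:
                markA[v] = sA
                distA[v] = du + 1
                queueA[tail] = v
                tail += 1
    nball = tail

    present[removed] = False
    degree[removed] = 0
    for p in range(indptr[removed], indptr[removed + 1]):
        v = indices[p]
        if present[v]:
            degree[v] -= 1

    delta = 0.0
    inner_limit = ell + 1 if recompute_all else ell
    for idx in range(1, nball):
        u = queueA[idx]
        if present[u] and distA[u] <= inner_limit:
            new = _ci_value_kernel(indptr, indices, present, degree, u, ell,
                                   markB, distB, queueB, stamp)
            d = new - ci[u]
            if d != 0.0:
                ci[u] = new
                delta += d
                if hpos[u] >= 0:
                    _update(hscores, hnodes, hpos, hsize, u, new, det)

    if not recompute_all:
        # Outer layer (distance exactly l+1): node j loses (k_j - 1) for each
        # neighbor m of the removed node that lies on j's l-frontier.  Found
        # by a depth-l BFS from each m in the post-removal graph.
        for p in range(indptr[removed], indptr[removed + 1]):
            m = indices[p]
            if not present[m]:
                continue
            stamp[0] += 1
            sB = stamp[0]
            markB[m] = sB
            distB[m] = 0
            queueB[0] = m
            head, tail = 0, 1
            while head < tail:
                u = queueB[head]
                head += 1
                du = distB[u]
                if du >= ell:
                    continue
                for p2 in range(indptr[u], indptr[u + 1]):
                    v = indices[p2]
                    if present[v] and markB[v] != sB:
                        markB[v] = sB
                        distB[v] = du + 1
                        queueB[tail] = v
                        tail += 1
                        if du + 1 == ell and markA[v] == sA and distA[v] == ell + 1:
                            dec = degree[v] - 1.0
                            if dec > 0.0:
                                ci[v] -= dec
                                delta -= dec
                                if hpos[v] >= 0:
                                    _update(hscores, hnodes, hpos, hsize, v, ci[v], det)
    return delta


@njit(cache=True)
def _ci_attack_kernel(indptr, indices, present, degree, ell, det, recompute_all,
                      stop_lambda, fixed_q, grid_every,
                      n0):  # pragma: no cover - jitted
    n = present.size
    markA = np.zeros(n, np.int64)
    distA = np.zeros(n, np.int64)
    queueA = np.empty(n, np.int64)
    markB = np.zeros(n, np.int64)
    distB = np.zeros(n, np.int64)
    queueB = np.empty(n, np.int64)
    stamp = np.zeros(1, np.int64)

    ci = _all_ci_kernel(indptr, indices, present, degree, ell)
    ci_sum = 0.0
    hscores = np.empty(n, np.float64)
    hnodes = np.empty(n, np.int64)
    hpos = np.full(n, -1, np.int64)
    hsize = 0
    for i in range(n):
        if present[i]:
            hscores[hsize] = ci[i]
            hnodes[hsize] = i
            hpos[i] = hsize
            hsize += 1
            ci_sum += ci[i]
    _build(hscores, hnodes, hpos, hsize, det)

    order = np.empty(n, np.int64)
    lam_tr = np.empty(n, np.float64)
    giant_tr = np.full(n, np.nan)
    second_tr = np.full(n, np.nan)

    expo = 1.0 / (ell + 1.0)
    # live N<k> = sum of degrees of present nodes = 2 x live edge count;
    # maintained incrementally so lambda tracks the remnant's kappa - 1
    denom = 0.0
    for i in range(n):
        if present[i]:
            denom += degree[i]
    lam0 = 0.0 if (denom <= 0.0 or ci_sum <= 0.0) else (ci_sum / denom) ** expo
    t = 0
    stop_reason = 0  # 1 lambda<=1, 2 fixed fraction reached, 3 exhausted
    if stop_lambda and lam0 <= 1.0:
        stop_reason = 1
    else:
        while hsize > 0:
            node, _, hsize = _pop(hscores, hnodes, hpos, hsize, det)
            ci_sum -= ci[node]
            ci[node] = 0.0
            denom -= 2.0 * degree[node]
            delta = _remove_and_update_kernel(
                indptr, indices, present, degree, node, ell, ci,
                hscores, hnodes, hpos, hsize, det, recompute_all,
                markA, distA, queueA, markB, distB, queueB, stamp)
            ci_sum += delta
            if ci_sum < 0.0:
                ci_sum = 0.0
            order[t] = node
            lam = 0.0 if (denom <= 0.0 or ci_sum <= 0.0) else (ci_sum / denom) ** expo
            lam_tr[t] = lam
            t += 1
            if t % grid_every == 0:
                g, s, _ = _components_kernel(indptr, indices, present)
                giant_tr[t - 1] = g / n0
                second_tr[t - 1] = s
            if stop_lambda and lam <= 1.0:
                stop_reason = 1
                break
            if (not stop_lambda) and t >= fixed_q * n0:
                stop_reason = 2
                break
        if stop_reason == 0:
            stop_reason = 3
    if t > 0 and np.isnan(giant_tr[t - 1]):
        g, s, _ = _components_kernel(indptr, indices, present)
        giant_tr[t - 1] = g / n0
        second_tr[t - 1] = s
    return order[:t], lam_tr[:t], giant_tr[:t], second_tr[:t], stop_reason, lam0


@njit(cache=True)
def _hda_kernel(indptr, indices, present, degree, det, grid_every, n0,
                giant_thresh, use_giant_stop, fixed_q):  # pragma: no cover
    n = present.size
    hscores = np.empty(n, np.float64)
    hnodes = np.empty(n, np.int64)
    hpos = np.full(n, -1, np.int64)
    hsize = 0
    for i in range(n):
        if present[i]:
            hscores[hsize] = degree[i]
            hnodes[hsize] = i
            hpos[i] = hsize
            hsize += 1
    _build(hscores, hnodes, hpos, hsize, det)

    order = np.empty(n, np.int64)
    giant_tr = np.full(n, np.nan)
    second_tr = np.full(n, np.nan)
    g, s, _ = _components_kernel(indptr, indices, present)
    t = 0
    stop_reason = 0
    if use_giant_stop and g <= giant_thresh:
        stop_reason = 1
    else:
        while hsize > 0:
            node, _, hsize = _pop(hscores, hnodes, hpos, hsize, det)
            present[node] = False
            degree[node] = 0
            for p in range(indptr[node], indptr[node + 1]):
                v = indices[p]
                if present[v]:
                    degree[v] -= 1
                    if hpos[v] >= 0:
                        _update(hscores, hnodes, hpos, hsize, v, float(degree[v]), det)
            order[t] = node
            t += 1
            if t % grid_every == 0 or hsize == 0:
                g, s, _ = _components_kernel(indptr, indices, present)
                giant_tr[t - 1] = g / n0
                second_tr[t - 1] = s
                if use_giant_stop and g <= giant_thresh:
                    stop_reason = 1
                    break
            if (not use_giant_stop) and t >= fixed_q * n0:
                stop_reason = 2
                break
        if stop_reason == 0:
            stop_reason = 3
    if t > 0 and np.isnan(giant_tr[t - 1]):
        g, s, _ = _components_kernel(indptr, indices, present)
        giant_tr[t - 1] = g / n0
        second_tr[t - 1] = s
    return order[:t], giant_tr[:t], second_tr[:t], stop_reason


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_STOP_REASONS = {1: "lambda<=1", 2: "fixed_fraction", 3: "exhausted"}


@dataclass
class CIConfig:
    """Configuration of the CI attack.

    Parameters
    ----------
    ell : int
        Ball radius l >= 1 of the CI score (l = 0 is the HDA baseline and is
        a separate algorithm).
    stop_rule : str
        ``"lambda_leq_one"`` stops at the first step with lambda(l;q) <= 1;
        ``"fixed_fraction"`` removes until q reaches ``fixed_q``.
    fixed_q : float
        Removal budget for the fixed-fraction rule, in [0, 1].
    deterministic_ties : bool
        Break equal scores by smallest node id (reproducible pop order).
    exact_update : bool
        Recompute every node in B(i, l+1) by BFS instead of using the
        outer-layer decrement (validation mode; the default update is already
        exact, this is a cross-check).
    grid_every : int or None
        Measure components every this many removals (default max(1, N/1000)).
    seed : int
        Reserved for randomized tie-breaking variants; the default attack is
        deterministic given the graph.
    """

    ell: int = 3
    stop_rule: str = "lambda_leq_one"
    fixed_q: float = 1.0
    deterministic_ties: bool = False
    exact_update: bool = False
    grid_every: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.ell < 1:
            raise GraphError("CI requires ell >= 1 (use hda_attack for the l=0 limit)")
        if not 0.0 <= self.fixed_q <= 1.0:
            raise GraphError("fixed_q must be in [0, 1]")
        if self.stop_rule not in ("lambda_leq_one", "fixed_fraction"):
            raise GraphError(f"unknown stop_rule {self.stop_rule!r}")


def _check_present(graph: Graph, i: int) -> None:
    if not graph.present[i]:
        raise GraphError(f"node {i} has been removed")


def frontier(graph: Graph, i: int, ell: int) -> np.ndarray:
    """Nodes at shortest-path distance exactly ``ell`` from ``i``."""
    _check_present(graph, i)
    n = graph.n_nodes
    mark = np.zeros(n, np.int64)
    dist = np.zeros(n, np.int64)
    queue = np.empty(n, np.int64)
    stamp = np.zeros(1, np.int64)
    tail = _ball_kernel(graph.indptr, graph.indices, graph.present, i, ell,
                        mark, dist, queue, stamp)
    visited = queue[:tail]
    return np.sort(visited[dist[visited] == ell])


def ci_value(graph: Graph, i: int, ell: int) -> float:
    """CI_l(i) from the current live degrees."""
    _check_present(graph, i)
    if ell < 1:
        raise GraphError("ell must be >= 1")
    n = graph.n_nodes
    mark = np.zeros(n, np.int64)
    dist = np.zeros(n, np.int64)
    queue = np.empty(n, np.int64)
    stamp = np.zeros(1, np.int64)
    return float(_ci_value_kernel(graph.indptr, graph.indices, graph.present,
                                  graph.degree, i, ell, mark, dist, queue, stamp))


def compute_all_ci(graph: Graph, ell: int) -> np.ndarray:
    """CI_l for every present node (removed nodes get 0)."""
    if ell < 1:
        raise GraphError("ell must be >= 1")
    return _all_ci_kernel(graph.indptr, graph.indices, graph.present,
                          graph.degree, ell)


def lambda_monitor(ci_sum: float, n: int, mean_k: float, ell: int) -> float:
    """lambda(l; q) = [ci_sum / (N <k>)]^(1/(l+1)).

    ``n * mean_k`` is the live N <k> (twice the live edge count), so lambda
    estimates the remnant's kappa - 1 and crosses 1 when the giant component
    is destroyed.  At q = 0 it equals kappa - 1 on tree-like random graphs
    (exactly 2 on a random 3-regular graph at l = 1).
    """
    if ci_sum <= 0 or n <= 0 or mean_k <= 0:
        return 0.0
    return float((ci_sum / (n * mean_k)) ** (1.0 / (ell + 1.0)))


def remove_and_update(graph: Graph, heap: IndexedMaxHeap, node: int, ell: int,
                      ci: np.ndarray, exact_update: bool = False) -> float:
    """Remove ``node`` and refresh CI of every perturbed node (heap kept valid).

    ``ci`` is updated in place; the return value is the net change of the
    total CI sum over the surviving nodes.  Only nodes within distance l+1 of
    the removed node (measured before the removal) are touched.
    """
    _check_present(graph, node)
    n = graph.n_nodes
    markA = np.zeros(n, np.int64)
    distA = np.zeros(n, np.int64)
    queueA = np.empty(n, np.int64)
    markB = np.zeros(n, np.int64)
    distB = np.zeros(n, np.int64)
    queueB = np.empty(n, np.int64)
    stamp = np.zeros(1, np.int64)
    delta = _remove_and_update_kernel(
        graph.indptr, graph.indices, graph.present, graph.degree, node, ell,
        ci, heap._scores, heap._nodes, heap._pos, heap._size,
        heap.deterministic_ties, exact_update,
        markA, distA, queueA, markB, distB, queueB, stamp)
    return float(delta)


def ci_attack(graph: Graph, config: CIConfig | None = None, **kwargs) -> AttackTrace:
    """Run the adaptive CI attack; the graph is mutated to the attacked state.

    Returns an :class:`AttackTrace` with the removal order and the q, G(q),
    second-cluster and lambda traces.  ``qc_estimate`` is the removed
    fraction at the first step where lambda(l; q) <= 1.
    """
    if config is None:
        config = CIConfig(**kwargs)
    n0 = graph.n_nodes
    grid = config.grid_every or max(1, n0 // 1000)
    stop_lambda = config.stop_rule == "lambda_leq_one"
    order, lam_tr, giant_tr, second_tr, stop, lam0 = _ci_attack_kernel(
        graph.indptr, graph.indices, graph.present, graph.degree,
        config.ell, config.deterministic_ties, config.exact_update,
        stop_lambda, config.fixed_q, grid, n0)
    t = order.size
    q = (np.arange(t) + 1.0) / n0
    if stop_lambda:
        qc = float(q[-1]) if t else 0.0
    else:
        hit = np.flatnonzero(lam_tr <= 1.0)
        qc = float(q[hit[0]]) if hit.size else math.nan
    return AttackTrace(
        n0=n0, removal_order=order, q=q, giant=giant_tr, second=second_tr,
        lam=lam_tr, qc_estimate=qc, stop_reason=_STOP_REASONS[int(stop)],
        meta={"method": "ci", "ell": config.ell, "lambda0": float(lam0)})


def hda_attack(graph: Graph, deterministic_ties: bool = False,
               grid_every: int | None = None, giant_threshold: float | None = None,
               stop_rule: str = "giant_zero", fixed_q: float = 1.0) -> AttackTrace:
    """High-degree-adaptive attack (the l = 0 limit of CI).

    Removes the current highest-degree node with the same heap machinery;
    stops when the giant component is destroyed (residual giant at most
    ``giant_threshold`` nodes, default 2 ln N, checked on a thinned grid).
    """
    n0 = graph.n_nodes
    grid = grid_every or max(1, n0 // 1000)
    if giant_threshold is None:
        giant_threshold = max(1.0, 2.0 * math.log(n0))
    use_giant = stop_rule == "giant_zero"
    order, giant_tr, second_tr, stop = _hda_kernel(
        graph.indptr, graph.indices, graph.present, graph.degree,
        deterministic_ties, grid, n0, giant_threshold, use_giant, fixed_q)
    t = order.size
    q = (np.arange(t) + 1.0) / n0
    qc = float(q[-1]) if (t and use_giant and stop == 1) else (0.0 if use_giant else math.nan)
    return AttackTrace(
        n0=n0, removal_order=order, q=q, giant=giant_tr, second=second_tr,
        lam=np.full(t, np.nan), qc_estimate=qc, stop_reason=_STOP_REASONS[int(stop)],
        meta={"method": "hda", "giant_threshold": float(giant_threshold)})


def reference_ci_attack(graph: Graph, ell: int, stop_rule: str = "lambda_leq_one",
                        fixed_q: float = 1.0) -> list[int]:
    """Naive O(N^2) reference: recompute every CI each step, remove the argmax.

    Ties broken by smallest node id.  Works on a copy of the graph.  The
    oracle for heap-attack equivalence on small instances.
    """
    g = graph.copy()
    n0 = g.n_nodes
    order: list[int] = []
    while g.n_present > 0:
        ci = compute_all_ci(g, ell)
        live_ksum = float(g.degree[g.present].sum())
        lam = lambda_monitor(float(ci.sum()), 1, live_ksum, ell)
        if stop_rule == "lambda_leq_one" and lam <= 1.0:
            break
        if stop_rule == "fixed_fraction" and len(order) >= fixed_q * n0:
            break
        ci[~g.present] = -np.inf
        best = int(np.argmax(ci))  # np.argmax returns the smallest index on ties
        g.remove_node(best)
        order.append(best)
    return order
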