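"""Collective immunization: SIR cavity equations + BP energy minimization.

The SIR epidemic with transmission probability beta and initial seed density
gamma is solved on a locally tree-like network by cavity messages:
nu_{i->j}, the probability that i ends up susceptible when j is absent,
satisfies

    nu_{i->j} = (1 - gamma) * prod_{k in di \\ j} [1 - beta n_k (1 - nu_{k->i})]

where n_k in {0, 1} marks whether k is present (n=1) or immunized (n=0) —
an immunized neighbor cannot transmit and contributes a factor 1.  The node
marginal nu_i takes the product over the full neighborhood.

Choosing the immunized set means minimizing the energy

    E(n) = sum_i n_i (1 - nu_i)  +  mu * sum_i (1 - n_i)

(expected outbreak size plus a chemical potential mu per immunized node;
mu tunes the immunized fraction q).  With the cavity messages frozen, E is a
sum of local factors a_i(n_i, n_di) on the network, and its minimum is found
by min-sum message passing: scalar fields h (log-likelihood-ratio style,
cost of keeping minus cost of removing) travel along edges, the node field
h_i collects the incoming messages plus the mu term, and the spin

    sigma_i = sign(h_i)     (+1 removed/immunized, -1 present; sign(0) = -1)

decides the configuration.  The full loop alternates: converge nu given n,
converge the h messages given nu, update sigma, repeat until the fields are
stable.  When the h iteration oscillates (loopy graphs), a reinforcement
self-field that integrates the running marginal forces convergence.

Optimal percolation is the limit gamma = 1/N -> 0, beta -> 1: the minimal
immunized set that destroys the giant component.  In that limit the cavity
probability reduces to a function of the cavity *cluster size*, and the
energy is minimized by a dedicated size-resolved min-sum solver
(:func:`percolation_solve`; see the section comment below) — the scalar
frozen-nu scheme degenerates there.  A bisection on mu
(:func:`percolation_immunize`) finds the smallest immunized fraction whose
residual giant component is sub-extensive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .graph_core import Graph, GraphError
from .ci_prop import DirectedEdgeIndex

__all__ = [
    "SIRParams",
    "BPState",
    "update_nu",
    "marginal_nu",
    "energy",
    "update_h",
    "config_energy",
    "cibp_solve",
    "percolation_immunize",
    "BPResult",
    "ImmunizationResult",
]

_ENUM_CAP = 14  # exact subset enumeration up to this many cavity neighbors


@dataclass
class SIRParams:
    """SIR + immunization parameters.

    gamma : initial infection probability per node (percolation mode: 1/N).
    beta : transmission probability (percolation mode: 1 - 1e-12, nudged off
        1 only to avoid degenerate patterns; the cavity products are exact).
    mu : chemical potential, the energy cost per immunized node.
    reinforce_rate : growth rate of the convergence-forcing self-field.
    damping : damping factor in [0, 1) for both message iterations.
    """

    gamma: float = 0.1
    beta: float = 1.0
    mu: float = 0.1
    reinforce_rate: float = 1e-3
    damping: float = 0.5
    tol_nu: float = 1e-8
    tol_h: float = 1e-6
    max_sweeps: int = 2000

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise GraphError("gamma must be in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise GraphError("beta must be in [0, 1]")
        if not 0.0 <= self.damping < 1.0:
            raise GraphError("damping must be in [0, 1)")
        if self.reinforce_rate < 0:
            raise GraphError("reinforce_rate must be >= 0")


@dataclass
class BPState:
    """Cavity probabilities, min-sum fields and the spin configuration."""

    nu: np.ndarray               # nu_{i->j} per directed edge
    nu_node: np.ndarray          # marginal nu_i
    h_edge: np.ndarray           # min-sum message from factor a_i to variable j
    h_self: np.ndarray           # message from factor a_i to its own variable
    h_node: np.ndarray           # assembled node field (keep-minus-remove cost)
    sigma: np.ndarray            # +1 removed/immunized, -1 present
    rf: np.ndarray               # reinforcement self-field
    nu_converged: bool = False
    h_converged: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_occ(self) -> np.ndarray:
        """Occupation numbers: n_i = 1 iff present (sigma = -1)."""
        return (self.sigma < 0).astype(np.float64)

    @classmethod
    def random_init(cls, index: DirectedEdgeIndex, rng: np.random.Generator) -> "BPState":
        n = index.graph.n_nodes
        m2 = index.n_edges
        sigma = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
        return cls(
            nu=np.full(m2, 1.0),
            nu_node=np.ones(n),
            h_edge=rng.uniform(-0.1, 0.1, size=m2),
            h_self=rng.uniform(-0.1, 0.1, size=n),
            h_node=np.zeros(n),
            sigma=sigma,
            rf=np.zeros(n),
        )


# ---------------------------------------------------------------------------
# cavity (nu) iteration
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nu_sweep(indptr, indices, rev, nocc, nu, nu_new, gamma, beta,
              damping):  # pragma: no cover - jitted
    n = indptr.size - 1
    maxdiff = 0.0
    for i in range(n):
        for p in range(indptr[i], indptr[i + 1]):
            acc = 1.0
            for p2 in range(indptr[i], indptr[i + 1]):
                if p2 == p:
                    continue
                k = indices[p2]
                acc *= 1.0 - beta * nocc[k] * (1.0 - nu[rev[p2]])
            val = (1.0 - gamma) * acc
            new = damping * nu[p] + (1.0 - damping) * val
            d = abs(new - nu[p])
            if d > maxdiff:
                maxdiff = d
            nu_new[p] = new
    return maxdiff


@njit(cache=True)
def _nu_marginal(indptr, indices, rev, nocc, nu, gamma, beta,
                 out):  # pragma: no cover - jitted
    n = indptr.size - 1
    for i in range(n):
        acc = 1.0
        for p in range(indptr[i], indptr[i + 1]):
            k = indices[p]
            acc *= 1.0 - beta * nocc[k] * (1.0 - nu[rev[p]])
        out[i] = (1.0 - gamma) * acc


def update_nu(index: DirectedEdgeIndex, state: BPState, params: SIRParams,
              n_occ: np.ndarray | None = None) -> BPState:
    """Iterate the cavity messages to their fixed point for a fixed n.

    The damped update is a convex combination of values in [0, 1], so nu
    stays in [0, 1] without clipping.  Non-convergence at ``max_sweeps`` is
    flagged and the last iterate returned.
    """
    g = index.graph
    nocc = state.n_occ if n_occ is None else np.asarray(n_occ, dtype=np.float64)
    nu_new = np.empty_like(state.nu)
    converged = False
    for _ in range(params.max_sweeps):
        diff = _nu_sweep(g.indptr, g.indices, index.rev, nocc, state.nu, nu_new,
                         params.gamma, params.beta, params.damping)
        state.nu, nu_new = nu_new, state.nu
        if diff < params.tol_nu:
            converged = True
            break
    _nu_marginal(g.indptr, g.indices, index.rev, nocc, state.nu,
                 params.gamma, params.beta, state.nu_node)
    state.nu_converged = converged
    return state


def marginal_nu(index: DirectedEdgeIndex, state: BPState, params: SIRParams) -> np.ndarray:
    """Marginal probability that each node ends susceptible (Bethe estimate)."""
    out = np.empty(index.graph.n_nodes)
    _nu_marginal(index.graph.indptr, index.graph.indices, index.rev,
                 state.n_occ, state.nu, params.gamma, params.beta, out)
    return out


def energy(graph: Graph, state: BPState, params: SIRParams,
           n_occ: np.ndarray | None = None) -> float:
    """E(n) = sum_i n_i (1 - nu_i) + mu sum_i (1 - n_i); nu must be converged."""
    nocc = state.n_occ if n_occ is None else np.asarray(n_occ, dtype=np.float64)
    outbreak = float(np.sum(nocc * (1.0 - state.nu_node)))
    cost = params.mu * float(np.sum(1.0 - nocc))
    return outbreak + cost


# ---------------------------------------------------------------------------
# min-sum (h) iteration
# ---------------------------------------------------------------------------

@njit(cache=True)
def _subset_min(vv, cc, deg, coef):  # pragma: no cover - jitted
    """min over subsets S of sum_{k in S} v_k - coef * prod_{k in S} c_k.

    Exact enumeration up to _ENUM_CAP elements, otherwise the best of three
    candidate subsets (empty, all, negatives) — an upper bound used only for
    very high-degree nodes.
    """
    if deg == 0:
        return -coef
    if deg <= _ENUM_CAP:
        best = 1e300
        for s in range(1 << deg):
            tot = 0.0
            prod = 1.0
            for k in range(deg):
                if s & (1 << k):
                    tot += vv[k]
                    prod *= cc[k]
            val = tot - coef * prod
            if val < best:
                best = val
        return best
    tot_neg = 0.0
    prod_neg = 1.0
    tot_all = 0.0
    prod_all = 1.0
    for k in range(deg):
        tot_all += vv[k]
        prod_all *= cc[k]
        if vv[k] < 0.0:
            tot_neg += vv[k]
            prod_neg *= cc[k]
    best = -coef  # empty subset
    v1 = tot_neg - coef * prod_neg
    v2 = tot_all - coef * prod_all
    if v1 < best:
        best = v1
    if v2 < best:
        best = v2
    return best


@njit(cache=True)
def _h_sweep(indptr, indices, rev, nu, eta, eta_self, eta_new, eta_self_new,
             insum, rf, gamma, beta, mu, damping,
             vv, cc, vv2, cc2):  # pragma: no cover - jitted
    """One damped min-sum sweep; returns the max message change.

    ``insum[i]`` must hold sum of incoming factor messages eta_{k->i}.
    ``vv, cc, vv2, cc2`` are scratch arrays of length >= max degree.
    """
    n = indptr.size - 1
    maxdiff = 0.0
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        deg = hi - lo
        # cavity fields of the neighbors toward factor a_i, and the cavity
        # transmission factors c_k = 1 - beta (1 - nu_{k->i})
        for t in range(deg):
            p = lo + t
            k = indices[p]
            vv[t] = eta_self[k] + insum[k] - eta[p] + rf[k]
            cc[t] = 1.0 - beta * (1.0 - nu[rev[p]])
        v_i = insum[i] + rf[i]

        sum_min0 = 0.0
        for t in range(deg):
            if vv[t] < 0.0:
                sum_min0 += vv[t]

        # message to each neighbor j
        for t in range(deg):
            p = lo + t
            noth = 0
            for t2 in range(deg):
                if t2 != t:
                    vv2[noth] = vv[t2]
                    cc2[noth] = cc[t2]
                    noth += 1
            branch0 = mu + sum_min0 - (vv[t] if vv[t] < 0.0 else 0.0)
            f1 = _subset_min(vv2, cc2, noth, (1.0 - gamma) * cc[t])
            f0 = _subset_min(vv2, cc2, noth, (1.0 - gamma))
            m1 = min(branch0, v_i + 1.0 + f1)
            m0 = min(branch0, v_i + 1.0 + f0)
            new = damping * eta[p] + (1.0 - damping) * (m1 - m0)
            d = abs(new - eta[p])
            if d > maxdiff:
                maxdiff = d
            eta_new[p] = new

        # message of factor a_i to its own variable
        m0s = mu + sum_min0
        m1s = 1.0 + _subset_min(vv, cc, deg, 1.0 - gamma)
        new = damping * eta_self[i] + (1.0 - damping) * (m1s - m0s)
        d = abs(new - eta_self[i])
        if d > maxdiff:
            maxdiff = d
        eta_self_new[i] = new
    return maxdiff


@njit(cache=True)
def _insum(indptr, rev, eta, out):  # pragma: no cover - jitted
    n = indptr.size - 1
    for i in range(n):
        acc = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            acc += eta[rev[p]]
        out[i] = acc


def _assemble_h(index: DirectedEdgeIndex, state: BPState) -> None:
    insum = np.empty(index.graph.n_nodes)
    _insum(index.graph.indptr, index.rev, state.h_edge, insum)
    state.h_node = state.h_self + insum


def update_h(index: DirectedEdgeIndex, state: BPState, params: SIRParams,
             reinforce: bool = False) -> bool:
    """Iterate the min-sum field messages for the current nu to convergence.

    With ``reinforce`` the self-field integrates the running node marginal
    (rf += rate * h_node each sweep), which polarizes the fields and forces
    convergence on instances where plain min-sum oscillates.  Returns the
    convergence flag; ``state.h_node`` and messages are updated in place.
    """
    g = index.graph
    n = g.n_nodes
    maxdeg = int(np.diff(g.indptr).max()) if n else 0
    vv = np.empty(maxdeg + 1)
    cc = np.empty(maxdeg + 1)
    vv2 = np.empty(maxdeg + 1)
    cc2 = np.empty(maxdeg + 1)
    eta_new = np.empty_like(state.h_edge)
    eself_new = np.empty_like(state.h_self)
    insum = np.empty(n)
    converged = False
    for _ in range(params.max_sweeps):
        _insum(g.indptr, index.rev, state.h_edge, insum)
        diff = _h_sweep(g.indptr, g.indices, index.rev, state.nu,
                        state.h_edge, state.h_self, eta_new, eself_new,
                        insum, state.rf, params.gamma, params.beta, params.mu,
                        params.damping, vv, cc, vv2, cc2)
        state.h_edge, eta_new = eta_new, state.h_edge
        state.h_self, eself_new = eself_new, state.h_self
        if reinforce and params.reinforce_rate > 0:
            _assemble_h(index, state)
            state.rf += params.reinforce_rate * state.h_node
        if diff < params.tol_h:
            converged = True
            break
    _assemble_h(index, state)
    state.h_converged = converged
    return converged


# ---------------------------------------------------------------------------
# full solver
# ---------------------------------------------------------------------------

@dataclass
class BPResult:
    """Output of one CI_BP solve at fixed parameters."""

    n_occ: np.ndarray            # 1 = present, 0 = immunized
    sigma: np.ndarray
    h_node: np.ndarray
    energy: float
    outbreak: float
    immunized_fraction: float
    converged: bool
    used_reinforcement: bool
    outer_rounds: int


def config_energy(graph: Graph, n_occ: np.ndarray, params: SIRParams,
                  index: DirectedEdgeIndex | None = None) -> float:
    """Energy of a fixed occupation: converge nu from the all-susceptible
    start (nu = 1) and evaluate E(n).  The canonical evaluator used to
    compare candidate immunization sets."""
    index = index or DirectedEdgeIndex(graph)
    nocc = np.asarray(n_occ, dtype=np.float64)
    m2 = index.n_edges
    state = BPState(nu=np.ones(m2), nu_node=np.ones(graph.n_nodes),
                    h_edge=np.zeros(m2), h_self=np.zeros(graph.n_nodes),
                    h_node=np.zeros(graph.n_nodes),
                    sigma=np.where(nocc > 0.5, -1, 1).astype(np.int8),
                    rf=np.zeros(graph.n_nodes))
    update_nu(index, state, params, n_occ=nocc)
    return energy(graph, state, params, n_occ=nocc)


def cibp_solve(graph: Graph, params: SIRParams, seed: int = 0,
               max_outer: int = 30, n_restarts: int = 3,
               index: DirectedEdgeIndex | None = None) -> BPResult:
    """Run the full CI_BP loop and return the immunization decision.

    The loop: random init of sigma and the fields; iterate nu to convergence
    for the current occupation; iterate the h messages to convergence
    (falling back to reinforcement if they oscillate); update the node
    fields and spins; repeat until the spin configuration is stable.
    ``n_restarts`` independent random initializations are run and the
    configuration of lowest energy kept (min-sum on loopy graphs can settle
    in different fixed points).
    """
    best: BPResult | None = None
    index = index or DirectedEdgeIndex(graph)
    for r in range(max(1, n_restarts)):
        res = _cibp_solve_once(graph, params, int(np.random.default_rng([seed, r]).integers(2 ** 31)),
                               max_outer, index)
        if best is None or res.energy < best.energy:
            best = res
    return best


def _cibp_solve_once(graph: Graph, params: SIRParams, seed: int,
                     max_outer: int, index: DirectedEdgeIndex) -> BPResult:
    if graph.n_present != graph.n_nodes:
        raise GraphError("cibp_solve expects a fully present graph")
    rng = np.random.default_rng(seed)
    state = BPState.random_init(index, rng)
    used_reinforce = False
    outer_converged = False
    rounds = 0
    prev_sigma = state.sigma.copy()
    for rounds in range(1, max_outer + 1):
        update_nu(index, state, params)
        ok = update_h(index, state, params, reinforce=False)
        if not ok:
            used_reinforce = True
            state.rf[:] = 0.0
            ok = update_h(index, state, params, reinforce=True)
        state.sigma = np.where(state.h_node > 0.0, 1, -1).astype(np.int8)
        state.rf[:] = 0.0
        if rounds > 1 and np.array_equal(state.sigma, prev_sigma) and ok:
            outer_converged = True
            break
        prev_sigma = state.sigma.copy()
    # final self-consistent nu and energy for the decided configuration,
    # evaluated with the canonical evaluator so candidates are comparable
    update_nu(index, state, params)
    nocc = state.n_occ
    outbreak = float(np.sum(nocc * (1.0 - state.nu_node)))
    e = config_energy(graph, nocc, params, index=index)
    return BPResult(
        n_occ=nocc, sigma=state.sigma.copy(), h_node=state.h_node.copy(),
        energy=e, outbreak=outbreak,
        immunized_fraction=float(np.mean(nocc == 0.0)),
        converged=outer_converged, used_reinforcement=used_reinforce,
        outer_rounds=rounds)


# ---------------------------------------------------------------------------
# percolation-limit solver: size-resolved min-sum
# ---------------------------------------------------------------------------
#
# In the optimal-percolation limit gamma = 1/N -> 0, beta -> 1, the cavity
# probability collapses to nu_{i->j} = (1 - gamma)^{S_{i->j}}, where S_{i->j}
# is the size of i's cluster when j is absent:
#
#     S_{i->j} = n_i * (1 + sum_{k in di \ j} S_{k->i}).
#
# The energy then groups by cluster, E = sum_clusters f(s) + mu |immunized|
# with f(s) = s (1 - (1-gamma)^s), and its minimum is found by min-sum
# messages that carry the cavity cluster size: m_{i->j}(y) for y in {0..C},
# where y = 0 means i immunized and y >= 1 means i present heading a cavity
# cluster of y nodes.  The cluster cost is paid incrementally at each merge
# (f(1 + sum y_k) - sum f(y_k)), which telescopes to exactly one f(s) per
# cluster on a tree.  Sizes saturate at the cap C; the first time a cluster
# reaches C it pays an extra penalty, so near-optimal configurations keep
# every cluster below the cap — which is how "the giant component vanishes"
# is encoded locally.  Reinforcement (an integrated external field on the
# immunize/keep gap) forces convergence on loopy graphs.

_BIG = 1e30


@njit(cache=True)
def _conv_in(rev, msg, fcost, slope, lo, deg, skip, partial,
             partial2, wbuf, minw):  # pragma: no cover - jitted
    """Saturated min-plus convolution of the incoming transformed messages.

    ``partial[s]`` for s in 0..C-1: best cost with accumulated neighbor
    cluster sizes exactly s; ``partial[C]``: saturated bucket (sizes >= C),
    cost already including ``slope`` per node of excess over C.  ``skip``
    excludes one neighbor slot (the message target), or -1 for none.
    Returns nothing; fills ``partial``.  ``wbuf``/``minw`` must already hold
    the transformed incoming messages (w[0] = m(0), w[y>=1] = m(y) - f(y))
    and their untransformed minima.
    """
    C = fcost.size - 1
    for s in range(C + 1):
        partial[s] = _BIG
    partial[0] = 0.0
    for t2 in range(deg):
        if t2 == skip:
            continue
        for s in range(C + 1):
            partial2[s] = _BIG
        for s in range(C + 1):
            ps = partial[s]
            if ps >= _BIG:
                continue
            for y in range(C + 1):
                w = wbuf[t2, y]
                if w >= _BIG:
                    continue
                if s == C:
                    # already saturated: each added node pays the slope
                    v = ps + w + slope * y
                    if v < partial2[C]:
                        partial2[C] = v
                else:
                    s2 = s + y
                    if s2 < C:
                        v = ps + w
                        if v < partial2[s2]:
                            partial2[s2] = v
                    else:
                        v = ps + w + slope * (s2 - C)
                        if v < partial2[C]:
                            partial2[C] = v
        for s in range(C + 1):
            partial[s] = partial2[s]


@njit(cache=True)
def _perc_sweep(indptr, indices, rev, msg, msg_new, fcost, slope, xi, mu,
                damping, wbuf, minw, partial, partial2):  # pragma: no cover
    """One damped sweep of the size-resolved min-sum messages.

    ``msg[e, y]``: message on directed edge e = (i->j); y = 0 immunized,
    y >= 1 present heading a cavity cluster of y nodes (y = C means C or
    more).  ``fcost[y]`` is the cluster cost f(y); beyond the cap the cost
    continues affinely with ``slope`` per node, so extensive clusters keep a
    positive local marginal cost (a saturating cap would make them look
    locally free).  Cluster costs are paid incrementally at each merge,
    which telescopes to one f per cluster on a tree.
    """
    n = indptr.size - 1
    C = fcost.size - 1
    maxdiff = 0.0
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        deg = hi - lo
        # incoming messages, transformed: w'[0] = m(0); w'[y>=1] = m(y) - f(y)
        for t in range(deg):
            e_in = rev[lo + t]
            best = _BIG
            for y in range(C + 1):
                v = msg[e_in, y]
                if v < best:
                    best = v
                wbuf[t, y] = v if y == 0 else v - fcost[y]
            minw[t] = best
        for t in range(deg):
            p = lo + t
            # option y = 0: immunized; neighbor clusters are complete and
            # their costs are already inside the incoming messages
            v0 = mu + xi[i]
            for t2 in range(deg):
                if t2 != t:
                    v0 += minw[t2]
            _conv_in(rev, msg, fcost, slope, lo, deg, t, partial, partial2,
                     wbuf, minw)
            # assemble: total size 1 + (accumulated sizes)
            best = v0
            for y in range(1, C + 1):
                v = partial[y - 1] + fcost[y]
                if y == C and partial[C] + fcost[C] + slope < v:
                    v = partial[C] + fcost[C] + slope
                partial2[y - 1] = v
                if v < best:
                    best = v
            val = damping * msg[p, 0] + (1.0 - damping) * (v0 - best)
            d = abs(val - msg[p, 0])
            if d > maxdiff:
                maxdiff = d
            msg_new[p, 0] = val
            for y in range(1, C + 1):
                newy = partial2[y - 1] - best
                if newy > _BIG:
                    newy = _BIG
                val = damping * msg[p, y] + (1.0 - damping) * newy
                d = abs(val - msg[p, y])
                if d > maxdiff and val < _BIG / 2:
                    maxdiff = d
                msg_new[p, y] = val
    return maxdiff


@njit(cache=True)
def _perc_beliefs(indptr, indices, rev, msg, fcost, slope, xi, mu, gap,
                  wbuf, minw, partial, partial2):  # pragma: no cover - jitted
    """gap[i] = B(present) - B(immunized); negative favors keeping node i."""
    n = indptr.size - 1
    C = fcost.size - 1
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        deg = hi - lo
        for t in range(deg):
            e_in = rev[lo + t]
            best = _BIG
            for y in range(C + 1):
                v = msg[e_in, y]
                if v < best:
                    best = v
                wbuf[t, y] = v if y == 0 else v - fcost[y]
            minw[t] = best
        b0 = mu + xi[i]
        for t in range(deg):
            b0 += minw[t]
        _conv_in(rev, msg, fcost, slope, lo, deg, -1, partial, partial2,
                 wbuf, minw)
        b1 = _BIG
        for y in range(1, C + 1):
            v = partial[y - 1] + fcost[y]
            if v < b1:
                b1 = v
        v = partial[C] + fcost[C] + slope
        if v < b1:
            b1 = v
        gap[i] = b1 - b0


def percolation_solve(graph: Graph, mu: float, gamma: float | None = None,
                      size_cap: int | None = None, cap_penalty: float = 0.0,
                      reinforce_rate: float = 0.02, damping: float = 0.5,
                      max_sweeps: int = 1000, tol: float = 1e-9,
                      stable_sweeps: int = 30, seed: int = 0,
                      index: DirectedEdgeIndex | None = None,
                      warmup: int = 30, field_noise: float | None = None) -> BPResult:
    """Minimize the percolation-limit energy at fixed mu by size-resolved
    min-sum with reinforcement; returns the immunization decision.

    ``field_noise`` sets the amplitude of quenched random node fields that
    seed symmetry breaking on (near-)regular graphs, where the energy has a
    large degeneracy of optimal sets (default: mu / 10).
    """
    n = graph.n_nodes
    if gamma is None:
        gamma = 1.0 / n
    if size_cap is None:
        size_cap = max(24, int(round(4.0 * math.log(n))))
    index = index or DirectedEdgeIndex(graph)
    C = int(size_cap)
    sizes = np.arange(C + 1, dtype=np.float64)
    fcost = sizes * (1.0 - (1.0 - gamma) ** sizes)
    slope = float(fcost[C] - fcost[C - 1])  # marginal cost per node at the cap
    fcost[C] += cap_penalty
    fcost[0] = 0.0

    rng = np.random.default_rng(seed)
    m2 = index.n_edges
    msg = rng.uniform(0.0, max(gamma, 1e-12), size=(m2, C + 1))
    msg_new = msg.copy()
    if field_noise is None:
        field_noise = mu / 10.0
    xi = rng.uniform(-field_noise, field_noise, size=n) if field_noise > 0 else np.zeros(n)
    gap = np.zeros(n)
    maxdeg = int(np.diff(graph.indptr).max()) if n else 0
    wbuf = np.empty((maxdeg + 1, C + 1))
    minw = np.empty(maxdeg + 1)
    partial = np.empty(C + 1)
    partial2 = np.empty(C + 1)

    decision = np.zeros(n, dtype=np.int8)
    stable = 0
    converged = False
    used_reinforce = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        diff = _perc_sweep(graph.indptr, graph.indices, index.rev, msg, msg_new,
                           fcost, slope, xi, mu, damping, wbuf, minw, partial, partial2)
        msg, msg_new = msg_new, msg
        _perc_beliefs(graph.indptr, graph.indices, index.rev, msg, fcost, slope,
                      xi, mu, gap, wbuf, minw, partial, partial2)
        # ties keep the node (sign(0) = keep); the margin makes that robust
        # to float noise at exactly balanced fixed points
        new_decision = (gap > 1e-6).astype(np.int8)  # 1 = immunize
        if np.array_equal(new_decision, decision):
            stable += 1
        else:
            stable = 0
        decision = new_decision
        if sweeps > warmup and reinforce_rate > 0:
            used_reinforce = True
            xi -= reinforce_rate * np.clip(gap, -1.0, 1.0)
        # size information needs ~C sweeps to propagate; only then can the
        # decision vector be trusted as stable
        if sweeps >= 2 * C and (stable >= stable_sweeps or diff < tol):
            converged = True
            break
    nocc = (decision == 0).astype(np.float64)
    sigma = np.where(decision == 1, 1, -1).astype(np.int8)
    return BPResult(
        n_occ=nocc, sigma=sigma, h_node=gap.copy(),
        energy=math.nan, outbreak=math.nan,
        immunized_fraction=float(np.mean(decision == 1)),
        converged=converged, used_reinforcement=used_reinforce,
        outer_rounds=sweeps)


@njit(cache=True)
def _trim_kernel(indptr, indices, keep, parent, size,
                 threshold):  # pragma: no cover - jitted
    """Reverse-greedy: reinsert immunized nodes whose merged cluster would
    stay within ``threshold``, smallest merged size first.  Returns the
    number reinserted; ``keep``/``parent``/``size`` updated in place."""
    n = keep.size
    # union-find over the kept nodes
    for i in range(n):
        parent[i] = i
        size[i] = 1
    for a in range(n):
        if keep[a]:
            for p in range(indptr[a], indptr[a + 1]):
                b = indices[p]
                if keep[b] and b < a:
                    ra = a
                    while parent[ra] != ra:
                        ra = parent[ra]
                    rb = b
                    while parent[rb] != rb:
                        rb = parent[rb]
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
    nback = 0
    roots = np.empty(64, np.int64)
    changed = True
    while changed:
        changed = False
        # pick the immunized node with the smallest feasible merged size
        best_merged = threshold + 1
        best_i = -1
        for i in range(n):
            if keep[i]:
                continue
            nr = 0
            merged = 1
            for p in range(indptr[i], indptr[i + 1]):
                b = indices[p]
                if keep[b]:
                    r = b
                    while parent[r] != r:
                        r = parent[r]
                    dup = False
                    for t in range(nr):
                        if roots[t] == r:
                            dup = True
                            break
                    if not dup:
                        roots[nr] = r
                        nr += 1
                        merged += size[r]
            if merged <= threshold and merged < best_merged:
                best_merged = merged
                best_i = i
        if best_i >= 0:
            i = best_i
            keep[i] = True
            parent[i] = i
            size[i] = 1
            for p in range(indptr[i], indptr[i + 1]):
                b = indices[p]
                if keep[b]:
                    ra = i
                    while parent[ra] != ra:
                        ra = parent[ra]
                    rb = b
                    while parent[rb] != rb:
                        rb = parent[rb]
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
            nback += 1
            changed = True
    return nback


def greedy_trim(graph: Graph, immunized: np.ndarray, threshold: float) -> np.ndarray:
    """Shed redundant immunized nodes: reinsert any whose merged cluster of
    kept neighbors stays within ``threshold`` nodes, smallest first.

    A reverse-greedy polish of the BP decision toward the bisection
    objective (smallest immunized set with sub-threshold clusters); it can
    only reduce the immunized set and never makes the residual giant exceed
    ``threshold``.
    """
    keep = ~np.asarray(immunized, dtype=np.bool_)
    parent = np.empty(graph.n_nodes, np.int64)
    size = np.empty(graph.n_nodes, np.int64)
    _trim_kernel(graph.indptr, graph.indices, keep, parent, size,
                 float(threshold))
    return ~keep


@dataclass
class ImmunizationResult:
    """Best immunization found by the mu bisection."""

    immunized: np.ndarray        # node ids
    q: float                     # immunized fraction
    mu: float
    giant: int                   # residual giant component (node count)
    giant_threshold: float
    history: list = field(default_factory=list)


def percolation_immunize(graph: Graph, seed: int = 0, bisect_steps: int = 20,
                         mu_lo: float = 0.0, mu_hi: float = 1.0,
                         giant_threshold: float | None = None,
                         gamma: float | None = None,
                         max_sweeps: int = 600,
                         reinforce_rate: float = 0.02,
                         damping: float = 0.7,
                         size_cap: int | None = None) -> ImmunizationResult:
    """Optimal-percolation mode: gamma = 1/N, beta -> 1, bisection on mu.

    Finds the smallest immunized fraction whose residual giant component
    (largest cluster of non-immunized nodes) is at most ``giant_threshold``
    (default 2 ln N, sub-extensive).  Feasibility is monotone in mu — small
    mu makes immunization cheap — so a bisection over [mu_lo, mu_hi]
    approaches the largest feasible mu, where the immunized set is minimal.
    Each evaluation runs the size-resolved min-sum solver.
    """
    n = graph.n_nodes
    if giant_threshold is None:
        giant_threshold = 2.0 * math.log(n)
    if gamma is None:
        gamma = 1.0 / n
    index = DirectedEdgeIndex(graph)
    history = []
    best = None

    def evaluate(mu: float, sub: int):
        res = percolation_solve(
            graph, mu, gamma=gamma, size_cap=size_cap,
            reinforce_rate=reinforce_rate, max_sweeps=max_sweeps,
            damping=damping,
            seed=int(np.random.default_rng([seed, sub]).integers(2 ** 31)),
            index=index)
        immunized = res.n_occ < 0.5
        st0 = graph.components_masked(~immunized)
        if st0.giant_size <= giant_threshold:
            # reverse-greedy polish: shed immunized nodes that are not needed
            # to keep every cluster within the threshold
            immunized = greedy_trim(graph, immunized, giant_threshold)
            res.n_occ = (~immunized).astype(np.float64)
            res.immunized_fraction = float(immunized.mean())
        st = graph.components_masked(~immunized)
        feasible = st.giant_size <= giant_threshold
        history.append({"mu": mu, "q": res.immunized_fraction,
                        "giant": st.giant_size, "feasible": feasible,
                        "bp_converged": res.converged,
                        "used_reinforcement": res.used_reinforcement})
        return res, st.giant_size, feasible

    res_lo, giant_lo, feas_lo = evaluate(mu_lo, 0)
    if feas_lo:
        best = (res_lo, mu_lo, giant_lo)
    lo, hi = mu_lo, mu_hi
    res_hi, giant_hi, feas_hi = evaluate(mu_hi, 1)
    if feas_hi and (best is None or res_hi.immunized_fraction < best[0].immunized_fraction):
        best = (res_hi, mu_hi, giant_hi)
    for step in range(bisect_steps):
        mid = 0.5 * (lo + hi)
        res, giant, feasible = evaluate(mid, 2 + step)
        if feasible:
            lo = mid
            if best is None or res.immunized_fraction < best[0].immunized_fraction:
                best = (res, mid, giant)
        else:
            hi = mid
    if best is None:
        raise GraphError("no feasible immunization found; widen the mu range")
    res, mu_star, giant = best
    immunized = np.flatnonzero(res.n_occ < 0.5)
    return ImmunizationResult(
        immunized=immunized, q=res.immunized_fraction, mu=mu_star,
        giant=int(giant), giant_threshold=float(giant_threshold),
        history=history)
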