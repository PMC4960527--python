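"""Graph container, random-graph generators, edge-list I/O and component accounting.

The central object is :class:`Graph`: an undirected simple graph stored in
compressed sparse row (CSR) form together with a *presence mask* and live
degrees.  Node removal never deletes adjacency — it flips the mask and
decrements the live degrees of the neighbors — so removed nodes can later be
reinserted with their original edges (the reinsertion refinement needs this).

Generators cover the two graph families used throughout: Erdős–Rényi graphs
with a fixed number of edges ``M = round(n * mean_degree / 2)`` (so the mean
degree is exact, matching how the experiments are parameterized) and random
regular graphs built with the pairing/configuration model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "Graph",
    "ComponentStats",
    "GraphError",
    "EdgeListParseError",
    "generate_er",
    "generate_rrg",
    "read_edgelist",
    "write_edgelist",
    "components",
]


class GraphError(ValueError):
    """Invalid graph parameters or operations."""


class EdgeListParseError(GraphError):
    """Malformed edge-list file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class ComponentStats:
    """Sizes of the largest and second-largest clusters of present nodes."""

    giant_size: int
    second_size: int
    n_components: int


@njit(cache=True)
def _components_kernel(indptr, indices, mask):  # pragma: no cover - jitted
    n = mask.size
    comp = np.full(n, -1, np.int64)
    queue = np.empty(n, np.int64)
    giant = 0
    second = 0
    ncomp = 0
    for s in range(n):
        if mask[s] and comp[s] < 0:
            ncomp += 1
            comp[s] = s
            queue[0] = s
            head, tail = 0, 1
            size = 0
            while head < tail:
                u = queue[head]
                head += 1
                size += 1
                for p in range(indptr[u], indptr[u + 1]):
                    v = indices[p]
                    if mask[v] and comp[v] < 0:
                        comp[v] = s
                        queue[tail] = v
                        tail += 1
            if size > giant:
                second = giant
                giant = size
            elif size > second:
                second = size
    return giant, second, ncomp


class Graph:
    """Undirected simple graph with a presence mask and live degrees.

    Parameters
    ----------
    n_nodes : int
        Number of nodes; ids are dense ``0..n_nodes-1``.
    edges : ndarray of shape (M, 2)
        Undirected edges; validated to be simple (no self-loops/duplicates).
    node_labels : ndarray, optional
        Original integer labels when read from a file (``node_labels[i]`` is
        the external label of internal node ``i``).
    """

    def __init__(self, n_nodes: int, edges: np.ndarray, node_labels: np.ndarray | None = None):
        if n_nodes < 1:
            raise GraphError("graph needs at least one node")
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= n_nodes:
                raise GraphError("edge endpoint out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise GraphError("self-loops are not allowed")
            lo = np.minimum(edges[:, 0], edges[:, 1])
            hi = np.maximum(edges[:, 0], edges[:, 1])
            code = lo * n_nodes + hi
            if np.unique(code).size != code.size:
                raise GraphError("parallel edges are not allowed")
        self.n_nodes = int(n_nodes)
        both = np.concatenate([edges, edges[:, ::-1]]) if edges.size else edges.reshape(0, 2)
        order = np.lexsort((both[:, 1], both[:, 0])) if both.size else np.empty(0, np.int64)
        both = both[order]
        counts = np.bincount(both[:, 0], minlength=n_nodes) if both.size else np.zeros(n_nodes, np.int64)
        self.indptr = np.zeros(n_nodes + 1, dtype=np.int64)
        np.cumsum(counts, out=self.indptr[1:])
        self.indices = np.ascontiguousarray(both[:, 1], dtype=np.int64)
        self.present = np.ones(n_nodes, dtype=np.bool_)
        self.degree = np.diff(self.indptr).astype(np.int64)
        self._degree0 = self.degree.copy()
        self.m_edges_initial = edges.shape[0]
        self.mean_degree_initial = 2.0 * self.m_edges_initial / n_nodes
        self.node_labels = node_labels

    # -- basic accessors ---------------------------------------------------

    def neighbors(self, i: int) -> np.ndarray:
        """All original neighbors of ``i`` (including currently removed ones)."""
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def present_neighbors(self, i: int) -> np.ndarray:
        nb = self.neighbors(i)
        return nb[self.present[nb]]

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    @property
    def m_edges(self) -> int:
        """Number of undirected edges among present nodes."""
        return int(self.degree[self.present].sum()) // 2

    def edges(self) -> np.ndarray:
        """All original undirected edges as an (M, 2) array with i < j."""
        src = np.repeat(np.arange(self.n_nodes), np.diff(self.indptr))
        mask = src < self.indices
        return np.column_stack([src[mask], self.indices[mask]])

    def copy(self) -> "Graph":
        g = object.__new__(Graph)
        g.n_nodes = self.n_nodes
        g.indptr = self.indptr
        g.indices = self.indices
        g.present = self.present.copy()
        g.degree = self.degree.copy()
        g._degree0 = self._degree0
        g.m_edges_initial = self.m_edges_initial
        g.mean_degree_initial = self.mean_degree_initial
        g.node_labels = self.node_labels
        return g

    # -- removal / reinsertion --------------------------------------------

    def remove_node(self, i: int) -> None:
        if not self.present[i]:
            raise GraphError(f"node {i} already removed")
        self.present[i] = False
        self.degree[i] = 0
        nb = self.present_neighbors(i)
        self.degree[nb] -= 1

    def restore_node(self, i: int) -> None:
        """Reinsert ``i`` restoring only edges to currently present neighbors."""
        if self.present[i]:
            raise GraphError(f"node {i} is already present")
        self.present[i] = True
        nb = self.present_neighbors(i)
        self.degree[nb] += 1
        self.degree[i] = nb.size

    def reset(self) -> None:
        """Restore the pristine graph (all nodes present)."""
        self.present[:] = True
        self.degree[:] = self._degree0

    def components(self) -> ComponentStats:
        g, s, c = _components_kernel(self.indptr, self.indices, self.present)
        return ComponentStats(int(g), int(s), int(c))

    def components_masked(self, mask: np.ndarray) -> ComponentStats:
        """Component stats over an arbitrary node mask (ANDed with presence)."""
        m = np.logical_and(self.present, mask)
        g, s, c = _components_kernel(self.indptr, self.indices, m)
        return ComponentStats(int(g), int(s), int(c))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Graph(n={self.n_nodes}, m={self.m_edges_initial}, "
                f"present={self.n_present})")


def components(graph: Graph) -> ComponentStats:
    """Sizes of the largest / second-largest connected components."""
    return graph.components()


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_er(n: int, mean_degree: float, seed: int) -> Graph:
    """Erdős–Rényi G(n, M) graph with M = round(n * mean_degree / 2) edges.

    The fixed-M variant makes the average degree exact, which is how the
    attack experiments are parameterized.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise GraphError("n must be >= 1")
    if mean_degree < 0:
        raise GraphError("mean_degree must be >= 0")
    m = int(round(n * mean_degree / 2.0))
    max_m = n * (n - 1) // 2
    if m > max_m:
        raise GraphError(f"mean_degree {mean_degree} implies {m} edges > n(n-1)/2 = {max_m}")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    seen: set[int] = set()
    while len(chosen) < m:
        need = m - len(chosen)
        a = rng.integers(0, n, size=2 * need + 16)
        b = rng.integers(0, n, size=2 * need + 16)
        ok = a != b
        lo = np.minimum(a[ok], b[ok])
        hi = np.maximum(a[ok], b[ok])
        for c in lo * n + hi:
            c = int(c)
            if c not in seen:
                seen.add(c)
                chosen.append(c)
                if len(chosen) == m:
                    break
    codes = np.asarray(chosen, dtype=np.int64)
    edges = np.column_stack([codes // n, codes % n])
    return Graph(n, edges)


def generate_rrg(n: int, k: int, seed: int, max_attempts: int = 10000) -> Graph:
    """Random k-regular simple graph via the pairing (configuration) model.

    Stubs are shuffled and paired; any self-loop or duplicate edge triggers a
    full restart, which is cheap for small k (the acceptance probability is
    asymptotically exp(-(k^2-1)/4)).
    """
    if k >= n:
        raise GraphError("k must be < n")
    if (n * k) % 2 != 0:
        raise GraphError(f"n*k = {n * k} is odd; a {k}-regular graph on {n} nodes does not exist")
    if k < 0:
        raise GraphError("k must be >= 0")
    rng = np.random.default_rng(seed)
    stubs0 = np.repeat(np.arange(n, dtype=np.int64), k)
    for _ in range(max_attempts):
        stubs = stubs0.copy()
        rng.shuffle(stubs)
        u = stubs[0::2]
        v = stubs[1::2]
        if np.any(u == v):
            continue
        lo = np.minimum(u, v)
        hi = np.maximum(u, v)
        code = lo * n + hi
        if np.unique(code).size != code.size:
            continue
        return Graph(n, np.column_stack([lo, hi]))
    raise GraphError("pairing model failed to produce a simple graph; increase max_attempts")


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def read_edgelist(path) -> Graph:
    """Read a whitespace-separated integer edge list (one edge per line).

    Lines starting with ``#`` are ignored.  Arbitrary integer labels are
    mapped to dense 0-based internal ids (sorted label order); the mapping is
    recorded in ``Graph.node_labels``.  Self-loops and duplicate edges are
    rejected with the offending line number.
    """
    raw: list[tuple[int, int]] = []
    lines: list[int] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            toks = s.split()
            if len(toks) != 2:
                raise EdgeListParseError(f"expected two integers, got {s!r}", ln)
            try:
                a, b = int(toks[0]), int(toks[1])
            except ValueError:
                raise EdgeListParseError(f"non-integer token in {s!r}", ln) from None
            if a == b:
                raise EdgeListParseError(f"self-loop {a} {b}", ln)
            raw.append((a, b))
            lines.append(ln)
    if not raw:
        raise EdgeListParseError("no edges in file", 0)
    arr = np.asarray(raw, dtype=np.int64)
    labels = np.unique(arr)
    lut = {int(lab): i for i, lab in enumerate(labels)}
    mapped = np.array([[lut[int(a)], lut[int(b)]] for a, b in arr], dtype=np.int64)
    lo = np.minimum(mapped[:, 0], mapped[:, 1])
    hi = np.maximum(mapped[:, 0], mapped[:, 1])
    code = lo * labels.size + hi
    seen: dict[int, int] = {}
    for c, ln in zip(code, lines):
        c = int(c)
        if c in seen:
            raise EdgeListParseError(f"duplicate edge (first at line {seen[c]})", ln)
        seen[c] = ln
    return Graph(labels.size, mapped, node_labels=labels)


def write_edgelist(graph: Graph, path) -> None:
    """Write the original edge set, one ``i j`` pair per line.

    External labels are used when the graph was read from a file.  Isolated
    nodes are not representable in the format.
    """
    edges = graph.edges()
    lab = graph.node_labels
    with open(path, "w") as fh:
        for a, b in edges:
            if lab is not None:
                a, b = lab[a], lab[b]
            fh.write(f"{a} {b}\n")
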