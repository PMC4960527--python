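"""Shared fixtures and small-graph builders for the test suite."""

import heapq

import numpy as np
import pytest

from ci_immunize import Graph


def random_tree(n: int, seed: int) -> Graph:
    """Uniform random labeled tree via Prüfer-sequence decoding."""
    if n == 1:
        return Graph(1, np.zeros((0, 2), dtype=np.int64))
    if n == 2:
        return Graph(2, [[0, 1]])
    rng = np.random.default_rng(seed)
    prufer = rng.integers(0, n, size=n - 2)
    degree = np.ones(n, dtype=np.int64)
    for x in prufer:
        degree[x] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for x in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(x)))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, int(x))
    edges.append((heapq.heappop(leaves), heapq.heappop(leaves)))
    return Graph(n, edges)


def random_loopy_graph(n: int, extra_edges: int, seed: int) -> Graph:
    """A random tree plus ``extra_edges`` random chords (connected, loopy)."""
    tree = random_tree(n, seed)
    rng = np.random.default_rng(seed + 1)
    existing = {(min(a, b), max(a, b)) for a, b in tree.edges()}
    chords = []
    while len(chords) < extra_edges:
        a, b = int(rng.integers(n)), int(rng.integers(n))
        if a == b:
            continue
        e = (min(a, b), max(a, b))
        if e not in existing:
            existing.add(e)
            chords.append(e)
    edges = np.vstack([tree.edges(), np.asarray(chords, dtype=np.int64)])
    return Graph(n, edges)


@pytest.fixture
def path5() -> Graph:
    """Path a-b-c-d-e on nodes 0..4."""
    return Graph(5, [[0, 1], [1, 2], [2, 3], [3, 4]])


@pytest.fixture
def star6() -> Graph:
    """Star K_{1,5}: center 0, leaves 1..5."""
    return Graph(6, [[0, i] for i in range(1, 6)])


@pytest.fixture
def cycle6() -> Graph:
    return Graph(6, [[i, (i + 1) % 6] for i in range(6)])


@pytest.fixture
def cycle4() -> Graph:
    return Graph(4, [[0, 1], [1, 2], [2, 3], [3, 0]])
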