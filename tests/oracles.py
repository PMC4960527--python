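"""Independent brute-force oracles shared by unit and acceptance tests."""

import itertools

import numpy as np

from ci_immunize import DirectedEdgeIndex, config_energy


def exhaustive_minimum(graph, params, index=None):
    """Exact minimum of the immunization energy by enumerating all 2^N
    occupation configurations (each with its own converged cavity fixed
    point).  Returns (best_energy, best_configuration)."""
    index = index or DirectedEdgeIndex(graph)
    n = graph.n_nodes
    best = np.inf
    best_cfg = None
    for bits in itertools.product([0, 1], repeat=n):
        nocc = np.asarray(bits, dtype=np.float64)
        e = config_energy(graph, nocc, params, index=index)
        if e < best:
            best = e
            best_cfg = nocc
    return best, best_cfg


def dense_nb_spectral_radius(graph):
    """Spectral radius of the explicitly built 2M x 2M non-backtracking
    matrix (dense eigendecomposition; small graphs only)."""
    from ci_immunize.ci_prop import nb_matrix_dense

    B = nb_matrix_dense(graph)
    if B.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(B))))
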