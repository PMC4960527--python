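"""SIR cavity equations, BP energy minimization, percolation-limit solver."""

import math

import numpy as np
import pytest

from ci_immunize import (DirectedEdgeIndex, Graph, GraphError, SIRParams,
                         BPState, cibp_solve, config_energy, energy,
                         generate_rrg, percolation_immunize, update_h,
                         update_nu)
from ci_immunize.ci_bp import percolation_solve, greedy_trim
from conftest import random_tree
from oracles import exhaustive_minimum


def fresh_state(index, seed=0):
    state = BPState.random_init(index, np.random.default_rng(seed))
    state.nu[:] = 1.0
    return state


class TestUpdateNu:
    def test_all_neighbors_immunized_gives_one_minus_gamma(self, star6):
        idx = DirectedEdgeIndex(star6)
        params = SIRParams(gamma=0.2, beta=0.9)
        nocc = np.zeros(6)
        nocc[0] = 1.0  # only the center present
        state = update_nu(idx, fresh_state(idx), params, n_occ=nocc)
        assert state.nu_node[0] == pytest.approx(0.8)

    def test_beta_zero_gives_one_minus_gamma_everywhere(self, cycle6):
        idx = DirectedEdgeIndex(cycle6)
        params = SIRParams(gamma=0.3, beta=0.0)
        state = update_nu(idx, fresh_state(idx), params, n_occ=np.ones(6))
        assert np.allclose(state.nu, 0.7)
        assert np.allclose(state.nu_node, 0.7)

    def test_epidemic_reaches_everyone_on_cubic_graph_at_beta_one(self):
        # nu = (1-gamma) nu^2 has only the nu ~ 0 stable branch
        g = generate_rrg(200, 3, seed=1)
        idx = DirectedEdgeIndex(g)
        params = SIRParams(gamma=0.05, beta=1.0)
        state = update_nu(idx, fresh_state(idx), params, n_occ=np.ones(200))
        assert state.nu_node.max() < 0.05

    def test_nu_stays_in_unit_interval(self):
        g = random_tree(30, 2)
        idx = DirectedEdgeIndex(g)
        rng = np.random.default_rng(3)
        for beta, gamma in [(0.5, 0.1), (1.0, 0.3), (0.9, 0.9)]:
            params = SIRParams(gamma=gamma, beta=beta)
            state = fresh_state(idx)
            state.nu[:] = rng.random(idx.n_edges)
            nocc = rng.integers(0, 2, size=30).astype(float)
            update_nu(idx, state, params, n_occ=nocc)
            assert np.all(state.nu >= 0.0) and np.all(state.nu <= 1.0)


class TestEnergy:
    def test_all_immunized_costs_mu_per_node(self, cycle6):
        idx = DirectedEdgeIndex(cycle6)
        params = SIRParams(gamma=0.2, beta=1.0, mu=0.7)
        assert config_energy(cycle6, np.zeros(6), params, index=idx) == \
            pytest.approx(0.7 * 6)

    def test_no_immunization_beta_one_outbreak_reaches_everyone(self):
        g = generate_rrg(100, 3, seed=4)
        idx = DirectedEdgeIndex(g)
        params = SIRParams(gamma=0.01, beta=1.0, mu=0.0)
        e = config_energy(g, np.ones(100), params, index=idx)
        assert e == pytest.approx(100, rel=0.05)

    def test_optimal_immunized_count_nonincreasing_in_mu(self):
        g = Graph(8, [[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [5, 6],
                      [6, 7], [7, 0], [0, 4]])
        idx = DirectedEdgeIndex(g)
        prev_count = None
        for mu in (0.05, 0.2, 0.5, 1.0):
            params = SIRParams(gamma=0.2, beta=1.0, mu=mu)
            _, cfg = exhaustive_minimum(g, params, index=idx)
            count = int(np.sum(cfg == 0))
            if prev_count is not None:
                assert count <= prev_count
            prev_count = count


class TestUpdateH:
    def test_isolated_node_is_kept_when_mu_exceeds_gamma(self):
        g = Graph(3, [[0, 1]])  # node 2 isolated
        idx = DirectedEdgeIndex(g)
        params = SIRParams(gamma=0.05, beta=1.0, mu=0.5)
        state = fresh_state(idx)
        update_nu(idx, state, params, n_occ=np.ones(3))
        update_h(idx, state, params)
        assert state.h_node[2] < 0.0  # sign(h) = -1: keep

    def test_cycle_decision_is_uniform_by_symmetry(self, cycle6):
        idx = DirectedEdgeIndex(cycle6)
        params = SIRParams(gamma=0.2, beta=0.8, mu=0.4)
        state = fresh_state(idx)
        state.h_edge[:] = 0.0
        state.h_self[:] = 0.0
        update_nu(idx, state, params, n_occ=np.ones(6))
        update_h(idx, state, params)
        assert np.allclose(state.h_node, state.h_node[0], atol=1e-6)

    def test_bp_decision_matches_exhaustive_on_small_graphs(self):
        # smoke version of the exhaustive-oracle check (full grid in the
        # acceptance suite): energies must match on most small instances
        from ci_immunize import generate_er
        hits, total = 0, 0
        for seed in range(3):
            g = generate_er(7, 2.5, seed=40 + seed)
            idx = DirectedEdgeIndex(g)
            for mu in (0.2, 0.5):
                params = SIRParams(gamma=0.2, beta=1.0, mu=mu)
                e_star, _ = exhaustive_minimum(g, params, index=idx)
                res = cibp_solve(g, params, seed=seed, index=idx)
                total += 1
                hits += res.energy <= e_star + 1e-7
        assert hits >= total - 1


class TestPercolationMode:
    def test_large_mu_immunizes_nobody(self):
        # above the largest possible saving per removal the set is empty
        g = generate_rrg(200, 3, seed=7)
        res = percolation_solve(g, mu=20.0, seed=0)
        assert res.immunized_fraction == 0.0

    def test_star_hub_is_immunized(self):
        g = Graph(31, [[0, i] for i in range(1, 31)])
        res = percolation_solve(g, mu=0.2, gamma=1 / 31, size_cap=10, seed=1)
        assert res.n_occ[0] == 0.0
        assert res.n_occ[1:].sum() == 30

    def test_cycle_is_fragmented_into_mu_sized_pieces(self):
        # enumerating k equispaced cuts of the 60-cycle at mu = 0.4,
        # gamma = 1/60: k mu + k f(60/k - 1) is minimized (flatly) around
        # k = 8..12 with total energy ~ 7.9; far from 0 and from 30
        g = Graph(60, [[i, (i + 1) % 60] for i in range(60)])
        res = percolation_solve(g, mu=0.4, gamma=1 / 60, size_cap=15, seed=2)
        imm = res.n_occ < 0.5
        st = g.components_masked(~imm)
        assert st.giant_size <= 15
        assert 6 <= imm.sum() <= 14

    def test_greedy_trim_only_sheds_redundant_nodes(self):
        g = generate_rrg(300, 3, seed=8)
        rng = np.random.default_rng(0)
        immunized = rng.random(300) < 0.7  # grossly over-immunized
        thr = 2 * math.log(300)
        st = g.components_masked(~immunized)
        assert st.giant_size <= thr
        trimmed = greedy_trim(g, immunized, thr)
        assert trimmed.sum() < immunized.sum()
        assert np.all(~trimmed | immunized)  # trim never adds
        st2 = g.components_masked(~trimmed)
        assert st2.giant_size <= thr

    def test_mu_bisection_destroys_giant_with_small_fraction(self):
        g = generate_rrg(500, 3, seed=9)
        res = percolation_immunize(g, seed=3, bisect_steps=8)
        assert res.giant <= res.giant_threshold
        assert 0.2 < res.q < 0.45
        mask = np.ones(500, dtype=bool)
        mask[res.immunized] = False
        st = g.components_masked(mask)
        assert st.giant_size == res.giant


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(GraphError):
            SIRParams(gamma=1.5)
        with pytest.raises(GraphError):
            SIRParams(beta=-0.1)
        with pytest.raises(GraphError):
            SIRParams(damping=1.0)
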