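"""CI scores, localized updates, the eigenvalue monitor, attacks."""

import numpy as np
import pytest

from ci_immunize import (CIConfig, Graph, GraphError, IndexedMaxHeap,
                         ci_attack, ci_value, compute_all_ci, frontier,
                         generate_er, generate_rrg, hda_attack,
                         lambda_monitor, reference_ci_attack,
                         remove_and_update)
from conftest import random_loopy_graph, random_tree


class TestFrontier:
    def test_path_center_radius_two(self, path5):
        assert list(frontier(path5, 2, 2)) == [0, 4]

    def test_star_center(self, star6):
        assert list(frontier(star6, 0, 1)) == [1, 2, 3, 4, 5]
        assert list(frontier(star6, 0, 2)) == []

    def test_four_cycle_antipodal_shortest_path_rule(self, cycle4):
        # shortest-path distance, not tree unrolling: single antipodal node
        assert list(frontier(cycle4, 0, 2)) == [2]

    def test_removed_node_rejected(self, path5):
        path5.remove_node(2)
        with pytest.raises(GraphError):
            frontier(path5, 2, 1)


class TestCIValue:
    def test_degree_one_node_is_zero_for_every_radius(self, path5):
        for ell in (1, 2, 3):
            assert ci_value(path5, 0, ell) == 0.0

    def test_star_center_is_zero(self, star6):
        assert ci_value(star6, 0, 1) == 0.0  # (5-1) * sum of (1-1)

    def test_path_center_radius_one(self, path5):
        assert ci_value(path5, 2, 1) == 2.0  # (2-1) * ((2-1)+(2-1))

    def test_uses_live_degrees(self, path5):
        path5.remove_node(4)
        # c's frontier at l=1 is {b, d}; d now has degree 1
        assert ci_value(path5, 2, 1) == 1.0


class TestLambdaMonitor:
    def test_random_regular_closed_form_exact_at_radius_one(self):
        # frontier = neighbor set, so CI = 2*6 = 12 for every node: lambda = 2
        g = generate_rrg(2000, 3, seed=1)
        ci = compute_all_ci(g, 1)
        lam = lambda_monitor(float(ci.sum()), 1, float(g.degree.sum()), 1)
        assert lam == pytest.approx(2.0, abs=1e-9)

    def test_random_regular_near_closed_form_at_radius_two(self):
        # short loops shrink a few frontiers: an O(1/N) correction
        g = generate_rrg(2000, 3, seed=1)
        ci = compute_all_ci(g, 2)
        lam = lambda_monitor(float(ci.sum()), 1, float(g.degree.sum()), 2)
        assert lam == pytest.approx(2.0, rel=1e-3)

    def test_zero_ci_sum_fires_stop(self):
        assert lambda_monitor(0.0, 100, 3.5, 3) == 0.0


class TestRemoveAndUpdate:
    @pytest.mark.parametrize("ell", [1, 2, 3])
    def test_tree_update_matches_full_recompute(self, ell):
        for seed in range(5):
            g = random_tree(60, seed)
            ci = compute_all_ci(g, ell)
            heap = IndexedMaxHeap(ci, mask=g.present.copy())
            rng = np.random.default_rng(seed)
            for _ in range(15):
                node = int(rng.choice(np.flatnonzero(g.present)))
                heap.update(node, ci[node])  # ensure slot valid
                remove_and_update(g, heap, node, ell, ci)
                expected = compute_all_ci(g, ell)
                assert np.allclose(ci[g.present], expected[g.present])
                assert heap.is_valid()

    @pytest.mark.parametrize("ell", [1, 2, 3])
    def test_loopy_update_matches_full_recompute(self, ell):
        # the multiplicity-counted outer-layer decrement is exact on loops too
        for seed in range(5):
            g = random_loopy_graph(50, 12, seed)
            ci = compute_all_ci(g, ell)
            heap = IndexedMaxHeap(ci, mask=g.present.copy())
            rng = np.random.default_rng(seed)
            for _ in range(15):
                node = int(rng.choice(np.flatnonzero(g.present)))
                remove_and_update(g, heap, node, ell, ci)
                expected = compute_all_ci(g, ell)
                assert np.allclose(ci[g.present], expected[g.present])

    def test_removing_isolated_node_updates_nothing(self):
        g = Graph(4, [[0, 1], [1, 2]])
        ci = compute_all_ci(g, 1)
        heap = IndexedMaxHeap(ci, mask=g.present.copy())
        before = ci.copy()
        delta = remove_and_update(g, heap, 3, 1, ci)
        assert delta == 0.0
        assert np.array_equal(ci, before)

    def test_path7_end_removal_hand_case(self):
        # remove node 0 of a 7-path at l=1: node 2 (distance 2) drops by
        # (k-1) = 1; nodes at distance >= 3 unchanged
        g = Graph(7, [[i, i + 1] for i in range(6)])
        ci = compute_all_ci(g, 1)
        before = ci.copy()
        heap = IndexedMaxHeap(ci, mask=g.present.copy())
        remove_and_update(g, heap, 0, 1, ci)
        assert ci[2] == before[2] - 1
        assert np.array_equal(ci[3:], before[3:])


class TestCIAttack:
    def test_ell_zero_rejected(self):
        with pytest.raises(GraphError):
            CIConfig(ell=0)

    def test_star_stops_before_any_removal(self, star6):
        # all CI values are zero, so lambda = 0 <= 1 at q = 0
        trace = ci_attack(star6, CIConfig(ell=1))
        assert trace.n_removed == 0
        assert trace.qc_estimate == 0.0

    @pytest.mark.parametrize("ell", [1, 2, 3])
    def test_heap_attack_equals_naive_reference_on_trees(self, ell):
        for seed in range(4):
            g = random_tree(80, seed + 10)
            ref = reference_ci_attack(g, ell, stop_rule="fixed_fraction",
                                      fixed_q=0.3)
            trace = ci_attack(g.copy(), CIConfig(
                ell=ell, stop_rule="fixed_fraction", fixed_q=0.3,
                deterministic_ties=True))
            assert list(trace.removal_order) == ref

    @pytest.mark.parametrize("ell", [1, 2])
    def test_heap_attack_equals_naive_reference_on_loopy_graphs(self, ell):
        for seed in range(4):
            g = random_loopy_graph(70, 20, seed + 20)
            ref = reference_ci_attack(g, ell, stop_rule="fixed_fraction",
                                      fixed_q=0.3)
            trace = ci_attack(g.copy(), CIConfig(
                ell=ell, stop_rule="fixed_fraction", fixed_q=0.3,
                deterministic_ties=True))
            assert list(trace.removal_order) == ref

    def test_exact_update_mode_agrees_with_default(self):
        g = random_loopy_graph(60, 15, 3)
        a = ci_attack(g.copy(), CIConfig(ell=2, stop_rule="fixed_fraction",
                                         fixed_q=0.4, deterministic_ties=True))
        b = ci_attack(g.copy(), CIConfig(ell=2, stop_rule="fixed_fraction",
                                         fixed_q=0.4, deterministic_ties=True,
                                         exact_update=True))
        assert np.array_equal(a.removal_order, b.removal_order)
        assert np.allclose(a.lam, b.lam)

    def test_q_increases_by_one_over_n(self):
        g = generate_er(500, 3.0, seed=1)
        trace = ci_attack(g, CIConfig(ell=2, stop_rule="fixed_fraction",
                                      fixed_q=0.2))
        assert np.allclose(np.diff(trace.q), 1.0 / 500)

    def test_ci_sum_nonnegative_and_exhaustion_reaches_zero(self):
        g = generate_er(300, 3.0, seed=2)
        trace = ci_attack(g, CIConfig(ell=2, stop_rule="fixed_fraction",
                                      fixed_q=1.0))
        assert np.all(trace.lam >= 0.0)
        assert trace.lam[-1] == 0.0

    def test_attack_trace_tsv_round_trip(self, tmp_path):
        g = generate_er(400, 3.5, seed=5)
        trace = ci_attack(g, CIConfig(ell=2))
        p = tmp_path / "trace.tsv"
        trace.to_tsv(p)
        from ci_immunize import AttackTrace
        back = AttackTrace.from_tsv(p)
        assert back.n0 == trace.n0
        assert np.array_equal(back.removal_order, trace.removal_order)
        assert np.allclose(back.lam, trace.lam)
        assert back.qc_estimate == pytest.approx(trace.qc_estimate)


class TestHDA:
    def test_star_center_removed_first(self, star6):
        trace = hda_attack(star6, giant_threshold=1.0)
        assert trace.removal_order[0] == 0

    def test_regular_graph_trace_reproducible_with_deterministic_ties(self):
        g = generate_rrg(200, 3, seed=4)
        a = hda_attack(g.copy(), deterministic_ties=True)
        b = hda_attack(g.copy(), deterministic_ties=True)
        assert np.array_equal(a.removal_order, b.removal_order)

    def test_stops_when_giant_destroyed(self):
        g = generate_er(2000, 3.5, seed=6)
        trace = hda_attack(g, grid_every=20)
        st = g.components()
        assert st.giant_size <= trace.meta["giant_threshold"]
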