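"""Graph container, generators, edge-list I/O, component accounting."""

import numpy as np
import pytest

from ci_immunize import (Graph, GraphError, EdgeListParseError,
                         generate_er, generate_rrg,
                         read_edgelist, write_edgelist)


class TestGenerateER:
    def test_zero_mean_degree_gives_empty_graph(self):
        g = generate_er(10, 0.0, seed=1)
        assert g.m_edges_initial == 0
        assert g.n_nodes == 10

    def test_edge_count_is_exact_and_simple(self):
        g = generate_er(1000, 3.5, seed=7)
        assert g.m_edges_initial == 1750
        e = g.edges()
        assert np.all(e[:, 0] < e[:, 1])  # no self-loops, canonical order
        codes = e[:, 0] * 1000 + e[:, 1]
        assert np.unique(codes).size == codes.size  # no parallel edges

    def test_degree_moments_match_poisson_limit(self):
        # kappa - 1 = <k^2>/<k> - 1 -> <k> for Poisson degrees
        g = generate_er(100_000, 3.5, seed=11)
        k = g.degree.astype(float)
        kappa_m1 = (k ** 2).mean() / k.mean() - 1.0
        # delta-method standard error of <k^2>/<k>
        m1, m2 = k.mean(), (k ** 2).mean()
        grad = np.array([-m2 / m1 ** 2, 1 / m1])
        cov = np.cov(np.vstack([k, k ** 2])) / k.size
        se = float(np.sqrt(grad @ cov @ grad))
        assert abs(kappa_m1 - 3.5) < 3 * se + 1e-12

    def test_too_dense_raises(self):
        with pytest.raises(GraphError):
            generate_er(10, 20.0, seed=0)

    def test_reproducible_for_fixed_seed(self):
        a = generate_er(500, 3.0, seed=42)
        b = generate_er(500, 3.0, seed=42)
        assert np.array_equal(a.edges(), b.edges())


class TestGenerateRRG:
    def test_n4_k3_is_complete_graph(self):
        g = generate_rrg(4, 3, seed=0)
        assert g.m_edges_initial == 6
        assert np.all(g.degree == 3)

    def test_parity_error(self):
        with pytest.raises(GraphError):
            generate_rrg(5, 3, seed=0)

    def test_k_ge_n_error(self):
        with pytest.raises(GraphError):
            generate_rrg(4, 4, seed=0)

    def test_regularity(self):
        g = generate_rrg(1000, 3, seed=5)
        assert np.all(g.degree == 3)
        assert g.m_edges_initial == 1500

    def test_reproducible_for_fixed_seed(self):
        a = generate_rrg(200, 3, seed=9)
        b = generate_rrg(200, 3, seed=9)
        assert np.array_equal(a.edges(), b.edges())


class TestEdgeListIO:
    def test_read_simple_path(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("# a comment\n0 1\n1 2\n")
        g = read_edgelist(p)
        assert g.n_nodes == 3
        assert g.m_edges_initial == 2

    def test_round_trip_preserves_edge_set(self, tmp_path):
        g = generate_er(200, 3.0, seed=3)
        p = tmp_path / "g.edges"
        write_edgelist(g, p)
        g2 = read_edgelist(p)
        # reader maps labels to dense ids; compare in label space
        relabeled = g2.node_labels[g2.edges()]
        canon = lambda e: {(min(a, b), max(a, b)) for a, b in e}
        assert canon(relabeled) == canon(g.edges())

    def test_self_loop_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("0 1\n2 2\n")
        with pytest.raises(EdgeListParseError, match="line 2"):
            read_edgelist(p)

    def test_duplicate_edge_rejected(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("0 1\n1 2\n1 0\n")
        with pytest.raises(EdgeListParseError, match="line 3"):
            read_edgelist(p)

    def test_non_integer_token_rejected(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("0 x\n")
        with pytest.raises(EdgeListParseError, match="line 1"):
            read_edgelist(p)

    def test_arbitrary_labels_are_mapped(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("10 30\n30 500\n")
        g = read_edgelist(p)
        assert g.n_nodes == 3
        assert list(g.node_labels) == [10, 30, 500]


class TestComponents:
    def test_path_is_single_component(self, path5):
        st = path5.components()
        assert (st.giant_size, st.second_size, st.n_components) == (5, 0, 1)

    def test_two_disjoint_cliques(self):
        edges = ([[a, b] for a in range(4) for b in range(a + 1, 4)] +
                 [[a, b] for a in range(4, 7) for b in range(a + 1, 7)])
        g = Graph(7, edges)
        st = g.components()
        assert (st.giant_size, st.second_size, st.n_components) == (4, 3, 2)

    def test_star_without_center_shatters(self, star6):
        star6.remove_node(0)
        st = star6.components()
        assert (st.giant_size, st.second_size, st.n_components) == (1, 1, 5)

    def test_component_sizes_partition_present_nodes(self):
        g = generate_er(300, 2.0, seed=1)
        rng = np.random.default_rng(0)
        for i in rng.choice(300, size=80, replace=False):
            g.remove_node(int(i))
        # removal never increases the giant; reinsertion never decreases it
        sizes = []
        giant = g.components().giant_size
        for i in rng.choice(np.flatnonzero(g.present), size=40, replace=False):
            g.remove_node(int(i))
            new_giant = g.components().giant_size
            assert new_giant <= giant
            giant = new_giant
            sizes.append(new_giant)
        for i in rng.choice(np.flatnonzero(~g.present), size=40, replace=False):
            g.restore_node(int(i))
            new_giant = g.components().giant_size
            assert new_giant >= giant
            giant = new_giant


class TestRemovalBookkeeping:
    def test_degrees_track_present_neighbors(self):
        g = generate_er(100, 4.0, seed=2)
        rng = np.random.default_rng(3)
        order = rng.permutation(100)[:50]
        for i in order:
            g.remove_node(int(i))
        for i in range(100):
            if g.present[i]:
                assert g.degree[i] == g.present_neighbors(i).size
            else:
                assert g.degree[i] == 0
        assert int(g.degree[g.present].sum()) % 2 == 0  # handshake

    def test_reset_restores_pristine_state(self):
        g = generate_er(50, 3.0, seed=4)
        d0 = g.degree.copy()
        for i in range(20):
            g.remove_node(i)
        g.reset()
        assert np.array_equal(g.degree, d0)
        assert g.present.all()
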