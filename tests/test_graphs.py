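import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pggnet as pg


def assert_valid(net: pg.Network):
    a = net.adjacency
    assert np.array_equal(a, a.T)
    assert np.all(np.diag(a) == 0)
    assert set(np.unique(a)) <= {0.0, 1.0}
    assert net.is_connected()


class TestStarFamilies:
    @pytest.mark.parametrize("n_leaves,n_nodes,hub_deg", [(1, 2, 1), (7, 8, 7), (9, 10, 9)])
    def test_star_shape(self, n_leaves, n_nodes, hub_deg):
        net = pg.make_star(n_leaves)
        assert_valid(net)
        assert net.n_nodes == n_nodes
        deg = sorted(net.degrees)
        assert deg == [1.0] * n_leaves + [hub_deg]

    def test_star_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pg.make_star(0)

    def test_joint_stars_single_hub_is_star(self):
        a = pg.make_joint_stars(1, 5).adjacency
        assert np.array_equal(a, pg.make_star(5).adjacency)

    def test_joint_stars_shapes(self):
        net = pg.make_joint_stars(3, 9)
        assert_valid(net)
        assert net.n_nodes == 30
        deg = net.degrees
        assert sorted(deg)[-3:] == [11.0, 11.0, 11.0]  # hubs: 2 hubs + 9 leaves
        assert (deg == 1).sum() == 27
        small = pg.make_joint_stars(2, 1)
        assert small.n_nodes == 4
        assert sorted(small.degrees) == [1, 1, 2, 2]

    def test_ceiling_fan_shapes(self):
        assert np.array_equal(pg.make_ceiling_fan(1).adjacency, 1.0 - np.eye(3))
        net = pg.make_ceiling_fan(9)
        assert_valid(net)
        assert net.n_nodes == 19
        assert sorted(net.degrees) == [2.0] * 18 + [18.0]
        # two blades: the hub closes 2 of its C(4,2) neighbor pairs
        import networkx as nx

        assert nx.clustering(pg.make_ceiling_fan(2).to_networkx(), 0) == pytest.approx(1 / 3)


class TestLattices:
    def test_von_neumann_degree_4(self):
        net = pg.make_lattice(5, "von_neumann")
        assert_valid(net)
        assert net.n_nodes == 25
        assert np.all(net.degrees == 4)

    def test_moore_3x3_is_complete(self):
        assert np.array_equal(pg.make_lattice(3, "moore").adjacency, 1.0 - np.eye(9))

    def test_von_neumann_4x4_bipartite(self):
        import networkx as nx

        net = pg.make_lattice(4)
        assert np.all(net.degrees == 4)
        assert nx.is_bipartite(net.to_networkx())

    def test_rejects_small_side(self):
        with pytest.raises(ValueError):
            pg.make_lattice(2, "von_neumann")


class TestRandomFamilies:
    def test_er_p1_is_complete(self):
        net = pg.make_erdos_renyi(5, 1.0, seed=0)
        assert np.array_equal(net.adjacency, 1.0 - np.eye(5))

    def test_er_mean_degree(self):
        # pooled edge count over draws is binomial; compare at 3 sigma
        n, p, draws = 50, 0.2, 60
        pairs = n * (n - 1) // 2
        total = sum(pg.make_erdos_renyi(n, p, seed=s).n_edges for s in range(draws))
        mean = draws * pairs * p
        # connectivity conditioning is negligible at this density
        sigma = np.sqrt(draws * pairs * p * (1 - p))
        assert abs(total - mean) < 3 * sigma

    def test_er_rejects_bad_p(self):
        with pytest.raises(ValueError):
            pg.make_erdos_renyi(10, 0.0, seed=1)

    def test_ws_ring_limit(self):
        net = pg.make_watts_strogatz(100, 2, 0.0, seed=0)
        assert np.all(net.degrees == 4)
        assert pg.clustering_coefficient(net) == pytest.approx(0.5)
        c10 = pg.make_watts_strogatz(10, 1, 0.0, seed=0)
        assert np.all(c10.degrees == 2)

    def test_ws_preserves_edge_count(self):
        for p in (0.2, 0.5, 1.0):
            net = pg.make_watts_strogatz(100, 2, p, seed=3)
            assert_valid(net)
            assert net.n_edges == 200

    def test_ba_edge_count_and_mean_degree(self):
        net = pg.make_scale_free(100, 2, 2.0, seed=5)
        assert_valid(net)
        assert net.n_edges == 2 * (100 - 2)
        assert net.degrees.mean() == pytest.approx(2 * 2 * (1 - 2 / 100))

    def test_ba_forced_attachment(self):
        net = pg.make_scale_free(3, 2, 1.0, seed=0)
        assert net.degrees[2] == 2  # newcomer attaches to both initial nodes

    def test_ba_gamma_controls_heterogeneity(self):
        hi = [pg.make_scale_free(80, 2, 2.0, seed=s).degrees.max() for s in range(30)]
        lo = [pg.make_scale_free(80, 2, 0.0, seed=s).degrees.max() for s in range(30)]
        assert np.mean(hi) > np.mean(lo) + 2

    def test_reproducible(self):
        for maker in (
            lambda s: pg.make_erdos_renyi(30, 0.15, s),
            lambda s: pg.make_watts_strogatz(30, 2, 0.4, s),
            lambda s: pg.make_scale_free(30, 2, 1.5, s),
        ):
            assert np.array_equal(maker(123).adjacency, maker(123).adjacency)


class TestIO:
    def test_parse_path_graph(self, tmp_path):
        f = tmp_path / "g.txt"
        f.write_text("# comment\na b\nb c\n")
        net = pg.read_edge_list(f)
        assert net.n_nodes == 3 and net.n_edges == 2
        assert sorted(net.degrees) == [1, 1, 2]

    def test_round_trip_star(self, tmp_path):
        import networkx as nx

        f = tmp_path / "star.txt"
        pg.write_edge_list(pg.make_star(4), f)
        back = pg.read_edge_list(f)
        assert nx.is_isomorphic(back.to_networkx(), pg.make_star(4).to_networkx())

    def test_self_loop_rejected(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("1 1\n")
        with pytest.raises(ValueError, match="self-loop"):
            pg.read_edge_list(f)

    def test_disconnected_warns(self, tmp_path):
        f = tmp_path / "disc.txt"
        f.write_text("a b\nc d\n")
        with pytest.warns(UserWarning, match="not connected"):
            pg.read_edge_list(f)

    def test_duplicate_edges_collapse(self, tmp_path):
        f = tmp_path / "dup.txt"
        f.write_text("a b\nb a\na,b\n")
        assert pg.read_edge_list(f).n_edges == 1


class TestClustering:
    def test_extremes(self):
        assert pg.clustering_coefficient(pg.Network(1.0 - np.eye(4))) == 1.0
        assert pg.clustering_coefficient(pg.make_star(6)) == 0.0


class TestNetworkValidation:
    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            pg.Network(a)

    def test_self_loop_rejected(self):
        a = np.eye(3)
        with pytest.raises(ValueError):
            pg.Network(a)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 25))
    def test_er_invariants(self, seed, n):
        assert_valid(pg.make_erdos_renyi(n, 0.3, seed))
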