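import numpy as np
import pytest

import pggnet as pg
from pggnet.thresholds import payoff_matrices, pgg_critical_r, dg_critical_bc


def complete(n):
    return pg.Network(1.0 - np.eye(n))


class TestUpsilon:
    def test_diagonal_vanishes(self, small_graph_zoo):
        for net in small_graph_zoo:
            t = pg.solve_coalescence_times(net)
            ups = pg.upsilon_matrix(net, t)
            assert np.all(np.diag(ups) == 0)

    def test_symmetrized_automorphism_invariance(self, cycle6):
        # on a vertex-transitive graph Upsilon_ij + Upsilon_ji depends
        # only on the orbit of the pair
        t = pg.solve_coalescence_times(cycle6)
        ups = pg.upsilon_matrix(cycle6, t)
        s = ups + ups.T
        for d in (1, 2, 3):
            vals = [s[i, (i + d) % 6] for i in range(6)]
            assert np.allclose(vals, vals[0])

    def test_closed_forms_match_generic(self, small_graph_zoo):
        # r* = tau(1)/Upsilon(1) under PC and tau(2)/Upsilon(2) under DB
        for net in small_graph_zoo:
            t = pg.solve_coalescence_times(net)
            ups = pg.upsilon_matrix(net, t)
            k = net.degrees
            p = pg.step_distribution(net)
            for rule, n_step in (("pc", 1), ("db", 2)):
                pn = np.linalg.matrix_power(p, n_step)
                tau_n = np.sum(k[:, None] * pn * t)
                ups_n = np.sum(k[:, None] * pn * ups)
                res = pgg_critical_r(net, rule=rule)
                if res.category == "no_support" and not res.favored_above:
                    # complete graphs: the Upsilon functional vanishes
                    assert abs(ups_n) < 1e-9 * tau_n
                else:
                    assert tau_n / ups_n == pytest.approx(res.value, rel=1e-9)


class TestPggThresholds:
    @pytest.mark.parametrize("n_leaves", [2, 3, 5, 9, 17, 33, 50])
    def test_db_star_is_exactly_four(self, n_leaves):
        res = pgg_critical_r(pg.make_star(n_leaves), rule="db")
        assert res.value == pytest.approx(4.0, abs=1e-9)
        assert res.category == "finite_supporting"

    @pytest.mark.parametrize("rule", ["pc", "db", "bd"])
    def test_complete_graph_never_supports(self, k8, rule):
        assert pgg_critical_r(k8, rule=rule).category == "no_support"

    def test_path3_pc_frozen_value(self, path3):
        # 60/7, from an independent symbolic first-order solve of the
        # full 8-state chain
        assert pgg_critical_r(path3, rule="pc").value == pytest.approx(60 / 7, rel=1e-10)

    def test_path3_matches_oracle(self, path3):
        for rule in ("pc", "db", "bd"):
            th = pgg_critical_r(path3, rule=rule).value
            oc = pg.oracle_critical(path3, rule=rule).value
            assert th == pytest.approx(oc, rel=1e-6)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        for net in (pg.make_lattice(4), pg.make_ceiling_fan(3)):
            base = pgg_critical_r(net, rule="db").value
            perm = rng.permutation(net.n_nodes)
            shuffled = pg.Network(net.adjacency[np.ix_(perm, perm)])
            assert pgg_critical_r(shuffled, rule="db").value == pytest.approx(base, abs=1e-9)

    def test_small_populations_rejected(self):
        with pytest.raises(ValueError):
            pgg_critical_r(complete(2))

    def test_disconnected_rejected(self):
        net = pg.Network(np.kron(np.eye(2), 1.0 - np.eye(2)))
        with pytest.raises(ValueError):
            pgg_critical_r(net)


class TestDonationGame:
    @pytest.mark.parametrize("rule", ["pc", "bd"])
    def test_spiteful_rules_never_support(self, small_graph_zoo, rule):
        for net in small_graph_zoo:
            if net.n_nodes < 3:
                continue
            assert dg_critical_bc(net, rule=rule).category == "no_support"

    def test_cycle_db_matches_oracle(self, cycle6):
        th = dg_critical_bc(cycle6, rule="db").value
        oc = pg.oracle_critical(cycle6, rule="db", game="dg").value
        assert th == pytest.approx(oc, rel=1e-6)


class TestPayoffMatrices:
    def test_all_cooperate_complete_graph(self):
        # every game returns (r-1)c to each player
        net = complete(6)
        phi_c, phi_b = payoff_matrices(net, "pgg", "average")
        x = np.ones(6)
        r = 3.0
        f = (r * phi_b - phi_c) @ x
        assert np.allclose(f, r - 1)

    def test_accumulated_is_group_count_times_average_on_regular(self, cycle6):
        phi_c_a, phi_b_a = payoff_matrices(cycle6, "pgg", "average")
        phi_c_s, phi_b_s = payoff_matrices(cycle6, "pgg", "accumulated")
        g = cycle6.group_sizes
        assert np.allclose(phi_b_s, g[:, None] * phi_b_a)
        assert np.allclose(phi_c_s, g[:, None] * phi_c_a)
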