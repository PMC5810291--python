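"""Coalteration matrix, contingency counts, Patel's kappa, Monte-Carlo
significance, and network assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coalternet as cn
from coalternet.coalteration import (ContingencyCounts,
                                     DegenerateMarginalError, kappa_array)


def node(nid, region, xyz, hemi="L"):
    return cn.NetworkNode(nid, region, hemi, *xyz, ale_value=0.5,
                          atlas_label=1)


class TestBuildMatrix:
    def _nodes(self):
        return [node("A_1", "A", (0.0, 0.0, 0.0)),
                node("B_1", "B", (30.0, 0.0, 0.0), "R")]

    def test_focus_at_peak_marks_cell(self):
        exps = [cn.Experiment(id="E1", label="", foci=[cn.Focus(0, 0, 0)])]
        m = cn.build_matrix(exps, self._nodes())
        assert m.values.tolist() == [[1, 0]]

    def test_radius_boundary_exclusive_beyond(self):
        exps = [cn.Experiment(id="E1", label="",
                              foci=[cn.Focus(10.1, 0, 0)]),
                cn.Experiment(id="E2", label="",
                              foci=[cn.Focus(10.0, 0, 0)])]
        m = cn.build_matrix(exps, self._nodes(), assign_radius_mm=10.0)
        assert m.values[:, 0].tolist() == [0, 1]

    def test_far_experiment_keeps_zero_row(self):
        exps = [cn.Experiment(id="E1", label="",
                              foci=[cn.Focus(-60, -60, -60)])]
        m = cn.build_matrix(exps, self._nodes())
        assert m.values.tolist() == [[0, 0]]

    def test_one_focus_can_mark_several_nodes(self):
        nodes = [node("A_1", "A", (0.0, 0.0, 0.0)),
                 node("A_2", "A", (12.0, 0.0, 0.0))]
        exps = [cn.Experiment(id="E1", label="", foci=[cn.Focus(6, 0, 0)])]
        m = cn.build_matrix(exps, nodes)
        assert m.values.tolist() == [[1, 1]]

    def test_region_rule_mode(self, two_region_atlas):
        nodes = [node("Box_L_1", "Box_L", (-10.0, 0.0, 0.0))]
        object.__setattr__(nodes[0], "atlas_label", 1)
        exps = [cn.Experiment(id="E1", label="",
                              foci=[cn.Focus(-4, 6, -6)]),   # inside Box_L
                cn.Experiment(id="E2", label="",
                              foci=[cn.Focus(30, 30, 30)])]  # background
        m = cn.build_matrix(exps, nodes, assign_rule="region",
                            atlas=two_region_atlas)
        assert m.values[:, 0].tolist() == [1, 0]

    def test_empty_nodes_rejected(self):
        with pytest.raises(ValueError):
            cn.build_matrix([], [])


class TestContingency:
    def _matrix(self, rows):
        return cn.CoalterationMatrix(
            experiment_ids=[f"E{i}" for i in range(len(rows))],
            node_ids=["a", "b"], values=np.array(rows))

    def test_direct_count(self):
        cc = cn.contingency(self._matrix([[1, 1], [1, 1], [0, 0]]), "a", "b")
        assert (cc.n1, cc.n2, cc.n3, cc.n4) == (2, 0, 0, 1)
        assert cc.N == 3

    def test_column_swap_exchanges_n2_n3(self):
        m = self._matrix([[1, 0], [1, 0], [0, 1], [1, 1]])
        ab = cn.contingency(m, "a", "b")
        ba = cn.contingency(m, "b", "a")
        assert (ab.n2, ab.n3) == (ba.n3, ba.n2)
        assert (ab.n1, ab.n4) == (ba.n1, ba.n4)

    def test_against_row_loop_oracle(self, rng):
        values = rng.integers(0, 2, size=(57, 2))
        m = self._matrix(values.tolist())
        cc = cn.contingency(m, "a", "b")
        tally = {"11": 0, "10": 0, "01": 0, "00": 0}
        for a, b in values:
            tally[f"{a}{b}"] += 1
        assert (cc.n1, cc.n2, cc.n3, cc.n4) == (
            tally["11"], tally["10"], tally["01"], tally["00"])

    def test_same_column_rejected(self):
        with pytest.raises(ValueError):
            cn.contingency(self._matrix([[1, 1]]), "a", "a")

    def test_theta_sums_to_one(self):
        cc = ContingencyCounts("a", "b", 3, 5, 7, 9)
        assert sum(cc.thetas()) == pytest.approx(1.0)


class TestPatelKappa:
    @pytest.mark.parametrize("theta,expected", [
        ((0.3, 0.0, 0.0, 0.7), 1.0),      # perfect co-occurrence
        ((0.0, 0.5, 0.5, 0.0), -1.0),     # complementary alteration
        ((0.25, 0.25, 0.25, 0.25), 0.0),  # independence
        ((0.2, 0.1, 0.1, 0.6), 0.11 / 0.21),
    ])
    def test_reference_values(self, theta, expected):
        assert cn.patel_kappa(theta) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("theta", [
        (1.0, 0.0, 0.0, 0.0),   # both always altered
        (0.0, 0.0, 0.0, 1.0),   # both never altered
        (0.5, 0.5, 0.0, 0.0),   # a always altered
    ])
    def test_degenerate_marginals_raise(self, theta):
        with pytest.raises(DegenerateMarginalError):
            cn.patel_kappa(theta)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            cn.patel_kappa((0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            cn.patel_kappa((-0.1, 0.5, 0.5, 0.1))

    @given(st.tuples(*[st.integers(1, 30) for _ in range(4)]))
    def test_symmetry_and_range_on_random_tables(self, counts):
        n = sum(counts)
        theta = tuple(c / n for c in counts)
        k = cn.patel_kappa(theta)
        swapped = (theta[0], theta[2], theta[1], theta[3])
        assert cn.patel_kappa(swapped) == pytest.approx(k, abs=1e-12)
        assert -1.0 <= k <= 1.0

    def test_kappa_array_nan_on_degenerate(self):
        out = kappa_array(np.array([[0.5, 0.5, 0.0, 0.0],
                                    [0.25, 0.25, 0.25, 0.25]]))
        assert np.isnan(out[0])
        assert out[1] == pytest.approx(0.0)

    def test_sign_matches_excess_over_independence(self, rng):
        for _ in range(50):
            c = rng.integers(1, 20, 4)
            theta = c / c.sum()
            E = (theta[0] + theta[1]) * (theta[0] + theta[2])
            k = cn.patel_kappa(tuple(theta))
            assert np.sign(k) == pytest.approx(np.sign(theta[0] - E))


class TestEdgeSignificance:
    def test_strong_cooccurrence_is_significant(self):
        cc = ContingencyCounts("a", "b", 25, 0, 0, 25)
        res = cn.edge_significance(cc, seed=0)
        assert res.significant
        assert res.posterior_prob > 0.99
        assert res.kappa == pytest.approx(1.0)

    def test_balanced_independent_table_not_significant(self):
        cc = ContingencyCounts("a", "b", 13, 12, 13, 12)
        res = cn.edge_significance(cc, seed=0)
        assert not res.significant
        assert 0.05 < res.posterior_prob < 0.95

    def test_deterministic_under_seed(self):
        cc = ContingencyCounts("a", "b", 10, 5, 7, 20)
        r1 = cn.edge_significance(cc, seed=42)
        r2 = cn.edge_significance(cc, seed=42)
        assert r1.posterior_prob == r2.posterior_prob

    def test_small_sample_count_rejected(self):
        cc = ContingencyCounts("a", "b", 10, 5, 7, 20)
        with pytest.raises(ValueError, match="1000"):
            cn.edge_significance(cc, n_samples=500)

    def test_posterior_prob_matches_direct_dirichlet_oracle(self):
        # independent recomputation from the same posterior definition
        cc = ContingencyCounts("a", "b", 20, 6, 5, 26)
        res = cn.edge_significance(cc, seed=7, n_samples=20_000)
        rng = np.random.default_rng(1234)
        draws = rng.dirichlet(1 + cc.counts, size=200_000)
        t1, t2, t3 = draws[:, 0], draws[:, 1], draws[:, 2]
        E = (t1 + t2) * (t1 + t3)
        tmax = np.minimum(t1 + t2, t1 + t3)
        tmin = np.maximum(0, 2 * t1 + t2 + t3 - 1)
        k = np.where(t1 >= E, (t1 - E) / (tmax - E), (t1 - E) / (E - tmin))
        oracle = float(np.mean(k > 0))
        assert res.posterior_prob == pytest.approx(oracle, abs=0.01)


class TestBuildNetwork:
    def _setup(self, rows):
        nodes = [node("A_1", "A", (0.0, 0.0, 0.0)),
                 node("B_1", "B", (30.0, 0.0, 0.0), "R"),
                 node("C_1", "C", (0.0, 30.0, 0.0))]
        matrix = cn.CoalterationMatrix(
            experiment_ids=[f"E{i}" for i in range(len(rows))],
            node_ids=[n.id for n in nodes], values=np.array(rows))
        return nodes, matrix

    def test_single_significant_pair_leaves_third_isolated(self, rng):
        # A and B always co-altered; C flips independently
        rows = [[1, 1, int(rng.integers(0, 2))] for _ in range(20)]
        rows += [[0, 0, int(rng.integers(0, 2))] for _ in range(20)]
        nodes, matrix = self._setup(rows)
        net = cn.build_network(matrix, nodes, seed=0, n_samples=2000)
        assert set(map(frozenset, net.edges)) == {frozenset(("A_1", "B_1"))}
        assert "C_1" in net.graph.nodes

    def test_kappa_symmetric_across_pair_order(self):
        rng = np.random.default_rng(8)
        rows = rng.integers(0, 2, size=(40, 3)).tolist()
        nodes, matrix = self._setup(rows)
        net = cn.build_network(matrix, nodes, seed=1, n_samples=2000)
        for res in net.results:
            cc = cn.contingency(matrix, res.node_b, res.node_a)
            assert cn.patel_kappa(cc.thetas()) == pytest.approx(res.kappa)

    def test_degenerate_columns_excluded_not_fatal(self):
        rows = [[1, 1, 0], [1, 0, 0], [1, 1, 0], [1, 0, 0]]
        nodes, matrix = self._setup(rows)
        net = cn.build_network(matrix, nodes, seed=0, n_samples=1000)
        assert set(net.excluded) == {"A_1", "C_1"}
        assert net.results == []
        assert set(net.graph.nodes) == {"A_1", "B_1", "C_1"}

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 2, size=(30, 3)).tolist()
        nodes, matrix = self._setup(rows)
        a = cn.build_network(matrix, nodes, seed=5, n_samples=1000)
        b = cn.build_network(matrix, nodes, seed=5, n_samples=1000)
        assert [r.posterior_prob for r in a.results] == \
               [r.posterior_prob for r in b.results]
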