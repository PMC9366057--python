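"""Core network representation: fitting, density, joint, BIC, arc strength."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from mmpibn.errors import DegenerateDensityError, FittingError, StructuralError
from mmpibn.gbn import (Dag, GaussianNetwork, LinearGaussianCpd, arc_strength,
                        bic_score, dag_to_dot, dag_to_graphml, fit_parameters,
                        load_network, log_density, network_from_json,
                        network_to_json, save_network, to_joint_mvn,
                        topological_order)
from mmpibn.simulate import ancestral_sample

from conftest import random_network, z_threshold


class TestDag:
    def test_no_constraints_keeps_canonical_order(self):
        assert topological_order(Dag(("C", "A", "B"))) == ["C", "A", "B"]

    def test_chain_forces_order(self):
        dag = Dag(("C", "A", "B"), frozenset({("A", "B"), ("B", "C")}))
        assert topological_order(dag) == ["A", "B", "C"]

    def test_two_cycle_rejected_naming_cycle(self):
        with pytest.raises(StructuralError, match="cycle"):
            Dag(("A", "B"), frozenset({("A", "B"), ("B", "A")}))

    def test_self_loop_rejected(self):
        with pytest.raises(StructuralError, match="self-loop"):
            Dag(("A",), frozenset({("A", "A")}))

    def test_undeclared_endpoint_rejected(self):
        with pytest.raises(StructuralError, match="undeclared"):
            Dag(("A",), frozenset({("A", "B")}))

    def test_parents_reported_in_canonical_order(self):
        dag = Dag(("B", "A", "C"), frozenset({("A", "C"), ("B", "C")}))
        assert dag.parents("C") == ("B", "A")


class TestFitParameters:
    def test_constant_single_node(self):
        net = fit_parameters(Dag(("X",)), np.full((20, 1), 50.0))
        cpd = net.cpds["X"]
        assert cpd.intercept == 50.0 and cpd.sigma == 0.0

    def test_linear_recovery_large_n(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        y = 2.0 * x + 1.0 + rng.standard_normal(10_000)
        dag = Dag(("X", "Y"), frozenset({("X", "Y")}))
        net = fit_parameters(dag, np.column_stack([x, y]))
        cpd = net.cpds["Y"]
        assert cpd.beta[0] == pytest.approx(2.0, abs=0.05)
        assert cpd.intercept == pytest.approx(1.0, abs=0.6)
        assert cpd.sigma == pytest.approx(1.0, abs=0.05)

    def test_reversed_arc_fits_with_equal_loglik(self):
        """Score equivalence: the two orientations of a single arc give the
        same maximized joint likelihood."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        y = 2.0 * x + 1.0 + rng.standard_normal(500)
        data = np.column_stack([x, y])
        ll = {}
        for arcs in ({("X", "Y")}, {("Y", "X")}):
            net = fit_parameters(Dag(("X", "Y"), frozenset(arcs)), data)
            ll[tuple(arcs)] = sum(log_density(net, row) for row in data)
        a, b = ll.values()
        assert a == pytest.approx(b, abs=1e-8)

    def test_noiseless_data_is_recovered_exactly(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        y = -1.5 * x + 3.0
        dag = Dag(("X", "Y"), frozenset({("X", "Y")}))
        cpd = fit_parameters(dag, np.column_stack([x, y])).cpds["Y"]
        assert cpd.beta[0] == pytest.approx(-1.5, abs=1e-10)
        assert cpd.sigma == pytest.approx(0.0, abs=1e-10)

    def test_collinear_parents_error_names_node(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(100)
        data = pd.DataFrame({"A": a, "B": 2 * a, "C": rng.standard_normal(100)})
        dag = Dag(("A", "B", "C"), frozenset({("A", "C"), ("B", "C")}))
        with pytest.raises(FittingError, match="'C'"):
            fit_parameters(dag, data)

    def test_empty_data_rejected(self):
        with pytest.raises(FittingError):
            fit_parameters(Dag(("X",)), np.empty((0, 1)))


class TestLogDensity:
    def test_standard_normal_at_mode(self):
        net = GaussianNetwork(Dag(("X",)),
                              {"X": LinearGaussianCpd("X", (), (), 0.0, 1.0)})
        assert log_density(net, [0.0]) == pytest.approx(-0.5 * math.log(2 * math.pi))

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_joint_mvn_density(self, seed):
        """The factored density must equal the closed-form joint MVN density."""
        net = random_network(p=min(3 + seed * 2, 13), seed=seed)
        joint = to_joint_mvn(net)
        rng = np.random.default_rng(100 + seed)
        profiles = rng.multivariate_normal(joint.mean, joint.covariance, 100,
                                           method="svd")
        expected = multivariate_normal.logpdf(profiles, joint.mean,
                                              joint.covariance,
                                              allow_singular=True)
        got = np.array([log_density(net, row) for row in profiles])
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_translation_equivariance(self, two_node_net):
        shifted_cpds = {
            "X": LinearGaussianCpd("X", (), (), 10.0, 1.0),
            # Y = 2X + 1: shifting both nodes by 10 changes the intercept
            # by 10 - 2*10 = -10 -> new intercept -9
            "Y": LinearGaussianCpd("Y", ("X",), (2.0,), -9.0, 1.0),
        }
        shifted = GaussianNetwork(two_node_net.dag, shifted_cpds)
        profile = np.array([0.3, 1.9])
        assert log_density(two_node_net, profile) == pytest.approx(
            log_density(shifted, profile + 10.0), abs=1e-12)

    def test_zero_sigma_off_value_is_minus_inf(self):
        net = GaussianNetwork(Dag(("X",)),
                              {"X": LinearGaussianCpd("X", (), (), 5.0, 0.0)})
        assert log_density(net, [4.0]) == float("-inf")

    def test_zero_sigma_on_value_raises(self):
        net = GaussianNetwork(Dag(("X",)),
                              {"X": LinearGaussianCpd("X", (), (), 5.0, 0.0)})
        with pytest.raises(DegenerateDensityError):
            log_density(net, [5.0])


class TestJointMvn:
    def test_two_node_hand_composition(self, two_node_net):
        joint = to_joint_mvn(two_node_net)
        np.testing.assert_allclose(joint.mean, [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(joint.covariance, [[1, 2], [2, 5]], atol=1e-12)

    def test_empty_arcs_give_diagonal_covariance(self):
        net = GaussianNetwork(Dag(("A", "B")), {
            "A": LinearGaussianCpd("A", (), (), 1.0, 2.0),
            "B": LinearGaussianCpd("B", (), (), -1.0, 0.5),
        })
        joint = to_joint_mvn(net)
        np.testing.assert_allclose(joint.covariance, np.diag([4.0, 0.25]))

    def test_ancestral_sample_moments_match(self):
        net = random_network(p=6, seed=42)
        joint = to_joint_mvn(net)
        n = 200_000
        sample = ancestral_sample(net, n, seed=7).to_numpy()
        p = joint.mean.size
        thresh = z_threshold(p + p * (p + 1) // 2)
        se_mean = np.sqrt(np.diag(joint.covariance) / n)
        assert np.all(np.abs(sample.mean(axis=0) - joint.mean) < thresh * se_mean)
        emp_cov = np.cov(sample.T)
        v = np.diag(joint.covariance)
        se_cov = np.sqrt((np.outer(v, v) + joint.covariance ** 2) / n)
        assert np.all(np.abs(emp_cov - joint.covariance) < thresh * se_cov)


class TestBicScore:
    def test_penalty_dominates_for_independent_columns(self):
        empty = Dag(("X", "Y"))
        arc = Dag(("X", "Y"), frozenset({("X", "Y")}))
        wins = 0
        for seed in range(50):
            data = np.random.default_rng(seed).standard_normal((2000, 2))
            if bic_score(empty, data) > bic_score(arc, data):
                wins += 1
        assert wins >= 45

    def test_markov_equivalent_dags_score_equally(self):
        data = np.random.default_rng(5).standard_normal((300, 2)) @ \
            np.array([[1.0, 0.8], [0.0, 1.0]])
        fwd = bic_score(Dag(("X", "Y"), frozenset({("X", "Y")})), data)
        rev = bic_score(Dag(("X", "Y"), frozenset({("Y", "X")})), data)
        assert fwd == pytest.approx(rev, abs=1e-8)

    def test_adding_arc_never_lowers_loglik_term(self):
        from mmpibn.gbn import GaussianSuffStats

        rng = np.random.default_rng(6)
        data = rng.standard_normal((500, 3))
        stats = GaussianSuffStats(data, ("A", "B", "C"))
        base = stats.family_loglik("C", ())
        assert stats.family_loglik("C", ("A",)) >= base - 1e-9
        assert stats.family_loglik("C", ("A", "B")) >= \
            stats.family_loglik("C", ("A",)) - 1e-9

    def test_decomposes_over_families(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((400, 3))
        from mmpibn.gbn import GaussianSuffStats

        nodes = ("A", "B", "C")
        stats = GaussianSuffStats(data, nodes)
        dag = Dag(nodes, frozenset({("A", "B"), ("B", "C")}))
        total = bic_score(dag, data)
        per_family = sum(stats.family_bic(v, dag.parents(v)) for v in nodes)
        assert total == pytest.approx(per_family, abs=1e-10)
        # editing one family changes only that term
        edited = dag.without_arc("B", "C")
        delta = bic_score(edited, data) - total
        assert delta == pytest.approx(
            stats.family_bic("C", ()) - stats.family_bic("C", ("B",)), abs=1e-10)


class TestArcStrength:
    def test_only_present_arcs_reported(self):
        data = np.random.default_rng(8).standard_normal((100, 2))
        dag = Dag(("X", "Y"), frozenset({("X", "Y")}))
        strengths = arc_strength(dag, data)
        assert set(strengths) == {("X", "Y")}

    def test_strong_coupling_gives_positive_strength(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(2000)
        y = 0.95 * x + np.sqrt(1 - 0.95 ** 2) * rng.standard_normal(2000)
        dag = Dag(("X", "Y"), frozenset({("X", "Y")}))
        assert arc_strength(dag, np.column_stack([x, y]))[("X", "Y")] > 0

    def test_independent_pair_gives_negative_strength(self):
        neg = 0
        dag = Dag(("X", "Y"), frozenset({("X", "Y")}))
        for seed in range(50):
            data = np.random.default_rng(200 + seed).standard_normal((2000, 2))
            if arc_strength(dag, data)[("X", "Y")] < 0:
                neg += 1
        assert neg >= 45


class TestPersistence:
    def test_json_round_trip_is_faithful(self, two_node_net):
        doc = json.loads(json.dumps(network_to_json(two_node_net)))
        back = network_from_json(doc)
        assert back.dag.arcs == two_node_net.dag.arcs
        assert back.nodes == two_node_net.nodes
        for node in two_node_net.nodes:
            a, b = two_node_net.cpds[node], back.cpds[node]
            assert a.parents == b.parents
            assert np.allclose(a.beta, b.beta, atol=1e-12)
            assert a.intercept == pytest.approx(b.intercept, abs=1e-12)
            assert a.sigma == pytest.approx(b.sigma, abs=1e-12)

    def test_file_round_trip(self, two_node_net, tmp_path):
        path = tmp_path / "net.json"
        save_network(two_node_net, path)
        assert load_network(path).dag.arcs == two_node_net.dag.arcs

    def test_graph_exports(self, two_node_net, tmp_path):
        import networkx as nx

        strengths = {("X", "Y"): 12.5}
        gpath = tmp_path / "net.graphml"
        dag_to_graphml(two_node_net.dag, gpath, strengths)
        g = nx.read_graphml(gpath)
        assert g.edges["X", "Y"]["strength"] == pytest.approx(12.5)
        dpath = tmp_path / "net.dot"
        dag_to_dot(two_node_net.dag, dpath, strengths)
        text = dpath.read_text()
        assert '"X" -> "Y"' in text and "strength=12.5" in text
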