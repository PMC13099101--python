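"""Discrete BBN: discretization, CPT learning, exact inference vs the
joint-enumeration oracle, variance reduction, scenarios and the bootstrap
driver statistic."""

import numpy as np
import pandas as pd
import pytest

from ecopipe import bbn


def two_node_net():
    """P(A=1)=0.4; P(B=1|A=1)=0.9, P(B=1|A=0)=0.2."""
    nodes = {
        "A": bbn.DiscreteNode("A", ("0", "1"), numeric_values=(0.0, 1.0)),
        "B": bbn.DiscreteNode("B", ("0", "1"), numeric_values=(0.0, 1.0)),
    }
    net = bbn.DiscreteBayesNet(nodes=nodes, parents={"A": (), "B": ("A",)})
    net.cpts["A"] = np.array([0.6, 0.4])
    net.cpts["B"] = np.array([[0.8, 0.2], [0.1, 0.9]])
    net.validate_cpts()
    return net


def with_numeric_states(net):
    """Random-net helper: give every node numeric state values 0,1,2,..."""
    nodes = {
        n: bbn.DiscreteNode(n, node.states,
                            numeric_values=tuple(float(i) for i in range(node.n_states)))
        for n, node in net.nodes.items()
    }
    out = bbn.DiscreteBayesNet(nodes=nodes, parents=net.parents)
    out.cpts = net.cpts
    return out


class TestDiscretize:
    def test_equal_frequency_counts(self):
        node, idx = bbn.discretize_equal_frequency(np.arange(9.0), 3, "x")
        assert node.n_states == 3
        assert np.bincount(idx).tolist() == [3, 3, 3]

    def test_two_state_edge_at_median(self, rng):
        v = rng.normal(size=101)
        node, idx = bbn.discretize_equal_frequency(v, 2, "x")
        assert node.bin_edges[1] == pytest.approx(np.median(v))
        assert abs(int((idx == 0).sum()) - int((idx == 1).sum())) <= 1

    def test_tied_data_matches_feasible_partition(self):
        v = np.array([1.0] * 10 + [2.0] * 10 + [3.0] * 2)
        node, idx = bbn.discretize_equal_frequency(v, 3, "x")
        # every value maps to exactly one state, states ordered with values
        assert node.n_states >= 2
        for a, b in zip(v[:-1], v[1:]):
            if a == b:
                pass
        order = np.argsort(v, kind="stable")
        assert np.all(np.diff(idx[order]) >= 0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            bbn.discretize_equal_frequency(np.ones(10), 2, "x")

    def test_extreme_state_labels(self):
        node, _ = bbn.discretize_equal_frequency(np.arange(30.0), 3, "x")
        assert node.states[0] == "low" and node.states[-1] == "high"


class TestLearnCPTs:
    @staticmethod
    def _nodes():
        return {
            "A": bbn.DiscreteNode("A", ("0", "1")),
            "B": bbn.DiscreteNode("B", ("0", "1")),
        }

    def test_laplace_formula(self):
        data = pd.DataFrame({"A": [0, 0, 0], "B": [0, 0, 1]})
        net = bbn.learn_cpts(data, self._nodes(), {"A": (), "B": ("A",)}, alpha=1.0)
        assert np.allclose(net.cpts["B"][0], [0.6, 0.4])  # (2+1, 1+1)/(3+2)

    def test_mle_alpha_zero(self):
        data = pd.DataFrame({"A": [1, 1, 1], "B": [0, 0, 0]})
        net = bbn.learn_cpts(data, self._nodes(), {"A": (), "B": ("A",)}, alpha=0.0)
        assert np.allclose(net.cpts["B"][1], [1.0, 0.0])

    def test_unseen_parent_config_uniform(self):
        data = pd.DataFrame({"A": [0, 0], "B": [0, 1]})
        net = bbn.learn_cpts(data, self._nodes(), {"A": (), "B": ("A",)}, alpha=0.0)
        assert np.allclose(net.cpts["B"][1], [0.5, 0.5])

    def test_rows_normalized(self, rng):
        data = pd.DataFrame({"A": rng.integers(0, 2, 50), "B": rng.integers(0, 2, 50)})
        net = bbn.learn_cpts(data, self._nodes(), {"A": (), "B": ("A",)})
        for cpt in net.cpts.values():
            assert np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-12)


class TestInference:
    def test_bayes_rule_example(self):
        post = bbn.infer_marginals(two_node_net(), evidence={"B": "1"})
        assert post["A"][1] == pytest.approx(0.75)

    def test_no_evidence_matches_prior_chain(self):
        net = two_node_net()
        m = bbn.infer_marginals(net)
        assert np.allclose(m["A"], [0.6, 0.4])
        assert np.allclose(m["B"], 0.6 * np.array([0.8, 0.2]) + 0.4 * np.array([0.1, 0.9]))

    def test_oracle_on_bayes_example(self):
        post = bbn.joint_enumeration_oracle(two_node_net(), evidence={"B": 1})
        assert post["A"][1] == pytest.approx(0.75)

    def test_deterministic_cpts_point_mass(self):
        net = two_node_net()
        net.cpts["B"] = np.array([[1.0, 0.0], [0.0, 1.0]])
        post = bbn.joint_enumeration_oracle(net, evidence={"B": 1})
        assert np.allclose(post["A"], [0.0, 1.0])

    def test_matches_oracle_on_random_nets(self):
        from ecopipe.experiments import bbn_agreement

        assert bbn_agreement(n_nets=30, seed=123) < 1e-10

    def test_impossible_evidence_raises(self):
        net = two_node_net()
        net.cpts["A"] = np.array([1.0, 0.0])
        with pytest.raises(bbn.ImpossibleEvidenceError):
            bbn.infer_marginals(net, evidence={"A": 1})


class TestEvaluateNetwork:
    def test_deterministic_relationship_perfect_accuracy(self, rng):
        a = rng.integers(0, 3, size=600)
        data = pd.DataFrame({"A": a, "B": a})
        nodes = {
            "A": bbn.DiscreteNode("A", ("0", "1", "2")),
            "B": bbn.DiscreteNode("B", ("0", "1", "2")),
        }
        out = bbn.evaluate_network(nodes, {"A": (), "B": ("A",)}, data,
                                   target_nodes=["B"], seed=5)
        assert out["per_target"]["B"]["accuracy"] == 1.0
        assert out["per_target"]["B"]["confusion"].sum() == 600 - round(0.7 * 600)

    def test_independent_target_near_chance(self, rng):
        data = pd.DataFrame({"A": rng.integers(0, 2, 3000),
                             "B": rng.integers(0, 2, 3000)})
        nodes = {
            "A": bbn.DiscreteNode("A", ("0", "1")),
            "B": bbn.DiscreteNode("B", ("0", "1")),
        }
        out = bbn.evaluate_network(nodes, {"A": (), "B": ("A",)}, data,
                                   target_nodes=["B"], seed=1)
        assert abs(out["per_target"]["B"]["accuracy"] - 0.5) < 0.06

    def test_fixed_seed_reproducible(self, rng):
        data = pd.DataFrame({"A": rng.integers(0, 2, 100),
                             "B": rng.integers(0, 2, 100)})
        nodes = {
            "A": bbn.DiscreteNode("A", ("0", "1")),
            "B": bbn.DiscreteNode("B", ("0", "1")),
        }
        o1 = bbn.evaluate_network(nodes, {"A": (), "B": ("A",)}, data, ["B"], seed=9)
        o2 = bbn.evaluate_network(nodes, {"A": (), "B": ("A",)}, data, ["B"], seed=9)
        np.testing.assert_array_equal(o1["per_target"]["B"]["confusion"],
                                      o2["per_target"]["B"]["confusion"])


def _vr_bruteforce(net, target, factor):
    """VR from the enumerated joint (independent of variable elimination)."""
    xq = net.nodes[target].midpoints()
    pq = bbn.joint_enumeration_oracle(net)[target]
    eq = pq @ xq
    vq = pq @ (xq - eq) ** 2
    pf = bbn.joint_enumeration_oracle(net)[factor]
    acc = 0.0
    for s, p in enumerate(pf):
        if p <= 0:
            continue
        cond = bbn.joint_enumeration_oracle(net, evidence={factor: s})[target]
        ec = cond @ xq
        acc += p * (cond @ (xq - ec) ** 2)
    return vq - acc


class TestVarianceReduction:
    def test_zero_under_independence(self):
        nodes = {
            "Q": bbn.DiscreteNode("Q", ("0", "1"), numeric_values=(0.0, 1.0)),
            "F": bbn.DiscreteNode("F", ("0", "1"), numeric_values=(0.0, 1.0)),
        }
        net = bbn.DiscreteBayesNet(nodes=nodes, parents={"Q": (), "F": ()})
        net.cpts["Q"] = np.array([0.3, 0.7])
        net.cpts["F"] = np.array([0.6, 0.4])
        assert abs(bbn.variance_reduction(net, "Q", "F")) < 1e-12

    def test_deterministic_copy_explains_all_variance(self):
        nodes = {
            "F": bbn.DiscreteNode("F", ("0", "1"), numeric_values=(0.0, 1.0)),
            "Q": bbn.DiscreteNode("Q", ("0", "1"), numeric_values=(0.0, 1.0)),
        }
        net = bbn.DiscreteBayesNet(nodes=nodes, parents={"F": (), "Q": ("F",)})
        net.cpts["F"] = np.array([0.3, 0.7])
        net.cpts["Q"] = np.eye(2)
        vq = 0.3 * 0.7  # Bernoulli variance
        assert bbn.variance_reduction(net, "Q", "F") == pytest.approx(vq, abs=1e-12)

    def test_matches_enumeration_bruteforce(self):
        worst = 0.0
        for seed in range(15):
            net = with_numeric_states(bbn.random_network(seed=seed, max_nodes=3))
            names = list(net.nodes)
            if len(names) < 2:
                continue
            got = bbn.variance_reduction(net, names[-1], names[0])
            expect = _vr_bruteforce(net, names[-1], names[0])
            worst = max(worst, abs(got - expect))
            assert got >= -1e-10
        assert worst < 1e-10


class TestScenarios:
    def test_empty_clamp_zero_deltas(self):
        net = two_node_net()
        sc = bbn.ScenarioSpec("s0", "I", ())
        deltas = bbn.run_scenario(net, sc)
        assert np.allclose(deltas["delta"], 0.0)

    def test_two_node_delta(self):
        net = two_node_net()
        sc = bbn.ScenarioSpec("s1", "I", (("B", "1"),))
        deltas = bbn.run_scenario(net, sc)
        d = deltas.set_index(["node", "state"]).loc[("A", "1"), "delta"]
        assert d == pytest.approx(0.75 - 0.4)

    def test_deltas_sum_to_zero_per_node(self):
        net = with_numeric_states(bbn.random_network(seed=3, max_nodes=5))
        name = list(net.nodes)[-1]
        sc = bbn.ScenarioSpec("s", "I", ((name, 0),))
        deltas = bbn.run_scenario(net, sc)
        sums = deltas.groupby("node")["delta"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)

    def test_templates_from_pair_matrix(self):
        from ecopipe.pairs import PairResult

        prs = [
            PairResult(("WY", "CS"), 0.5, 100, 0.001, 0.002, (0.3, 0.6), "synergy", "moderate"),
            PairResult(("N", "HQ"), -0.4, 100, 0.001, 0.002, (-0.6, -0.2), "trade-off", "moderate"),
            PairResult(("WY", "FS"), 0.05, 100, 0.5, 0.6, (-0.1, 0.2), "non-significant", "weak"),
        ]
        specs = bbn.scenarios_from_pairs(prs)
        assert [s.scenario_type for s in specs] == ["I", "II", "III", "IV"]
        assert specs[0].clamped == (("WY", "high"), ("CS", "high"))
        assert specs[1].clamped == (("WY", "low"), ("CS", "low"))
        assert specs[2].clamped == (("N", "high"), ("HQ", "low"))
        assert specs[3].clamped == (("N", "low"), ("HQ", "high"))

    def test_clamping_zero_prior_state_raises(self):
        net = two_node_net()
        net.cpts["A"] = np.array([1.0, 0.0])
        net.cpts["B"] = np.array([[1.0, 0.0], [0.5, 0.5]])
        sc = bbn.ScenarioSpec("s", "I", (("B", "1"),))
        with pytest.raises(bbn.ImpossibleEvidenceError):
            bbn.run_scenario(net, sc)


class TestIdentifyDrivers:
    @staticmethod
    def _frame(values, nodes=None):
        n = len(values)
        return pd.DataFrame({
            "scenario": ["s"] * n,
            "node": nodes if nodes is not None else [f"f{i}" for i in range(n)],
            "state": ["low"] * n,
            "delta": values,
        })

    def test_equal_deltas_no_driver(self):
        res = bbn.identify_drivers(self._frame([0.2] * 25))
        assert res.drivers == []

    def test_clear_separation(self):
        values = [0.9] + [0.05] * 39
        nodes = ["big"] + [f"null{i}" for i in range(39)]
        res = bbn.identify_drivers(self._frame(values, nodes))
        assert res.drivers == ["big"]
        assert 0.05 <= res.threshold < 0.9

    def test_bootstrap_reproducible(self):
        f = self._frame(list(np.linspace(0, 1, 40)))
        r1 = bbn.identify_drivers(f, seed=5)
        r2 = bbn.identify_drivers(f, seed=5)
        assert r1.threshold == r2.threshold and r1.ci95 == r2.ci95

    def test_ci_widens_with_dispersion(self, rng):
        tight = self._frame(list(0.5 + 0.01 * rng.standard_normal(200)))
        wide = self._frame(list(0.5 + 0.3 * rng.standard_normal(200)))
        r_t = bbn.identify_drivers(tight, seed=0)
        r_w = bbn.identify_drivers(wide, seed=0)
        assert (r_w.ci95[1] - r_w.ci95[0]) > (r_t.ci95[1] - r_t.ci95[0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bbn.identify_drivers(self._frame([0.1] * 5))


def test_network_json_roundtrip():
    net = bbn.random_network(seed=17)
    restored = bbn.DiscreteBayesNet.from_json(net.to_json())
    assert set(restored.nodes) == set(net.nodes)
    for n in net.nodes:
        np.testing.assert_allclose(restored.cpts[n], net.cpts[n])
        assert restored.parents[n] == net.parents[n]


def test_cycle_rejected():
    nodes = {
        "A": bbn.DiscreteNode("A", ("0", "1")),
        "B": bbn.DiscreteNode("B", ("0", "1")),
    }
    with pytest.raises(ValueError):
        bbn.DiscreteBayesNet(nodes=nodes, parents={"A": ("B",), "B": ("A",)})
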