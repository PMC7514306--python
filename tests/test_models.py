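"""Factorization, interventions, conditioning, sampling, and fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

import causalinfo as ci
from causalinfo import (
    ChainGraph,
    ComponentTable,
    DiscreteModel,
    InputError,
    ModelValidationError,
    ResourceCapError,
    ZeroProbabilityError,
    fit_empirical,
    intervene,
    joint_table,
    random_model,
    sample,
)
from causalinfo.config import options

from conftest import random_binary_model


def _two_node_manual(px=0.3, py_given=(0.8, 0.4)):
    g = ChainGraph("XY", [("X", "Y")])
    tables = [
        ComponentTable(("X",), (), np.array([1 - px, px])),
        ComponentTable(("Y",), ("X",), np.array(
            [[1 - py_given[0], py_given[0]], [1 - py_given[1], py_given[1]]])),
    ]
    return DiscreteModel(g, {"X": (0, 1), "Y": (0, 1)}, tables)


class TestJointTable:
    def test_two_node_product(self):
        m = _two_node_manual()
        t = joint_table(m)
        assert t.probs[1, 0] == pytest.approx(0.3 * 0.6)
        assert t.probs.sum() == pytest.approx(1.0)

    def test_chain_graph_with_singletons_reproduces_dag_product(self):
        m = random_binary_model(7, 5)
        t = joint_table(m)
        # recompute the product by explicit enumeration of node conditionals
        for vals in itertools.product((0, 1), repeat=5):
            assign = dict(zip(m.graph.nodes, vals))
            p = 1.0
            for v in m.graph.nodes:
                ct = m.component_table(v)
                idx = tuple(assign[u] for u in ct.parents) + (assign[v],)
                p *= ct.probs[idx]
            assert t.prob(assign) == pytest.approx(p, abs=1e-12)

    def test_chain_component_factor_used_jointly(self):
        # one 2-node component P(A,B) given parent C
        g = ChainGraph("CAB", [("C", "A"), ("C", "B")], [("A", "B")])
        comp = np.array([[[0.1, 0.2], [0.3, 0.4]], [[0.4, 0.3], [0.2, 0.1]]])
        tables = [ComponentTable(("C",), (), np.array([0.6, 0.4])),
                  ComponentTable(("A", "B"), ("C",), comp)]
        m = DiscreteModel(g, {v: (0, 1) for v in "CAB"}, tables)
        t = joint_table(m)
        assert t.prob({"C": 1, "A": 0, "B": 1}) == pytest.approx(0.4 * 0.3)

    def test_state_space_cap(self):
        m = random_binary_model(0, 6)
        old = options.state_space_cap
        options.state_space_cap = 10
        try:
            with pytest.raises(ResourceCapError):
                joint_table(m)
        finally:
            options.state_space_cap = old

    def test_bad_row_sum_rejected_with_location(self):
        g = ChainGraph("XY", [("X", "Y")])
        with pytest.raises(ModelValidationError, match="row"):
            DiscreteModel(g, {"X": (0, 1), "Y": (0, 1)}, [
                ComponentTable(("X",), (), np.array([0.5, 0.5])),
                ComponentTable(("Y",), ("X",), np.array([[0.5, 0.4], [0.5, 0.5]])),
            ])


class TestIntervene:
    def test_do_on_root_selects_cpt_row(self):
        m = _two_node_manual()
        t = intervene(m, {"X": 1}).marginal(["Y"])
        assert t.probs[1] == pytest.approx(0.4)

    def test_adjusting_for_direct_causes_identity(self, triangle):
        # do(X=x) marginal of Y equals sum_z P(Y|x,z) P(z)
        t = joint_table(triangle)
        for x in (0, 1):
            got = intervene(triangle, {"X": x}).marginal(["Y"]).probs
            want = np.zeros(2)
            for z in (0, 1):
                pz = t.marginal(["Z"]).probs[z]
                py = t.condition({"X": x, "Z": z}).marginal(["Y"]).probs
                want += pz * py
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_empty_do_is_observational(self, triangle):
        np.testing.assert_allclose(
            intervene(triangle, {}).probs, joint_table(triangle).probs)

    def test_point_mass_on_intervened_nodes(self, triangle):
        t = intervene(triangle, {"X": 1})
        assert t.marginal(["X"]).probs[0] == pytest.approx(0.0)
        assert t.marginal(["X"]).probs[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_modularity(self, seed):
        # conditional of a non-intervened node given its parents is invariant
        m = random_binary_model(seed, 5)
        nodes = m.graph.nodes
        do = {nodes[0]: 1, nodes[2]: 0}
        t = intervene(m, do)
        for w in nodes:
            if w in do:
                continue
            ct = m.component_table(w)
            for pa_vals in itertools.product((0, 1), repeat=len(ct.parents)):
                event = dict(zip(ct.parents, pa_vals))
                try:
                    cond = t.condition(event).marginal([w]).probs
                except ZeroProbabilityError:
                    continue  # parent configuration unreachable post-do
                np.testing.assert_allclose(cond, ct.probs[pa_vals], atol=1e-9)

    def test_chain_graph_partial_component_intervention(self):
        # do on one member of a 2-node component conditions the other
        g = ChainGraph("AB", [], [("A", "B")])
        comp = np.array([[0.1, 0.2], [0.3, 0.4]])
        m = DiscreteModel(g, {"A": (0, 1), "B": (0, 1)},
                          [ComponentTable(("A", "B"), (), comp)])
        t = intervene(m, {"A": 1})
        np.testing.assert_allclose(
            t.marginal(["B"]).probs, comp[1] / comp[1].sum(), atol=1e-12)

    def test_value_not_in_domain(self, two_node):
        with pytest.raises(InputError):
            intervene(two_node, {"X": 7})


class TestMarginalCondition:
    def test_marginal_identity_empty_and_factor(self, triangle):
        t = joint_table(triangle)
        np.testing.assert_allclose(t.marginal(t.variables).probs, t.probs)
        assert t.marginal([]).probs == pytest.approx(1.0)
        # an independent product table marginalizes to its stored factor
        m = _two_node_manual()
        t2 = joint_table(m)
        np.testing.assert_allclose(t2.marginal(["X"]).probs, [0.7, 0.3])

    def test_condition_uniform_pair_and_full_assignment(self):
        g = ChainGraph("XY", [])
        m = DiscreteModel(g, {"X": (0, 1), "Y": (0, 1)}, [
            ComponentTable(("X",), (), np.array([0.5, 0.5])),
            ComponentTable(("Y",), (), np.array([0.5, 0.5]))])
        t = joint_table(m)
        np.testing.assert_allclose(t.condition({"X": 0}).probs, [0.5, 0.5])
        assert t.condition({"X": 0, "Y": 1}).probs == pytest.approx(1.0)

    def test_zero_probability_event_raises(self):
        m = _two_node_manual(px=0.0)
        with pytest.raises(ZeroProbabilityError):
            joint_table(m).condition({"X": 1})

    def test_condition_after_intervene_is_explicit_ratio(self, triangle):
        # P(X,Z | do(Y)) / P(Z | do(Y)) computed both ways
        t = intervene(triangle, {"Y": 1})
        got = t.condition({"Z": 1}).marginal(["X"]).probs
        num = t.marginal(["Z", "X"]).probs[1, :]  # axis order Z,X in node order
        den = t.marginal(["Z"]).probs[1]
        np.testing.assert_allclose(got, num / den, atol=1e-12)


class TestSampleFit:
    def test_empty_and_reproducible(self, two_node):
        assert len(sample(two_node, 0, 1)) == 0
        a = sample(two_node, 500, 42)
        b = sample(two_node, 500, 42)
        pd.testing.assert_frame_equal(a, b)

    def test_frequencies_match_joint_within_3se(self, triangle):
        n = 200_000
        df = sample(triangle, n, 7)
        t = joint_table(triangle)
        counts = df.value_counts()
        for vals in itertools.product((0, 1), repeat=3):
            p = t.prob(dict(zip(t.variables, vals)))
            se = np.sqrt(p * (1 - p) / n)
            obs = counts.get(vals, 0) / n
            assert abs(obs - p) < 3 * se + 1e-12, vals

    def test_chain_graph_sampling_matches_joint(self):
        g = ChainGraph("CAB", [("C", "A"), ("C", "B")], [("A", "B")])
        comp = np.array([[[0.1, 0.2], [0.3, 0.4]], [[0.4, 0.3], [0.2, 0.1]]])
        m = DiscreteModel(g, {v: (0, 1) for v in "CAB"}, [
            ComponentTable(("C",), (), np.array([0.6, 0.4])),
            ComponentTable(("A", "B"), ("C",), comp)])
        n = 100_000
        df = sample(m, n, 3)
        t = joint_table(m)
        for vals in itertools.product((0, 1), repeat=3):
            p = t.prob(dict(zip(t.variables, vals)))
            obs = ((df["C"] == vals[0]) & (df["A"] == vals[1])
                   & (df["B"] == vals[2])).mean()
            assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-12

    def test_exact_recovery_from_enumerated_dataset(self):
        m = _two_node_manual(px=0.25, py_given=(0.5, 0.75))
        # 16 rows realizing the joint exactly: P scaled by 16 is integral
        rows = []
        t = joint_table(m)
        for vals in itertools.product((0, 1), repeat=2):
            k = round(t.prob(dict(zip("XY", vals))) * 16)
            rows += [vals] * k
        df = pd.DataFrame(rows, columns=["X", "Y"])
        fitted = fit_empirical(df, m.graph, m.domains)
        for key in m.tables:
            np.testing.assert_allclose(fitted.tables[key].probs,
                                       m.tables[key].probs, atol=1e-12)

    def test_fit_of_large_sample_is_close(self, triangle):
        df = sample(triangle, 100_000, 5)
        fitted = fit_empirical(df, triangle.graph, triangle.domains)
        for key in triangle.tables:
            np.testing.assert_allclose(fitted.tables[key].probs,
                                       triangle.tables[key].probs, atol=0.02)

    def test_empty_dataset_gives_flagged_uniform(self, two_node):
        df = pd.DataFrame({"X": [], "Y": []})
        fitted = fit_empirical(df, two_node.graph, two_node.domains)
        np.testing.assert_allclose(fitted.tables[("X",)].probs, [0.5, 0.5])
        np.testing.assert_allclose(fitted.tables[("Y",)].probs, 0.5)
        assert fitted.meta["uniform_rows"]

    def test_out_of_domain_value_rejected(self, two_node):
        df = pd.DataFrame({"X": [0, 2], "Y": [0, 1]})
        with pytest.raises(InputError):
            fit_empirical(df, two_node.graph, two_node.domains)


class TestRandomModel:
    def test_reproducible_and_row_stochastic(self):
        g = ChainGraph("ABC", [("A", "B"), ("B", "C")])
        doms = {v: (0, 1, 2) for v in "ABC"}
        m1 = random_model(g, doms, seed=9)
        m2 = random_model(g, doms, seed=9)
        for key in m1.tables:
            np.testing.assert_array_equal(m1.tables[key].probs,
                                          m2.tables[key].probs)
            member_axes = tuple(range(len(m1.tables[key].parents),
                                      m1.tables[key].probs.ndim))
            np.testing.assert_allclose(
                m1.tables[key].probs.sum(axis=member_axes), 1.0, atol=1e-12)

    def test_high_alpha_concentrates_on_uniform(self):
        g = ChainGraph("AB", [("A", "B")])
        doms = {"A": (0, 1), "B": (0, 1)}
        devs = []
        for alpha in (1.0, 50.0, 5000.0):
            m = random_model(g, doms, seed=2, alpha=alpha)
            dev = max(float(np.abs(ct.probs - 0.5).max())
                      for ct in m.tables.values())
            devs.append(dev)
        assert devs[0] > devs[1] > devs[2]
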