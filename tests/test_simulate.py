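"""Ideal-L3-graph construction, perturbation simulations, trace statistics
and the duplication-mutation generator."""

import itertools
import random

import numpy as np
import pytest

import l3npred as L
from l3npred.simulate import SimulationTrace, _derive_seed

from conftest import er_network


class TestBuildIdealL3:
    def test_node_and_edge_counts(self):
        g = L.build_ideal_l3(50, 50)
        assert len(g.net) == 102
        assert g.net.edge_count == 50 * 50 + 50 + 50

    def test_smallest_is_a_path(self):
        g = L.build_ideal_l3(1, 1)
        assert g.net.edge_count == 3
        assert L.count_p4(g.net, "x", "y") == 1

    def test_rectangular_p4_count(self):
        g = L.build_ideal_l3(2, 3)
        assert L.count_p4(g.net, "x", "y") == 6

    def test_elements_match_construction(self):
        g = L.build_ideal_l3(3, 3)
        elems = L.l3_elements(g.net, "x", "y")
        assert elems.U == frozenset(g.U) and elems.V == frozenset(g.V)

    @pytest.mark.parametrize("nu,nv", [(0, 3), (3, 0), (-1, 2)])
    def test_invalid_sizes(self, nu, nv):
        with pytest.raises(ValueError):
            L.build_ideal_l3(nu, nv)


class TestClassifyEdges:
    def test_fifty_fifty_inventory(self):
        compatible, incompatible = L.classify_edges(L.build_ideal_l3(50, 50))
        assert len(compatible) == 2450
        assert len(incompatible) == 2550

    def test_smallest_case(self):
        compatible, incompatible = L.classify_edges(L.build_ideal_l3(1, 1))
        assert len(compatible) == 0
        assert incompatible == {frozenset(("x", "v0")), frozenset(("y", "u0"))}

    def test_two_by_two_brute_force(self):
        g = L.build_ideal_l3(2, 2)
        compatible, incompatible = L.classify_edges(g)
        # brute enumeration of the definitions
        expect_comp = {
            frozenset((u, v))
            for u in g.U for v in g.V
            if frozenset((u, v)) not in {frozenset(e) for e in g.matching}
        }
        expect_incomp = (
            {frozenset(p) for p in itertools.combinations(g.U, 2)}
            | {frozenset(p) for p in itertools.combinations(g.V, 2)}
            | {frozenset(("x", v)) for v in g.V}
            | {frozenset(("y", u)) for u in g.U}
        )
        assert compatible == expect_comp and len(compatible) == 2
        assert incompatible == expect_incomp and len(incompatible) == 6

    def test_partition_properties(self):
        g = L.build_ideal_l3(4, 5)
        compatible, incompatible = L.classify_edges(g)
        assert not compatible & incompatible
        assert frozenset(("x", "y")) not in compatible | incompatible
        assert len(compatible) == 4 * 5 - 4
        assert len(incompatible) == 6 + 10 + 4 + 5
        # compatible edges all exist in the ideal graph; incompatible do not
        for e in compatible:
            assert g.net.has_edge(*tuple(e))
        for e in incompatible:
            assert not g.net.has_edge(*tuple(e))


class TestRemovalSimulation:
    def test_trace_shape_and_endpoints(self):
        g = L.build_ideal_l3(5, 5)
        trace = L.run_removal_sim(g, ["p4", "l3"], repeats=3, seed=1)
        T = 5 * 5 - 5
        assert trace.raw["p4"].shape == (3, T + 1)
        # iteration 0: ideal graph; final: only the protected matching remains
        assert np.all(trace.raw["p4"][:, 0] == 25)
        assert np.all(trace.raw["p4"][:, -1] == 5)
        assert np.all(trace.raw["l3"][:, 0] == pytest.approx(25 / 6))

    def test_iteration_zero_matches_closed_forms(self):
        n = 6
        g = L.build_ideal_l3(n, n)
        names = ["p4", "l3", "sim", "l3n_f1", "l3n_f2", "l3n_prime_f1", "ch2"]
        trace = L.run_removal_sim(g, names, repeats=1, seed=0)
        q = n / (n + 1)
        expected = {
            "p4": n**2, "l3": n**2 / (n + 1), "sim": 2 * n**2 / (n + 1),
            "l3n_f1": n**2, "l3n_f2": n**2,
            "l3n_prime_f1": n**2 * q**2, "ch2": n**2 * (n + 1),
        }
        for name, value in expected.items():
            assert trace.raw[name][0, 0] == pytest.approx(value)

    def test_hand_stepped_replay(self):
        """The full trace equals an independent replay of the same seed."""
        g = L.build_ideal_l3(2, 2)
        trace = L.run_removal_sim(g, ["p4"], repeats=1, seed=42)
        compatible, _ = L.classify_edges(g)
        order = sorted(tuple(sorted(e)) for e in compatible)
        random.Random(_derive_seed(42, 0, 0)).shuffle(order)
        net = g.net.copy()
        expected = [L.count_p4(net, "x", "y")]
        for a, b in order:
            net.remove_edge(a, b)
            expected.append(L.count_p4(net, "x", "y"))
        assert trace.raw["p4"][0].tolist() == expected

    def test_empty_predictor_list_rejected(self):
        with pytest.raises(ValueError):
            L.run_removal_sim(L.build_ideal_l3(2, 2), [])

    def test_rand_cannot_be_traced(self):
        with pytest.raises(ValueError):
            L.run_removal_sim(L.build_ideal_l3(2, 2), ["rand"])


class TestInsertionSimulation:
    def test_trace_length_is_incompatible_count(self):
        g = L.build_ideal_l3(3, 3)
        trace = L.run_insertion_sim(g, ["p4"], repeats=2, seed=5)
        T = 3 + 3 + 3 + 3  # C(3,2)*2 + 3 + 3
        assert trace.raw["p4"].shape == (2, T + 1)

    def test_control_raw_trace_is_nondecreasing(self):
        """P4 counts are monotone under edge insertion, deterministically."""
        g = L.build_ideal_l3(4, 4)
        trace = L.run_insertion_sim(g, ["p4"], repeats=3, seed=2)
        assert np.all(np.diff(trace.raw["p4"], axis=1) >= 0)

    def test_hand_stepped_replay(self):
        g = L.build_ideal_l3(2, 2)
        trace = L.run_insertion_sim(g, ["l3"], repeats=1, seed=9)
        _, incompatible = L.classify_edges(g)
        order = sorted(tuple(sorted(e)) for e in incompatible)
        random.Random(_derive_seed(9, 1, 0)).shuffle(order)
        net = g.net.copy()
        expected = [L.score_l3(net, "x", "y")]
        for a, b in order:
            net.add_edge(a, b)
            expected.append(L.score_l3(net, "x", "y"))
        assert trace.raw["l3"][0].tolist() == pytest.approx(expected)

    def test_freeze_elements_differs_from_recompute(self):
        g = L.build_ideal_l3(3, 3)
        live = L.run_insertion_sim(g, ["p4"], repeats=1, seed=4)
        frozen = L.run_insertion_sim(g, ["p4"], repeats=1, seed=4, freeze_elements=True)
        # same edit order (same seed); frozen scoring pins U, V so the
        # trajectories must eventually disagree
        assert not np.allclose(live.raw["p4"][0], frozen.raw["p4"][0])


def _manual_trace(rows: dict[str, list[list[float]]], kind="removal") -> SimulationTrace:
    raw = {k: np.array(v, dtype=float) for k, v in rows.items()}
    T = next(iter(raw.values())).shape[1]
    return SimulationTrace(kind=kind, iterations=np.arange(T), raw=raw, seed=0)


class TestTraceStatistics:
    def test_normalize_max_is_one(self):
        g = L.build_ideal_l3(3, 3)
        trace = L.normalize_trace(L.run_removal_sim(g, ["p4", "l3"], repeats=2, seed=0))
        for name in trace.predictors:
            assert np.allclose(trace.normalized[name].max(axis=1), 1.0)

    def test_normalize_constant_and_zero(self):
        t = _manual_trace({"a": [[2.0, 2.0, 2.0]], "b": [[0.0, 0.0, 0.0]]})
        t = L.normalize_trace(t)
        assert np.allclose(t.normalized["a"], 1.0)
        assert np.allclose(t.normalized["b"], 0.0)

    def test_removal_l3n_starts_at_maximum(self):
        g = L.build_ideal_l3(6, 6)
        trace = L.normalize_trace(
            L.run_removal_sim(g, ["l3n_f1", "l3n_prime_f2"], repeats=2, seed=3)
        )
        for name in trace.predictors:
            assert np.allclose(trace.normalized[name][:, 0], 1.0)

    def test_auc_constant_is_one(self):
        t = L.normalize_trace(_manual_trace({"a": [[5.0] * 10]}))
        assert L.trace_auc(t)["a"] == pytest.approx(1.0)

    def test_auc_linear_descent_is_half(self):
        t = L.normalize_trace(_manual_trace({"a": [np.linspace(1, 0, 11).tolist()]}))
        assert L.trace_auc(t)["a"] == pytest.approx(0.5)

    def test_partial_auc_from_v_minimum(self):
        # V shape: descend 1..0 over 5 points, ascend back over 4
        traj = [1.0, 0.75, 0.5, 0.25, 0.0, 0.25, 0.5, 0.75, 1.0]
        t = L.normalize_trace(_manual_trace({"a": [traj]}))
        partial = L.trace_auc(t, mode="partial-from-min")["a"]
        x = np.linspace(0, 1, 5)
        assert partial == pytest.approx(float(np.trapezoid([0, 0.25, 0.5, 0.75, 1.0], x)))

    def test_auc_requires_two_points(self):
        t = L.normalize_trace(_manual_trace({"a": [[1.0]]}))
        with pytest.raises(ValueError):
            L.trace_auc(t)

    def test_auc_unknown_mode(self):
        t = L.normalize_trace(_manual_trace({"a": [[1.0, 0.5]]}))
        with pytest.raises(ValueError):
            L.trace_auc(t, mode="banana")


class TestSmoothing:
    def test_cubic_polynomial_reproduced_exactly(self):
        x = np.arange(40, dtype=float)
        poly = 0.01 * x**3 - 0.3 * x**2 + 2 * x + 5
        t = _manual_trace({"a": [poly.tolist()]})
        sm = L.smooth_trace(t, window=21, polyorder=3)
        assert np.allclose(sm.raw["a"][0], poly, atol=1e-6)

    def test_constant_unchanged(self):
        t = _manual_trace({"a": [[3.0] * 30]})
        sm = L.smooth_trace(t)
        assert np.allclose(sm.raw["a"], 3.0)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 4 * np.pi, 200)
        clean = np.sin(x)
        noisy = clean + rng.normal(0, 0.3, x.size)
        t = _manual_trace({"a": [noisy.tolist()]})
        sm = L.smooth_trace(t, window=21, polyorder=3)
        assert np.var(sm.raw["a"][0] - clean) < np.var(noisy - clean)

    @pytest.mark.parametrize("window,order", [(20, 3), (5, 7), (101, 3)])
    def test_invalid_window(self, window, order):
        t = _manual_trace({"a": [[1.0] * 30]})
        with pytest.raises(ValueError):
            L.smooth_trace(t, window=window, polyorder=order)


class TestDuplicationMutationGenerator:
    def test_perfect_twins_when_all_edges_kept(self):
        net = L.generate_dmc_network(20, p_keep=1.0, p_anchor=0.0, seed=1)
        assert len(net) == 20
        # with certain retention and no anchors, duplicates are exact twins
        # of their parents, and twin classes persist under later growth
        twins = [
            (a, b)
            for a in net.nodes for b in net.nodes
            if a < b and net.neighbors(a) == net.neighbors(b)
        ]
        assert twins, "expected at least one perfect-twin pair"

    def test_deterministic_under_seed(self):
        a = L.generate_dmc_network(60, seed=7)
        b = L.generate_dmc_network(60, seed=7)
        assert list(a.edges()) == list(b.edges())

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            L.generate_dmc_network(50, p_keep=1.5)
        with pytest.raises(ValueError):
            L.generate_dmc_network(2)

    def test_heavier_degree_tail_than_er(self):
        net = L.generate_dmc_network(400, p_keep=0.7, p_anchor=0.1, seed=11)
        degrees = np.array([net.degree(n) for n in net.nodes])
        er = er_network(400, 2 * net.edge_count / (400 * 399), seed=11)
        er_deg = np.array([er.degree(n) for n in er.nodes])
        tail = (degrees > 3 * degrees.mean()).mean()
        er_tail = (er_deg > 3 * er_deg.mean()).mean()
        assert tail > er_tail

    def test_gadget_network_truth_edges(self):
        net, truth = L.build_gadget_network(n_gadgets=3, n_side=3, seed=0)
        assert len(truth) == 3
        for e in truth:
            assert net.has_edge(*tuple(e))
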