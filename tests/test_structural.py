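"""Loops, forward paths, motif classes and the three-node controller algebra."""

import numpy as np
import pytest

from adaptscan.fixtures import get_fixture
from adaptscan.network import SignedDigraph
from adaptscan.structural import (ThreeNodeClosedLoop, classify_motif,
                                  decompose_det_3node, find_forward_paths,
                                  find_loops, table1_conditions,
                                  theorem2_edge_check)
from conftest import brute_force_cycles, brute_force_paths, random_signed_graph


class TestLoops:
    def test_three_cycle_sign(self):
        g = SignedDigraph(("A", "B", "C"),
                          {("A", "B"): 1, ("B", "C"): 1, ("C", "A"): -1},
                          "A", "C")
        loops = find_loops(g)
        assert len(loops) == 1
        assert loops[0].cycle == ("A", "B", "C") and loops[0].sign == -1
        assert loops[0].contains_output_to_input_edge  # C -> A is output -> input

    def test_acyclic_graph_empty(self):
        assert find_loops(get_fixture("ifflp3").graph) == []

    def test_nfblb_loop_is_admissible(self):
        loops = find_loops(get_fixture("nfblb3_bc").graph)
        assert len(loops) == 1
        lp = loops[0]
        assert set(lp.cycle) == {"B", "C"} and lp.sign == -1
        assert not lp.contains_output_to_input_edge

    def test_matches_brute_force_oracle(self, rng):
        for n in (3, 4):
            for _ in range(25):
                g = random_signed_graph(rng, n, p_edge=0.5)
                got = {(l.cycle, l.sign) for l in find_loops(g)}
                assert got == brute_force_cycles(g)


class TestForwardPaths:
    def test_ifflp_two_opposing_paths(self):
        paths = find_forward_paths(get_fixture("ifflp3").graph)
        assert {(p.path, p.sign) for p in paths} == {
            (("A", "C"), 1), (("A", "B", "C"), -1)}

    def test_unreachable_output_empty(self):
        g = SignedDigraph(("A", "B", "C"), {("B", "C"): 1}, "A", "C")
        assert find_forward_paths(g) == []
        assert not classify_motif(g).input_output_connected

    def test_coherent_paths_share_sign(self):
        paths = find_forward_paths(get_fixture("coherent_ff3").graph)
        assert {p.sign for p in paths} == {1}

    def test_matches_brute_force_oracle(self, rng):
        for n in (3, 4):
            for _ in range(25):
                g = random_signed_graph(rng, n, p_edge=0.5)
                got = {(p.path, p.sign) for p in find_forward_paths(g)}
                assert got == brute_force_paths(g)


class TestEdgeCount:
    @pytest.mark.parametrize("n, n_edges, expected", [
        (3, 2, False), (3, 3, True), (5, 4, False), (2, 1, True)])
    def test_minimum_edges(self, n, n_edges, expected):
        nodes = tuple(chr(ord("A") + i) for i in range(n))
        edges = {(nodes[i], nodes[i + 1]): 1 for i in range(n_edges)} \
            if n_edges < n else \
            {(nodes[i], nodes[(i + 1) % n]): 1 for i in range(n_edges)}
        g = SignedDigraph(nodes, edges, nodes[0], nodes[-1])
        assert theorem2_edge_check(g) is expected


class TestMotifClassification:
    def test_ifflp_class(self):
        rep = classify_motif(get_fixture("ifflp3").graph)
        assert rep.motif_class == "IFFLP"
        assert rep.has_incoherent_feedforward
        assert not rep.has_admissible_negative_feedback
        assert rep.necessary_condition_met and not rep.excluded

    def test_nfblb_class(self):
        rep = classify_motif(get_fixture("nfblb3_bc").graph)
        assert rep.motif_class == "NFBLB" and not rep.excluded

    def test_combined_class(self):
        rep = classify_motif(get_fixture("iffl_nfb3").graph)
        assert rep.motif_class == "BOTH"

    def test_loop_through_output_input_edge_not_admissible(self):
        # negative loop exactly {input -> output, output -> input}: the only
        # feedback runs through the output -> input edge, so it cannot count
        g = SignedDigraph(("A", "B"), {("A", "B"): 1, ("B", "A"): -1}, "A", "B")
        rep = classify_motif(g)
        assert len(rep.loops) == 1 and rep.loops[0].sign == -1
        assert rep.loops[0].contains_output_to_input_edge
        assert not rep.has_admissible_negative_feedback
        assert not rep.necessary_condition_met and rep.excluded

    def test_all_positive_network_excluded(self):
        g = SignedDigraph(("A", "B", "C"),
                          {("A", "B"): 1, ("B", "C"): 1, ("C", "A"): 1,
                           ("A", "C"): 1}, "A", "C")
        rep = classify_motif(g)
        assert rep.motif_class == "NONE" and rep.excluded

    def test_report_invariant(self, rng):
        for _ in range(50):
            rep = classify_motif(random_signed_graph(rng, 3))
            assert rep.necessary_condition_met == (
                rep.has_admissible_negative_feedback
                or rep.has_incoherent_feedforward)


class TestTable1:
    def base(self, **kw):
        vals = dict(a11=-1.0, a12=0.0, a21=1.0, a22=-1.0, beta1=1.0,
                    beta2=0.0, beta3=0.0, alpha_ab=0.0, alpha_cb=0.0,
                    alpha_bb=0.0)
        vals.update(kw)
        return ThreeNodeClosedLoop(**vals)

    def test_negative_feedback_buffer_output(self):
        flags = table1_conditions(self.base(alpha_cb=1.0, beta3=-1.0))
        assert flags["negative_feedback_b_c"]
        assert not flags["gross_negative_feedback"]

    def test_gross_negative_feedback(self):
        flags = table1_conditions(self.base(a21=1.0, alpha_cb=1.0, beta2=-1.0))
        assert flags["gross_negative_feedback"]

    def test_negative_feedback_input_buffer(self):
        flags = table1_conditions(self.base(alpha_ab=-1.0, beta2=1.0))
        assert flags["negative_feedback_a_b"]

    def test_unobservable_output_rejected(self):
        flags = table1_conditions(self.base(a21=0.0, beta3=0.0, alpha_ab=1.0,
                                            alpha_bb=1.0))
        assert flags["rejected"] is not None
        assert "uncontrollable" in flags["rejected"] or "unobservable" in flags["rejected"]

    def test_all_zero_balance_rejected(self):
        flags = table1_conditions(self.base(a21=0.0, alpha_bb=0.0, beta3=0.0,
                                            alpha_ab=0.0))
        assert flags["rejected"] is not None and "singular" in flags["rejected"]

    def test_incoherent_balance_accepted(self):
        # a21 * alpha_bb = beta3 * alpha_ab = -1 != 0 with opposing routes
        flags = table1_conditions(self.base(a21=1.0, alpha_bb=-1.0, beta3=1.0,
                                            alpha_ab=-1.0))
        assert flags["balance"] == 0.0
        assert flags["incoherent_feedforward"]
        assert flags["rejected"] is None

    def test_a_cl_layout(self):
        p = self.base(beta2=2.0, beta3=3.0, alpha_ab=4.0, alpha_cb=5.0,
                      alpha_bb=6.0)
        assert p.a_cl() == pytest.approx(np.array(
            [[-1.0, 0.0, 2.0], [1.0, -1.0, 3.0], [4.0, 5.0, 6.0]]))
        assert p.b_cl() == pytest.approx([1.0, 0.0, 0.0])


class TestDeterminantDecomposition:
    def test_diagonal_matrix_only_l4(self):
        out = decompose_det_3node(np.diag([-1.0, -2.0, -3.0]))
        assert out["L1"] == out["L2"] == out["L3"] == 0.0
        assert out["L4"] == pytest.approx(-6.0)
        assert out["L4"] == pytest.approx(out["det"])

    def test_sum_identity_without_output_input_edge(self, rng):
        for _ in range(100):
            A = rng.normal(size=(3, 3))
            A[0, 2] = 0.0  # no output -> input edge
            out = decompose_det_3node(A)
            total = out["L1"] + out["L2"] + out["L3"] + out["L4"]
            assert total == pytest.approx(out["det"], abs=1e-12)
            assert out["residual"] == pytest.approx(0.0, abs=1e-15)

    def test_residual_closes_identity_in_general(self, rng):
        for _ in range(100):
            A = rng.normal(size=(3, 3))
            out = decompose_det_3node(A)
            total = out["L1"] + out["L2"] + out["L3"] + out["L4"] + out["residual"]
            assert total == pytest.approx(out["det"], abs=1e-12)

    def test_ifflp_jacobian_attributed_to_feedforward(self):
        from adaptscan.kinetics import find_steady_state, linearize

        f = get_fixture("ifflp3").rate_field()
        st = find_steady_state(f, 0.5)
        ss = linearize(f, st.x, 0.5)
        out = decompose_det_3node(ss.A)
        assert out["negative_terms"] == ["L4"]
        assert out["feedforward_attribution"] and not out["feedback_attribution"]

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            decompose_det_3node(np.eye(2))
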