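"""Linear-systems conditions: controllability, stability, DC gain, minor,
step responses and the minimum-peak-time property of origin-zero systems."""

import numpy as np
import pytest

from adaptscan.linear import (StateSpace, TransferFunctionFamily,
                              adaptation_verdict, characteristic_conditions,
                              controllability_rank, dc_gain, default_time_grid,
                              is_hurwitz, minor_condition, peak_time,
                              step_response, theorem1_compare)


def random_hurwitz(rng, n):
    """Random stable matrix built from its spectrum (eigenvalue oracle).

    Real block-diagonal canonical form conjugated by a random real matrix,
    so complex conjugate pairs are exercised while A stays exactly real.
    """
    D = np.diag(-rng.uniform(0.2, 3.0, size=n))
    if n >= 2 and rng.random() < 0.5:
        w = rng.uniform(0.1, 2.0)
        D[0, 1], D[1, 0] = w, -w
        D[1, 1] = D[0, 0]
    while True:
        T = rng.normal(size=(n, n))
        if abs(np.linalg.det(T)) > 1e-3:
            break
    return T @ D @ np.linalg.inv(T)


class TestControllability:
    def test_two_state_chain_controllable(self):
        A = np.array([[-1.0, 0.0], [1.0, -1.0]])
        rank, ok = controllability_rank(A, np.array([1.0, 0.0]))
        assert (rank, ok) == (2, True)

    def test_zero_input_matrix(self):
        A = -np.eye(3)
        rank, ok = controllability_rank(A, np.zeros(3))
        assert (rank, ok) == (0, False)

    def test_broken_chain_rank_one(self):
        A = np.array([[-1.0, 0.0], [0.0, -1.0]])  # link A[1][0] removed
        rank, ok = controllability_rank(A, np.array([1.0, 0.0]))
        assert (rank, ok) == (1, False)


class TestStability:
    def test_negative_identity(self):
        ok, eig = is_hurwitz(-np.eye(2))
        assert ok and eig == pytest.approx([-1.0, -1.0])

    def test_marginal_rotation_not_hurwitz(self):
        ok, eig = is_hurwitz(np.array([[0.0, 1.0], [-1.0, 0.0]]))
        assert not ok
        assert sorted(eig.imag) == pytest.approx([-1.0, 1.0])

    def test_agrees_with_eigenvalue_oracle(self, rng):
        for _ in range(50):
            shift = rng.uniform(-1.0, 1.0)
            M = rng.normal(size=(5, 5))
            A = M - (np.max(np.linalg.eigvals(M).real) + shift) * np.eye(5)
            ok, _ = is_hurwitz(A)
            assert ok == (np.max(np.linalg.eigvals(A).real) < 0) or abs(shift) < 1e-9


class TestCharacteristicConditions:
    def test_negative_identity_two_nodes(self):
        coeffs, all_pos, sign_ok = characteristic_conditions(-np.eye(2))
        assert coeffs == pytest.approx([1.0, 2.0, 1.0])  # s^2 + 2s + 1
        assert all_pos and sign_ok

    def test_saddle_fails_sign_condition(self):
        _, all_pos, sign_ok = characteristic_conditions(np.diag([1.0, -1.0]))
        assert not sign_ok and not all_pos

    def test_hurwitz_implies_both_flags(self, rng):
        for _ in range(200):
            A = random_hurwitz(rng, int(rng.integers(2, 6)))
            _, all_pos, sign_ok = characteristic_conditions(A)
            assert all_pos and sign_ok

    def test_converse_counterexamples(self):
        # all characteristic coefficients positive yet unstable: complex pair
        # with small positive real part plus a fast stable mode
        lam = np.array([0.1 + 1j, 0.1 - 1j, -5.0])
        coeffs = np.real(np.poly(lam))
        assert np.all(coeffs[1:] > 0)
        A = np.diag([-5.0, 0.1, 0.0]) + np.array(
            [[0, 0, 0], [0, 0, 1.0], [0, -1.0, 0.1]])
        ok, _ = is_hurwitz(A)
        _, all_pos, sign_ok = characteristic_conditions(A)
        assert not ok and all_pos and sign_ok
        # sign condition alone holds for A = I (det = 1 = (-1)^2) though unstable
        _, all_pos_i, sign_ok_i = characteristic_conditions(np.eye(2))
        assert sign_ok_i and not all_pos_i and not is_hurwitz(np.eye(2))[0]


class TestDCGainAndMinor:
    def test_decoupled_nodes_zero_gain(self):
        assert dc_gain(-np.eye(3), np.eye(3)[0], np.eye(3)[2]) == 0.0

    def test_two_state_chain_gain(self):
        A = np.array([[-1.0, 0.0], [1.0, -1.0]])
        assert dc_gain(A, np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(-1.0)

    def test_minor_worked_example(self):
        # input row 0, output column 2: minor = det [[a21, a22], [a31, a32]]
        A = np.zeros((3, 3))
        A[1, 0], A[1, 1], A[2, 0], A[2, 1] = 1.0, -1.0, 1.0, -1.0
        m, ok = minor_condition(A, 0, 2)
        assert m == pytest.approx(0.0) and ok
        A[2, 1] = 1.0
        m, ok = minor_condition(A, 0, 2)
        assert m == pytest.approx(2.0) and not ok

    def test_two_node_minor_is_forward_element(self):
        A = np.array([[-1.0, 0.5], [0.7, -2.0]])
        m, _ = minor_condition(A, 0, 1)
        assert m == pytest.approx(0.7)

    def test_cofactor_identity(self, rng):
        # C A^{-1} B = beta * (-1)^(in+out) * minor / det A  on 500 systems
        for _ in range(500):
            n = int(rng.integers(2, 7))
            A = rng.normal(size=(n, n))
            if abs(np.linalg.det(A)) < 1e-3:
                continue
            i_in, i_out = rng.integers(0, n, size=2)
            beta = rng.normal()
            B = np.zeros(n)
            B[i_in] = beta
            C = np.zeros(n)
            C[i_out] = 1.0
            gain = dc_gain(A, B, C)
            minor, _ = minor_condition(A, int(i_in), int(i_out))
            expected = beta * (-1.0) ** (i_in + i_out) * minor / np.linalg.det(A)
            assert gain == pytest.approx(expected, rel=1e-8, abs=1e-10)


class TestVerdict:
    def test_integral_feedback_adaptive(self):
        ss = StateSpace(A=np.array([[-1.0, -1.0], [1.0, 0.0]]),
                        B=np.array([1.0, 0.0]), C=np.array([1.0, 0.0]))
        assert adaptation_verdict(ss).verdict == "adaptive"

    def test_two_node_distinct_io_never_adaptive(self):
        # minor = a21: zero kills controllability, nonzero kills precision
        for a21 in (0.0, 1.0, -1.0):
            A = np.array([[-1.0, 0.3], [a21, -1.0]])
            ss = StateSpace(A=A, B=np.array([1.0, 0.0]), C=np.array([0.0, 1.0]))
            assert adaptation_verdict(ss).verdict != "adaptive"

    def test_unstable_dominates(self):
        ss = StateSpace(A=np.eye(2), B=np.array([1.0, 0.0]), C=np.array([0.0, 1.0]))
        assert adaptation_verdict(ss).verdict == "unstable"

    def test_marginal_not_silently_adaptive(self):
        A = np.array([[0.0, 1.0], [-1.0, 0.0]])
        ss = StateSpace(A=A, B=np.array([1.0, 0.0]), C=np.array([1.0, 0.0]))
        assert adaptation_verdict(ss).verdict == "marginal"


class TestStepResponse:
    def test_scalar_closed_form(self):
        ss = StateSpace(A=np.array([[-1.0]]), B=np.array([1.0]), C=np.array([1.0]))
        t = np.linspace(0, 8, 200)
        assert step_response(ss, t) == pytest.approx(1 - np.exp(-t), abs=1e-12)

    def test_zero_gain_system_returns_to_zero(self):
        ss = StateSpace(A=np.array([[-1.0, -1.0], [1.0, 0.0]]),
                        B=np.array([1.0, 0.0]), C=np.array([1.0, 0.0]))
        t = np.linspace(0, 80, 4000)
        y = step_response(ss, t)
        assert y[0] == pytest.approx(0.0, abs=1e-12)
        assert abs(y[-1]) <= 1e-6 * np.max(np.abs(y))

    def test_matches_ode_integrator_oracle(self, rng):
        from scipy.integrate import solve_ivp

        for _ in range(5):
            n = int(rng.integers(2, 5))
            A = random_hurwitz(rng, n)
            B = rng.normal(size=n)
            C = rng.normal(size=n)
            ss = StateSpace(A=A, B=B, C=C)
            t = np.linspace(0, 10, 400)
            sol = solve_ivp(lambda _t, x: A @ x + B, (0, 10), np.zeros(n),
                            t_eval=t, rtol=1e-11, atol=1e-13)
            assert step_response(ss, t) == pytest.approx(C @ sol.y, abs=1e-8)


class TestPeakTime:
    def test_critically_damped_peak(self):
        t = np.linspace(0, 12, 3000)
        tp, yp, flagged = peak_time(t * np.exp(-t), t)
        assert tp == pytest.approx(1.0, abs=1e-3)
        assert yp == pytest.approx(np.exp(-1.0), abs=1e-4)
        assert not flagged

    def test_monotone_response_flagged(self):
        t = np.linspace(0, 5, 500)
        tp, _, flagged = peak_time(1 - np.exp(-t), t)
        assert flagged and tp == pytest.approx(5.0)

    def test_flat_response_flagged(self):
        t = np.linspace(0, 5, 100)
        tp, yp, flagged = peak_time(np.zeros_like(t), t)
        assert flagged and np.isnan(tp) and yp == 0.0


class TestMinimumPeakTime:
    def test_double_pole_family_closed_form(self):
        # poles {-1, -1}: z1 = 0 gives y = t e^{-t} (peak at 1);
        # z1 = 0.5 gives y = 0.5 - 0.5 e^{-t} + 0.5 t e^{-t} (peak at 2)
        fam = TransferFunctionFamily(poles=(1.0, 1.0))
        rows = {r["z1"]: r for r in theorem1_compare(fam, [0.0, 0.5])}
        assert rows[0.0]["peak_time"] == pytest.approx(1.0, abs=1e-3)
        assert rows[0.5]["peak_time"] == pytest.approx(2.0, abs=1e-3)

    def test_origin_zero_attains_minimum(self, rng):
        for _ in range(25):
            n_poles = int(rng.integers(2, 6))
            poles = tuple(rng.uniform(0.3, 4.0, size=n_poles))
            n_shared = int(rng.integers(0, n_poles - 1))
            zeros = tuple(rng.uniform(0.3, 4.0, size=n_shared))
            fam = TransferFunctionFamily(poles=poles, shared_zeros=zeros)
            rows = theorem1_compare(fam, list(rng.uniform(0.1, 5.0, size=4)))
            origin = [r for r in rows if r["is_origin"]][0]
            others = [r for r in rows if not r["is_origin"]]
            assert all(origin["peak_time"] <= r["peak_time"] + 1e-6 for r in others)

    def test_origin_compared_with_itself_is_equality(self):
        fam = TransferFunctionFamily(poles=(1.0, 2.0))
        rows = theorem1_compare(fam, [0.0])
        assert len(rows) == 1 and rows[0]["is_origin"]

    def test_unstable_pole_rejected(self):
        with pytest.raises(ValueError):
            TransferFunctionFamily(poles=(1.0, -2.0))

    def test_improper_family_rejected(self):
        with pytest.raises(ValueError):
            TransferFunctionFamily(poles=(1.0,), shared_zeros=(1.0,))


def test_default_time_grid_spans_slowest_mode():
    A = np.diag([-0.1, -10.0])
    t = default_time_grid(A, 100)
    assert t[-1] == pytest.approx(100.0)
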