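"""Rate functions and the delayed right-hand side."""

import math

import mpmath
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hscdelay.model import (
    ModelParameters,
    StateSnapshot,
    TreatmentSchedule,
    eval_beta_C,
    eval_beta_HIA,
    eval_beta_N,
    eval_g_C,
    eval_g_HIA,
    eval_rhs,
)
from hscdelay.steady import closed_form_steady_state

P_DEF = ModelParameters()


class TestBetaN:
    def test_maximum_at_zero(self):
        assert eval_beta_N(0.0, P_DEF) == pytest.approx(1.4)

    def test_half_maximum_at_theta(self):
        assert eval_beta_N(60.0, P_DEF) == pytest.approx(0.7)

    def test_consistent_with_steady_state_relation(self):
        # at the positive equilibrium, beta(N*) = delta / (2*exp(-gamma*tau) - 1)
        ss = closed_form_steady_state(P_DEF)
        expected = P_DEF.delta / (2.0 * math.exp(-P_DEF.gamma * P_DEF.tau) - 1.0)
        assert eval_beta_N(ss.N_star, P_DEF) == pytest.approx(expected, rel=1e-12)
        # the equilibrium sits near N = 114.5, where beta is ~0.208/d
        assert eval_beta_N(114.5, P_DEF) == pytest.approx(0.2078, abs=5e-4)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            eval_beta_N(-1.0, P_DEF)

    @given(
        N=st.floats(0.0, 1e4),
        beta0=st.floats(0.01, 10.0),
        theta=st.floats(1.0, 500.0),
        n=st.floats(0.1, 6.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_decreasing(self, N, beta0, theta, n):
        p = ModelParameters(beta0=beta0, theta=theta, n=n)
        v = eval_beta_N(N, p)
        assert 0.0 < v <= beta0
        assert eval_beta_N(N + 1.0, p) < v


class TestDecayFactors:
    def test_g_hia_branches(self):
        assert eval_g_HIA(P_DEF.tau1 / 2.0, P_DEF) == 1.0
        assert eval_g_HIA(P_DEF.tau1, P_DEF) == 1.0  # continuity: exp(0)=1
        one_constant = P_DEF.tau1 + 1.0 / P_DEF.s1
        assert eval_g_HIA(one_constant, P_DEF) == pytest.approx(math.exp(-1.0))

    def test_g_c_branches_and_residual(self):
        assert eval_g_C(P_DEF.tau2, P_DEF) == 1.0
        # frozen residual: exp(-s2*(tau3 - tau2)) = exp(-0.2*13)
        residual = math.exp(-0.2 * 13.0)
        assert eval_g_C(P_DEF.tau3, P_DEF) == pytest.approx(residual)
        assert eval_g_C(1e6, P_DEF) == pytest.approx(residual)
        assert residual == pytest.approx(0.0743, abs=5e-5)

    def test_g_c_degenerate_tau3_equals_tau2(self):
        p = ModelParameters(tau2=5.0, tau3=5.0)
        for t in (1.0, 5.0, 20.0, 1e3):
            assert eval_g_C(t, p) == 1.0

    @pytest.mark.parametrize("fn", [eval_g_HIA, eval_g_C])
    def test_continuity_and_monotonicity(self, fn):
        # dense grid straddling every branch point
        grid = [k * 0.01 for k in range(0, 3000)]
        vals = [fn(t, P_DEF) for t in grid]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        # adaptive check across the corners
        for corner in (P_DEF.tau1, P_DEF.tau2, P_DEF.tau3):
            left = fn(corner - 1e-9, P_DEF)
            right = fn(corner + 1e-9, P_DEF)
            assert right == pytest.approx(left, abs=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            eval_g_HIA(-0.1, P_DEF)
        with pytest.raises(ValueError):
            eval_g_C(-0.1, P_DEF)


class TestTreatmentHills:
    def test_hia_half_maximum_at_theta1(self):
        assert eval_beta_HIA(100.0, 1.0, P_DEF) == pytest.approx(0.04)

    def test_hia_absent_when_rate_zero(self):
        p = ModelParameters(beta0_HIA=0.0)
        for P in (0.0, 50.0, 500.0):
            assert eval_beta_HIA(P, 3.0, p) == 0.0

    def test_hia_shallow_hill_high_precision(self):
        # m = 0.1 makes the Hill nearly flat; cross-check the fractional
        # power arithmetic against 50-digit evaluation
        with mpmath.workdps(50):
            t1m = mpmath.mpf(100) ** mpmath.mpf("0.1")
            pm = mpmath.mpf(50) ** mpmath.mpf("0.1")
            expected = float(mpmath.mpf("0.08") * t1m / (t1m + pm))
        assert eval_beta_HIA(50.0, 1.0, P_DEF) == pytest.approx(expected, rel=1e-14)

    def test_cta_vanishes_at_zero_and_saturates(self):
        assert eval_beta_C(0.0, 1.0, P_DEF) == 0.0
        assert eval_beta_C(100.0, 1.0, P_DEF) == pytest.approx(0.103)
        assert eval_beta_C(1e12, 1.0, P_DEF) == pytest.approx(0.206, rel=1e-9)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            eval_beta_HIA(-1.0, 0.0, P_DEF)
        with pytest.raises(ValueError):
            eval_beta_C(-1.0, 0.0, P_DEF)

    @given(
        P=st.floats(0.0, 1e4),
        beta0_C=st.floats(0.001, 2.0),
        theta2=st.floats(1.0, 500.0),
        w=st.floats(0.1, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_cta_bounded_and_increasing(self, P, beta0_C, theta2, w):
        p = ModelParameters(beta0_C=beta0_C, theta2=theta2, w=w)
        v = eval_beta_C(P, 0.0, p)
        assert 0.0 <= v <= beta0_C
        nxt = eval_beta_C(P + 1.0, 0.0, p)
        assert nxt >= v
        if v < beta0_C * (1.0 - 1e-12):  # strict until float saturation
            assert nxt > v and v < beta0_C

    @given(
        P=st.floats(0.0, 1e4),
        beta0_HIA=st.floats(0.001, 2.0),
        theta1=st.floats(1.0, 500.0),
        m=st.floats(0.05, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_hia_bounded_and_decreasing(self, P, beta0_HIA, theta1, m):
        p = ModelParameters(beta0_HIA=beta0_HIA, theta1=theta1, m=m)
        v = eval_beta_HIA(P, 0.0, p)
        assert 0.0 < v <= beta0_HIA
        assert eval_beta_HIA(P + 1.0, 0.0, p) < v


def _mackey_rhs(P, N, N_tau, p):
    """Independent two-compartment delayed hematopoiesis right-hand side
    (no treatment terms), coded directly from the classical form."""
    beta = lambda x: p.beta0 * p.theta**p.n / (p.theta**p.n + x**p.n)
    E = math.exp(-p.gamma * p.tau)
    dP = -p.gamma * P + beta(N) * N - E * beta(N_tau) * N_tau
    dN = -beta(N) * N - p.delta * N + 2.0 * E * beta(N_tau) * N_tau
    return dP, dN


class TestRhs:
    def test_trivial_state_is_equilibrium(self):
        now = StateSnapshot(10.0, 0.0, 0.0)
        lag = StateSnapshot(10.0 - P_DEF.tau, 0.0, 0.0)
        assert eval_rhs(now, lag, TreatmentSchedule.off(), P_DEF) == (0.0, 0.0)

    def test_positive_equilibrium_zeroes_rhs(self):
        ss = closed_form_steady_state(P_DEF)
        now = StateSnapshot(100.0, ss.P_star, ss.N_star)
        lag = StateSnapshot(100.0 - P_DEF.tau, ss.P_star, ss.N_star)
        dP, dN = eval_rhs(now, lag, TreatmentSchedule.off(), P_DEF)
        assert abs(dP) < 1e-10 and abs(dN) < 1e-10

    @given(
        P=st.floats(0.0, 500.0),
        N=st.floats(0.0, 500.0),
        N_tau=st.floats(0.0, 500.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_reduces_to_mackey_model_without_treatment(self, P, N, N_tau):
        now = StateSnapshot(20.0, P, N)
        lag = StateSnapshot(20.0 - P_DEF.tau, P, N_tau)
        got = eval_rhs(now, lag, TreatmentSchedule.off(), P_DEF)
        exp = _mackey_rhs(P, N, N_tau, P_DEF)
        assert got[0] == pytest.approx(exp[0], rel=1e-12, abs=1e-12)
        assert got[1] == pytest.approx(exp[1], rel=1e-12, abs=1e-12)

    def test_total_cell_balance(self):
        # d(P+N)/dt = -gamma*P - delta*N + E*beta(N_tau)*N_tau: treatment
        # terms transfer cells between pools without creating or removing any
        sched = TreatmentSchedule(hia_on=True, cta_on=True)
        now = StateSnapshot(3.0, 80.0, 120.0)
        lag = StateSnapshot(3.0 - P_DEF.tau, 70.0, 100.0)
        dP, dN = eval_rhs(now, lag, sched, P_DEF)
        E = math.exp(-P_DEF.gamma * P_DEF.tau)
        expected = (
            -P_DEF.gamma * 80.0
            - P_DEF.delta * 120.0
            + E * eval_beta_N(100.0, P_DEF) * 100.0
        )
        assert dP + dN == pytest.approx(expected, rel=1e-12)

    def test_mismatched_delay_offset_rejected(self):
        now = StateSnapshot(10.0, 50.0, 70.0)
        bad = StateSnapshot(9.0, 50.0, 70.0)  # tau is 2.22, not 1.0
        with pytest.raises(ValueError):
            eval_rhs(now, bad, TreatmentSchedule.off(), P_DEF)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau": 0.0},
            {"delta": -0.1},
            {"theta": 0.0},
            {"n": 0.0},
            {"tau2": 6.0, "tau3": 5.0},
            {"gamma": float("nan")},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            P_DEF.with_overrides(beta_zero=2.0)
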