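"""NMDA gating kinetics: jump constants, exact trajectories, aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate as sint

from nmdanet._integrate import rk4_fixed
from nmdanet.gating import (
    ExactGatingState,
    GatingParams,
    approx_gating_trajectory,
    approx_jump,
    compute_jump_constants,
    exact_gating_closed_form,
    exact_gating_evolve,
    exact_spike_update,
    periodic_steady_state,
    simulate_synapse_approx,
)


def gamma_lower_quad(s, x):
    """Oracle 1: adaptive quadrature of the unnormalized lower incomplete gamma."""
    val, _ = sint.quad(lambda u: u ** (s - 1.0) * np.exp(-u), 0.0, x,
                       epsabs=1e-14, epsrel=1e-13, limit=500)
    return val


def gamma_lower_series(s, x, n_terms=80):
    """Oracle 2: power series x^s sum (-x)^n / (n! (s+n))."""
    total = 0.0
    term_fac = 1.0
    for n in range(n_terms):
        if n > 0:
            term_fac *= -x / n
        total += term_fac / (s + n)
    return x ** s * total


class TestJumpConstants:
    def test_default_parameters_match_dual_oracles(self, gp, jc):
        s = 1.0 - gp.tau_r / gp.tau_d  # 0.98
        a = gp.alpha * gp.tau_r        # 1.0
        g_quad = gamma_lower_quad(s, a)
        g_series = gamma_lower_series(s, a)
        assert g_quad == pytest.approx(g_series, abs=1e-8)
        k0_oracle = a ** (gp.tau_r / gp.tau_d) * g_quad
        assert jc.k0 == pytest.approx(k0_oracle, abs=1e-8)
        assert jc.k0 == pytest.approx(0.6484, abs=2e-4)
        assert jc.k1_prime == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert jc.k1 == pytest.approx(np.exp(-1.0) - 1.0, rel=1e-12)

    def test_vanishing_gain_gives_no_jump(self):
        jc0 = compute_jump_constants(GatingParams(alpha=0.0))
        assert jc0.k0 == 0.0
        assert jc0.k1 == 0.0
        assert jc0.k1_prime == 1.0

    def test_fixed_point_slightly_above_one(self, jc):
        # ceiling of the approximate gating variable
        assert jc.fixed_point == pytest.approx(jc.k0 / (1.0 - np.exp(-1.0)), rel=1e-12)
        assert 1.0 < jc.fixed_point < 1.1
        assert jc.fixed_point == pytest.approx(1.026, abs=2e-3)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 2.0])
    @pytest.mark.parametrize("tau_r", [0.5, 2.0, 5.0])
    @pytest.mark.parametrize("tau_d", [50.0, 100.0, 200.0])
    def test_closed_form_matches_quadrature_across_grid(self, alpha, tau_r, tau_d):
        p = GatingParams(alpha=alpha, tau_r=tau_r, tau_d=tau_d)
        jc = compute_jump_constants(p)
        a = alpha * tau_r
        oracle = a ** (tau_r / tau_d) * gamma_lower_quad(1.0 - tau_r / tau_d, a)
        assert jc.k0 == pytest.approx(oracle, abs=1e-8)
        assert -1.0 < jc.k1 <= 0.0
        assert 0.0 < jc.k1_prime <= 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GatingParams(tau_r=100.0, tau_d=100.0)
        with pytest.raises(ValueError):
            GatingParams(tau_r=120.0, tau_d=100.0)
        with pytest.raises(ValueError):
            GatingParams(alpha=-0.1)


class TestExactModel:
    def test_spike_enters_only_x(self):
        s = exact_spike_update(ExactGatingState(S=0.0, x=0.0))
        assert (s.S, s.x) == (0.0, 1.0)
        s = exact_spike_update(ExactGatingState(S=0.3, x=0.5))
        assert (s.S, s.x) == (0.3, 1.5)
        s = exact_spike_update(ExactGatingState(S=0.3, x=0.5), n_spikes=2)
        assert s.x == 2.5

    def test_rest_state_is_fixed_point(self, gp):
        _, S, x = exact_gating_evolve(ExactGatingState(0.0, 0.0), gp, 50.0, 1.0)
        assert np.all(S == 0.0)
        assert np.all(x == 0.0)

    def test_x_decays_exponentially(self, gp):
        t, _, x = exact_gating_evolve(ExactGatingState(0.0, 1.0), gp, 20.0, 0.5)
        assert x == pytest.approx(np.exp(-t / gp.tau_r), abs=1e-8)

    def test_trajectory_matches_closed_form(self, gp):
        t, S, _ = exact_gating_evolve(ExactGatingState(0.1, 1.0), gp, 100.0, 5.0)
        ref = exact_gating_closed_form(ExactGatingState(0.1, 1.0), gp, t[1:])
        assert S[1:] == pytest.approx(ref, abs=1e-7)

    def test_asymptotically_equal_to_decay_form(self, gp, jc):
        # single spike from rest: S(t) / (k0 e^{-t/tau_d}) -> 1
        for t_probe, tol in [(50.0, 1e-4), (100.0, 1e-6)]:
            S = exact_gating_closed_form(ExactGatingState(0.0, 1.0), gp, t_probe)
            ratio = S / (jc.k0 * np.exp(-t_probe / gp.tau_d))
            assert abs(ratio - 1.0) < tol

    def test_peak_below_one_matches_fine_rk4(self, gp):
        # fine-step RK4 of the two-ODE system is the oracle for the peak
        inv_td, inv_tr, al = 1 / gp.tau_d, 1 / gp.tau_r, gp.alpha

        def rhs(_t, y):
            S, x = y
            return [-S * inv_td + al * x * (1 - S), -x * inv_tr]

        step = 1e-3
        n = int(20.0 / step)
        y = [np.array([0.0]), np.array([1.0])]
        peak, t_peak = 0.0, 0.0
        for i in range(n):
            y = rk4_fixed(rhs, y, step, step)
            if y[0][0] > peak:
                peak, t_peak = y[0][0], (i + 1) * step
        assert peak < 1.0
        t, S, _ = exact_gating_evolve(ExactGatingState(0.0, 1.0), gp, 20.0, 0.05)
        i = np.argmax(S)
        assert S[i] == pytest.approx(peak, abs=1e-6)
        assert t[i] == pytest.approx(t_peak, abs=0.1)

    @given(st.lists(st.floats(0.5, 200.0), min_size=1, max_size=20),
           st.floats(0.0, 1.0), st.floats(0.0, 3.0))
    def test_saturation_invariant(self, gaps, S0, x0):
        # S stays within [0, 1] for any spike train when started inside
        gp = GatingParams()
        state = ExactGatingState(S=S0, x=x0)
        for gap in gaps:
            _, S, _ = exact_gating_evolve(state, gp, gap, gap / 4, atol=1e-9, rtol=1e-9)
            assert np.all(S >= -1e-9)
            assert np.all(S <= 1.0 + 1e-9)
            state = exact_spike_update(
                ExactGatingState(S=min(S[-1], 1.0), x=state.x * np.exp(-gap / gp.tau_r)))

    def test_jump_error_sign(self, gp, jc):
        # immediately after a spike the approximation exceeds the exact model
        for S0 in (0.0, 0.3, 0.8):
            t = np.array([0.5, 1.0, 2.0])
            exact = exact_gating_closed_form(ExactGatingState(S0, 1.0), gp, t)
            approx = (S0 + jc.k0 + jc.k1 * S0) * np.exp(-t / gp.tau_d)
            assert np.all(approx >= exact)


class TestApproxModel:
    def test_jump_values(self, jc):
        assert approx_jump(0.0, jc) == pytest.approx(jc.k0)
        assert approx_jump(jc.fixed_point, jc) == pytest.approx(0.0, abs=1e-15)
        assert approx_jump(0.5, jc) == pytest.approx(0.6484 - 0.6321 * 0.5, abs=2e-4)

    def test_pure_decay(self, gp):
        S = approx_gating_trajectory(1.0, gp, [], [gp.tau_d])
        assert S[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_aggregation_linearity(self, gp, jc, rng):
        # two synapses summed == one aggregated variable with both streams
        t_eval = np.linspace(0, 500, 251)
        ev1, _ = simulate_synapse_approx(np.sort(rng.uniform(0, 500, 12)), gp, jc)
        ev2, _ = simulate_synapse_approx(np.sort(rng.uniform(0, 500, 9)), gp, jc)
        s1 = approx_gating_trajectory(0.0, gp, ev1, t_eval)
        s2 = approx_gating_trajectory(0.0, gp, ev2, t_eval)
        merged = sorted(ev1 + ev2)
        s12 = approx_gating_trajectory(0.0, gp, merged, t_eval)
        np.testing.assert_allclose(s12, s1 + s2, rtol=1e-13, atol=1e-15)

    def test_periodic_steady_state_matches_iterated_map(self, gp, jc):
        for interval in (10.0, 50.0, 200.0):
            S_star = periodic_steady_state(jc, gp, interval)
            q = np.exp(-interval / gp.tau_d)
            S = 0.0
            for _ in range(1000):
                S = (S + jc.k0 + jc.k1 * S) * q
            assert S == pytest.approx(S_star, rel=1e-10)

    def test_single_synapse_bounded_by_fixed_point(self, gp, jc):
        _, post = simulate_synapse_approx(np.arange(1.0, 2000.0, 2.0), gp, jc)
        assert np.all(post <= jc.fixed_point + 1e-12)
        assert post[-1] > 1.0  # rapid firing drives S slightly above one

    def test_negative_trajectory_rejected(self, gp):
        with pytest.raises(ValueError):
            approx_gating_trajectory(0.0, gp, [(1.0, -0.5)], [2.0])
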