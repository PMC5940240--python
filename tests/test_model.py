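import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respcpg import ModelParameters
from respcpg.model import (
    DEFAULT_INITIAL_STATE,
    NetworkState,
    gate_steady_states,
    make_rhs,
    membrane_currents,
    output_activities,
    output_activity,
    state_derivative,
)

PARAMS = ModelParameters()


def _random_state(draw):
    V = np.array([draw(st.floats(-80.0, -10.0)) for _ in range(5)])
    h = draw(st.floats(0.0, 1.0))
    m = np.array([draw(st.floats(0.0, k)) for k in PARAMS.k_AD])
    return NetworkState(V, h, m)


state_strategy = st.builds(
    lambda V, h, m: NetworkState(np.array(V), h, np.array(m) * np.array(PARAMS.k_AD)),
    st.lists(st.floats(-80.0, -10.0), min_size=5, max_size=5),
    st.floats(0.0, 1.0),
    st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
)
stim_strategy = st.lists(st.floats(0.0, 2.0), min_size=5, max_size=5).map(np.array)


class TestOutputActivity:
    def test_midpoint_at_half_activation(self):
        for pop in range(1, 6):
            assert output_activity(-30.0, pop, PARAMS) == pytest.approx(0.5)

    def test_hard_cutoff_below_minus_60(self):
        assert output_activity(-61.0, 3, PARAMS) == 0.0
        assert output_activity(-60.0, 3, PARAMS) > 0.0   # boundary included

    def test_sigmoid_value_one_slope_above_midpoint(self):
        # pop 1 has slope 8 mV: at -22 mV the argument is exactly 1
        assert output_activity(-22.0, 1, PARAMS) == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-4)

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            output_activity(-30.0, 0, PARAMS)

    def test_vectorized_matches_scalar(self):
        V = np.array([-70.0, -55.0, -30.0, -61.0, -20.0])
        vec = output_activities(V, PARAMS)
        for i in range(5):
            assert vec[i] == pytest.approx(output_activity(V[i], i + 1, PARAMS))


class TestGates:
    def test_half_inactivation_at_minus_48(self):
        g = gate_steady_states(-48.0, PARAMS)
        assert g.h_inf_NaP == pytest.approx(0.5)
        assert g.tau_hNaP == pytest.approx(PARAMS.tau_hNaP_max)

    def test_half_activations(self):
        assert gate_steady_states(-40.0, PARAMS).m_NaP == pytest.approx(0.5)
        assert gate_steady_states(-30.0, PARAMS).m_K == pytest.approx(0.5)

    @given(V1=st.floats(-100.0, 0.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gate_ranges(self, V1):
        g = gate_steady_states(V1, PARAMS)
        assert 0.0 < g.m_NaP < 1.0
        assert 0.0 < g.h_inf_NaP < 1.0
        assert 0.0 < g.m_K < 1.0
        assert 0.0 < g.tau_hNaP <= PARAMS.tau_hNaP_max


class TestMembraneCurrents:
    def test_leak_vanishes_at_reversal(self):
        state = NetworkState(np.full(5, PARAMS.E_L), 0.5, np.zeros(4))
        cur = membrane_currents(state, PARAMS, np.zeros(5))
        assert np.allclose(cur.I_L, 0.0)

    def test_no_light_no_chr_current(self):
        state = NetworkState(np.array([-50.0, -40, -60, -55, -45]), 0.5, np.full(4, 0.2))
        cur = membrane_currents(state, PARAMS, np.zeros(5))
        assert np.allclose(cur.I_ChR, 0.0)

    def test_silent_sources_give_no_inhibition(self):
        state = NetworkState(np.full(5, -65.0), 0.5, np.zeros(4))
        cur = membrane_currents(state, PARAMS, np.zeros(5))
        assert np.allclose(cur.I_SynI, 0.0)

    def test_current_applicability_by_population(self):
        state = NetworkState(np.array([-40.0, -40, -40, -40, -40]), 0.5, np.full(4, 0.3))
        cur = membrane_currents(state, PARAMS, np.zeros(5))
        assert np.all(cur.I_NaP[1:] == 0) and cur.I_NaP[0] != 0
        assert np.all(cur.I_K[1:] == 0) and cur.I_K[0] != 0
        assert cur.I_AD[0] == 0 and np.all(cur.I_AD[1:] != 0)

    def test_early_i_receives_burster_excitation(self):
        # with pop 1 active, the excitatory input to pop 2 exceeds its tonic share
        V = np.array([-20.0, -50.0, -65.0, -65.0, -65.0])
        state = NetworkState(V, 0.5, np.zeros(4))
        cur = membrane_currents(state, PARAMS, np.zeros(5))
        f1 = output_activity(-20.0, 1, PARAMS)
        expected = PARAMS.g_SynE * (PARAMS.drive[1] + PARAMS.a12 * f1) * (V[1] - PARAMS.E_SynE)
        assert cur.I_SynE[1] == pytest.approx(expected)

    def test_negative_stim_rejected(self):
        state = DEFAULT_INITIAL_STATE.copy()
        with pytest.raises(ValueError):
            membrane_currents(state, PARAMS, np.array([0.0, -0.1, 0, 0, 0]))


class TestStateDerivative:
    @given(state=state_strategy, stim=stim_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_voltage_derivative_balances_currents(self, state, stim):
        """-C dV/dt equals the summed current decomposition, everywhere."""
        deriv = state_derivative(0.0, state, PARAMS, lambda t: stim)
        currents = membrane_currents(state, PARAMS, stim)
        assert np.allclose(-PARAMS.C * deriv.V, currents.total(), rtol=1e-12)

    @given(state=state_strategy, stim=stim_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_packed_rhs_matches_reference_derivative(self, state, stim):
        """The unrolled integrator RHS agrees with the readable reference."""
        rhs = make_rhs(PARAMS)
        fast = rhs(0.0, state.to_vector(), stim)
        ref = state_derivative(0.0, state, PARAMS, lambda t: stim)
        assert np.allclose(fast, np.concatenate((ref.V, [ref.h_NaP], ref.m_AD)), rtol=1e-12)

    def test_inactivation_stationary_at_steady_state(self):
        V = np.array([-52.0, -60, -60, -60, -60])
        h_inf = gate_steady_states(V[0], PARAMS).h_inf_NaP
        deriv = state_derivative(0.0, NetworkState(V, h_inf, np.zeros(4)), PARAMS,
                                 lambda t: np.zeros(5))
        assert deriv.h_NaP == pytest.approx(0.0, abs=1e-15)

    def test_silent_recovered_adaptation_is_stationary(self):
        state = NetworkState(np.full(5, -70.0), 0.5, np.zeros(4))
        deriv = state_derivative(0.0, state, PARAMS, lambda t: np.zeros(5))
        assert np.allclose(deriv.m_AD, 0.0)

    def test_adaptation_follows_exponential_relaxation(self):
        """With voltages clamped, m_AD relaxes to k_AD*f with time constant
        tau_AD — compare stepped integration of the model derivative against
        the closed-form solution of the linear ODE."""
        V = np.array([-40.0, -35.0, -45.0, -38.0, -42.0])
        f = output_activities(V, PARAMS)[1:]
        target = np.asarray(PARAMS.k_AD) * f
        tau = np.asarray(PARAMS.tau_AD)

        m = np.zeros(4)
        dt, t_end = 0.5, 1500.0
        for _ in range(int(t_end / dt)):       # RK4 on the m_AD block only
            def dm(mv):
                return state_derivative(
                    0.0, NetworkState(V, 0.5, mv), PARAMS, lambda t: np.zeros(5)
                ).m_AD
            k1 = dm(m)
            k2 = dm(m + 0.5 * dt * k1)
            k3 = dm(m + 0.5 * dt * k2)
            k4 = dm(m + dt * k3)
            m = m + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        closed_form = target * (1.0 - np.exp(-t_end / tau))
        assert np.allclose(m, closed_form, rtol=1e-6)


def test_flow_invariance_along_baseline(baseline_trace, params):
    """h_NaP stays in [0,1] and each m_AD_i in [0, k_AD_i] along the orbit."""
    assert baseline_trace.h_NaP.min() >= 0.0
    assert baseline_trace.h_NaP.max() <= 1.0
    for i, k in enumerate(params.k_AD):
        assert baseline_trace.m_AD[i].min() >= 0.0
        assert baseline_trace.m_AD[i].max() <= k + 1e-9
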