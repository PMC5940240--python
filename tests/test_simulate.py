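import numpy as np
import pytest

from respcpg import ModelParameters
from respcpg.model import DEFAULT_INITIAL_STATE, NetworkState, state_derivative
from respcpg.protocol import PhaseLockedOnset, StimulusEpoch, StimulusProtocol
from respcpg.simulate import SolverSettings, integrate_model, run_phase_locked
from respcpg.analysis import cycle_metrics, detect_bursts


def _phase_ordering_holds(trace, t_start=20000.0):
    """Three-phase activation sequence on every complete cycle:

    inspiration (pre-I/I + early-I together), then decrementing post-I with
    the brief post-I_pBC transient early in expiration, then augmenting
    aug-E peaking late in expiration.
    """
    bursts = detect_bursts(trace, t_start=t_start)
    if len(bursts.onsets) < 4:
        return False
    t, f = trace.t, trace.f
    for onset, offset, next_onset in zip(
        bursts.onsets[:-1], bursts.offsets, bursts.onsets[1:]
    ):
        T_E = next_onset - offset
        insp = (t >= onset) & (t < offset)
        exp_ = (t >= offset) & (t < next_onset)
        if not insp.any() or not exp_.any():
            return False
        # inspiratory populations peak together during inspiration
        if f[0][insp].max() < 2 * f[0][exp_].max():
            return False
        if f[1][insp].max() < 2 * f[1][exp_].max():
            return False
        peak = {i: t[exp_][np.argmax(f[i][exp_])] for i in (2, 3, 4)}
        # post-I decrements from expiration onset; post-I_pBC transient early
        if peak[3] - offset > T_E / 3 or peak[4] - offset > T_E / 3:
            return False
        # aug-E augments toward the next inspiration, after both post-I peaks
        if peak[2] - offset < 2 * T_E / 3:
            return False
        if not (peak[2] > peak[3] and peak[2] > peak[4]):
            return False
    return True


class TestIntegration:
    def test_silent_network_settles_at_rest_equilibrium(self):
        """With drives off and the burster conductance removed the network
        settles at a silent fixed point at the leak reversal (placed below
        the −60 mV output cutoff so the equilibrium is non-degenerate)."""
        params = ModelParameters().replace(drive=(0, 0, 0, 0, 0), g_NaP=0.0, E_L=-62.0)
        trace = integrate_model(params, StimulusProtocol(), (0.0, 20000.0))
        late = trace.t >= 15000.0
        assert np.all(trace.f[:, late] == 0.0)
        final = trace.final_state()
        deriv = state_derivative(0.0, final, params, lambda t: np.zeros(5))
        assert np.max(np.abs(deriv.V)) < 1e-6
        assert np.all(np.abs(trace.V[:, -1] - params.E_L) < 0.01)

    def test_network_rhythm_survives_burster_block(self):
        """Removing I_NaP weakens and slows the rhythm but the inhibitory
        network oscillator persists — rhythmogenesis is not purely
        pacemaker-driven in this circuit."""
        params = ModelParameters().replace(g_NaP=0.0)
        trace = integrate_model(params, StimulusProtocol(), (0.0, 40000.0))
        bursts = detect_bursts(trace, t_start=10000.0)
        assert len(bursts.onsets) >= 3
        from respcpg.analysis import cycle_metrics

        assert cycle_metrics(bursts).mean_period > 3000.0   # slower than baseline
        assert bursts.peak_values.max() < 0.5               # weaker than baseline

    def test_determinism_bitwise(self, params):
        protocol = StimulusProtocol((
            StimulusEpoch(frozenset({2, 5}), 1.0, t_on=2000.0, duration=300.0),
        ))
        a = integrate_model(params, protocol, (0.0, 5000.0))
        b = integrate_model(params, protocol, (0.0, 5000.0))
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.h_NaP, b.h_NaP)
        assert np.array_equal(a.m_AD, b.m_AD)

    def test_output_grid_uniform_and_f_consistent(self, baseline_trace, params):
        from respcpg.model import output_activities

        assert np.allclose(np.diff(baseline_trace.t), 1.0)
        assert np.allclose(baseline_trace.f, output_activities(baseline_trace.V, params))

    def test_invalid_t_span_rejected(self, params):
        with pytest.raises(ValueError):
            integrate_model(params, StimulusProtocol(), (1000.0, 1000.0))


class TestBaselineRhythm:
    def test_periodic_bursting_with_three_phase_ordering(self, baseline_trace):
        assert _phase_ordering_holds(baseline_trace)

    def test_transient_decays_within_discard_window(self, baseline_metrics):
        periods = baseline_metrics.periods
        assert len(periods) >= 10
        assert np.all(np.abs(np.diff(periods)) / periods[:-1] < 0.005)

    def test_inhibition_required_for_three_phase_pattern(self, params):
        """Cutting all inhibitory conductance destroys the alternation."""
        quiet = params.replace(g_SynI=0.0)
        trace = integrate_model(quiet, StimulusProtocol(), (0.0, 40000.0))
        assert not _phase_ordering_holds(trace, t_start=10000.0)

    def test_period_solver_independent(self, params, baseline_metrics):
        """Cycle period agrees within 0.1% when tolerances tighten 100-fold."""
        tight = SolverSettings(rtol=1e-10, atol=1e-10)
        trace = integrate_model(params, StimulusProtocol(), (0.0, 60000.0),
                                settings=tight)
        period = cycle_metrics(detect_bursts(trace, t_start=20000.0)).mean_period
        assert abs(period - baseline_metrics.mean_period) / period < 1e-3


class TestStimulusBookkeeping:
    def test_trace_stim_channel_matches_protocol(self, params):
        from respcpg.protocol import stimulus_intensity_at

        protocol = StimulusProtocol((
            StimulusEpoch(frozenset({3, 4}), 0.7, t_on=500.0, duration=800.0),
            StimulusEpoch(frozenset({1}), 0.2, t_on=2000.0, duration=1000.0,
                          waveform="pulse-train", pulse_width=100.0, pulse_period=250.0),
        ))
        trace = integrate_model(params, protocol, (0.0, 4000.0))
        expected = np.stack([stimulus_intensity_at(protocol, t) for t in trace.t], axis=1)
        assert np.array_equal(trace.stim, expected)


class TestPhaseLocking:
    def test_zero_offset_coincides_with_inspiration_onset(self, params, baseline_bursts):
        protocol = StimulusProtocol(
            (StimulusEpoch(frozenset({2, 5}), 1.0, t_on=0.0, duration=300.0),),
            PhaseLockedOnset("inspiration-onset", cycle_index=0),
        )
        _, resolved, baseline = run_phase_locked(params, protocol, (0.0, 45000.0))
        # pass-1 landmarks agree with the independently detected baseline
        assert resolved.epochs[0].t_on == pytest.approx(baseline_bursts.onsets[0], abs=1.0)
        assert baseline["inspiration_onset"] == pytest.approx(baseline_bursts.onsets[0], abs=1.0)

    def test_fractional_offset_lands_mid_expiration(self, params):
        protocol = StimulusProtocol(
            (StimulusEpoch(frozenset({2, 5}), 1.0, t_on=0.0, duration=300.0),),
            PhaseLockedOnset("expiration-onset", cycle_index=0, offset_fraction=0.5),
        )
        _, resolved, baseline = run_phase_locked(params, protocol, (0.0, 45000.0))
        expected = baseline["inspiration_offset"] + 0.5 * baseline["T_E"]
        assert resolved.epochs[0].t_on == pytest.approx(expected)
        assert baseline["inspiration_offset"] < resolved.epochs[0].t_on < baseline["next_inspiration_onset"]

    def test_apnea_cannot_phase_lock(self):
        params = ModelParameters().replace(
            drive=(0, 0, 0, 0, 0), g_NaP=0.0, E_L=-62.0)
        protocol = StimulusProtocol(
            (StimulusEpoch(frozenset({2, 5}), 1.0, t_on=0.0, duration=300.0),),
            PhaseLockedOnset("inspiration-onset"),
        )
        with pytest.raises(RuntimeError, match="apnea|rhythm"):
            run_phase_locked(params, protocol, (0.0, 45000.0))
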