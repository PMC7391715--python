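"""HMM state recovery, dwell statistics, sliding occupancy and g(V) curves."""

import numpy as np
import pytest

from trapnoise import (
    CurrentTrace,
    FlatCurveError,
    K_B,
    NoTwoLevelStructureError,
    Q_E,
    RTSTrace,
    compose_trace,
    dwell_times,
    fit_two_state_hmm,
    g_curve,
    make_fixture,
    rts_amplitude,
    simulate_rts,
    sliding_g,
)


class TestHMM:
    def test_noiseless_trace_exact_recovery(self, device, trap):
        trace = compose_trace(device, trap, 0.0, 2.0, 1e-4, seed=1,
                              include_dp=False, white_sigma=0.0)
        res = fit_two_state_hmm(trace, seed=0)
        assert np.array_equal(res.states, trace.states)
        assert res.emission_sigma < 1e-3 * res.delta_i

    def test_noisy_recovery_at_snr5(self, device, trap):
        # Delta_I / sigma = 5, gamma = 488: >= 99% decoded accuracy and
        # switching rates within 10% of ground truth.
        sigma = rts_amplitude(device, trap) / 5
        trace = compose_trace(device, trap, 0.0, 10.0, 1e-4, seed=3,
                              include_dp=False, white_sigma=sigma)
        res = fit_two_state_hmm(trace, seed=0)
        assert np.mean(res.states == trace.states) >= 0.99
        dw = dwell_times(res.states, dt=trace.dt)
        assert dw.tau_c_hat == pytest.approx(1 / 488, rel=0.10)
        assert dw.tau_e_hat == pytest.approx(1 / 488, rel=0.10)

    def test_fitted_levels_and_amplitude(self, device, trap):
        sigma = rts_amplitude(device, trap) / 6
        trace = compose_trace(device, trap, 0.0, 5.0, 1e-4, seed=8,
                              include_dp=False, white_sigma=sigma, baseline=1e-6)
        res = fit_two_state_hmm(trace, seed=0)
        assert res.level_low < res.level_high
        assert res.delta_i == pytest.approx(rts_amplitude(device, trap), rel=0.05)
        assert res.emission_sigma == pytest.approx(sigma, rel=0.1)

    def test_zero_variance_rejected(self):
        trace = CurrentTrace(dt=1e-4, current=np.ones(2000))
        with pytest.raises(NoTwoLevelStructureError):
            fit_two_state_hmm(trace)

    def test_trapfree_trace_rejected(self):
        # DP + white noise only: no two-level structure to find.
        fx = make_fixture("trapfree", seed=2, duration=10.0)
        with pytest.raises(NoTwoLevelStructureError):
            fit_two_state_hmm(fx["trace"], seed=0)

    def test_short_trace_rejected(self, device, trap):
        trace = compose_trace(device, trap, 0.0, 0.05, 1e-4, seed=1, include_dp=False)
        with pytest.raises(ValueError, match="short"):
            fit_two_state_hmm(trace)

    def test_occupied_level_high_convention(self, device, trap):
        trace = compose_trace(device, trap, 0.0, 2.0, 1e-4, seed=5,
                              include_dp=False, occupied_lowers_current=False)
        res = fit_two_state_hmm(trace, seed=0, occupied_level="high")
        assert np.mean(res.states == trace.states) > 0.999


class TestDwellTimes:
    def test_hand_countable_runs(self):
        # One interior run: three samples of state 1 at dt = 1 ms;
        # censored edge runs are dropped, so no capture dwell survives.
        states = RTSTrace(dt=1e-3, states=[0, 0, 1, 1, 1, 0, 0])
        dw = dwell_times(states)
        assert dw.emission_dwells.tolist() == pytest.approx([3e-3])
        assert dw.capture_dwells.size == 0
        assert np.isnan(dw.tau_c_hat)
        assert dw.tau_e_hat == pytest.approx(3e-3)

    def test_too_few_transitions_rejected(self):
        with pytest.raises(ValueError, match="transitions"):
            dwell_times(RTSTrace(dt=1e-3, states=[0, 0, 1, 1]))

    def test_symmetric_rate_recovery(self):
        trace = simulate_rts(488.0, 488.0, duration=100.0, dt=2e-5, seed=21)
        dw = dwell_times(trace)
        assert dw.tau_c_hat == pytest.approx(1 / 488, rel=0.05)
        assert dw.tau_e_hat == pytest.approx(1 / 488, rel=0.05)
        assert not dw.warnings

    def test_low_transition_count_warns(self):
        trace = simulate_rts(20.0, 20.0, duration=5.0, dt=1e-4, seed=2)
        dw = dwell_times(trace)
        assert any("transitions" in w for w in dw.warnings)


class TestSlidingG:
    def test_all_ones(self):
        trace = RTSTrace(dt=1e-3, states=np.ones(1000, dtype=int))
        g = sliding_g(trace, theta=0.1)
        assert np.all(g.g == 1.0)

    def test_square_wave_window_equals_period(self):
        # Theta = one full period of a deterministic square wave -> g = 1/2.
        period = 200  # samples
        states = np.tile(np.r_[np.ones(period // 2), np.zeros(period // 2)], 10)
        trace = RTSTrace(dt=1e-3, states=states.astype(int))
        g = sliding_g(trace, theta=period * 1e-3)
        assert np.allclose(g.g, 0.5)

    def test_output_length(self):
        trace = RTSTrace(dt=1e-3, states=np.zeros(1000, dtype=int))
        g = sliding_g(trace, theta=0.1, stride=0.01)
        # floor((duration - theta)/stride) + 1
        assert len(g) == int((1.0 - 0.1) / 0.01) + 1

    def test_window_longer_than_trace_rejected(self):
        trace = RTSTrace(dt=1e-3, states=np.zeros(100, dtype=int))
        with pytest.raises(ValueError, match="theta"):
            sliding_g(trace, theta=1.0)

    def test_mean_matches_stationary_occupancy(self):
        gamma, theta = 488.0, 0.1
        trace = simulate_rts(gamma, gamma, duration=60.0, dt=1e-4, seed=17)
        g = sliding_g(trace, theta=theta, stride=theta)
        # Var[g^Theta] from the integrated autocovariance of the chain.
        var = 0.5 / theta**2 * (theta / (2 * gamma) - (1 - np.exp(-2 * gamma * theta)) / (4 * gamma**2))
        n_eff = len(g)
        assert np.mean(g.g) == pytest.approx(0.5, abs=4 * np.sqrt(var / n_eff) + 1e-3)

    def test_variance_decreases_with_window(self):
        trace = simulate_rts(100.0, 100.0, duration=100.0, dt=1e-3, seed=9)
        variances = [np.var(sliding_g(trace, theta=th).g) for th in (0.1, 0.5, 2.0, 5.0)]
        assert np.all(np.diff(variances) < 0)

    def test_bounds(self):
        trace = simulate_rts(100.0, 300.0, duration=20.0, dt=1e-3, seed=4)
        g = sliding_g(trace, theta=0.25)
        assert g.g.min() >= 0.0 and g.g.max() <= 1.0


class TestGCurve:
    def test_parameter_recovery_from_fixture(self, device):
        # alpha = 0.5 trap sampled at 7 voltages spanning the transition:
        # midpoint within 2 mV, slope scale within 10%.
        fx = make_fixture("steep_slope", seed=5)
        gc = g_curve(fx["traces"])
        assert abs(gc.v0 - fx["trap"].V0) < 2e-3
        expected_scale = K_B * device.T / (Q_E * fx["trap"].alpha)
        assert gc.scale == pytest.approx(expected_scale, rel=0.10)

    def test_recovery_bias_over_replicates(self, device):
        # Recovered coupling alpha biased by < 10% across seeded replicates.
        scales = []
        for seed in range(8):
            fx = make_fixture("steep_slope", seed=seed, duration=20.0)
            scales.append(g_curve(fx["traces"]).scale)
        expected = K_B * device.T / (Q_E * 0.5)
        assert np.mean(scales) == pytest.approx(expected, rel=0.10)

    def test_max_slope_at_half_occupancy(self):
        fx = make_fixture("steep_slope", seed=5)
        gc = g_curve(fx["traces"])
        v = np.linspace(gc.V_G.min(), gc.V_G.max(), 501)
        slopes = gc.g_g(v)
        v_peak = v[np.argmax(slopes)]
        assert abs(gc.g_model(np.array([v_peak]))[0] - 0.5) < 0.02
        assert gc.g_g_max == pytest.approx(slopes.max(), rel=1e-3)

    def test_flat_curve_rejected(self):
        traces = [(v, RTSTrace(dt=1e-3, states=np.ones(100, dtype=int)))
                  for v in (0.0, 0.01, 0.02, 0.03)]
        with pytest.raises(FlatCurveError):
            g_curve(traces)

    def test_too_few_voltages_rejected(self):
        traces = [(v, RTSTrace(dt=1e-3, states=np.ones(100, dtype=int)))
                  for v in (0.0, 0.01, 0.02)]
        with pytest.raises(ValueError, match="4"):
            g_curve(traces)
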