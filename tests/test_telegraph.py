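"""Telegraph-process simulation and composite-trace synthesis."""

import numpy as np
import pytest
from scipy.stats import kstest

from trapnoise import (
    DeviceModel,
    TrapModel,
    compose_trace,
    dwell_times,
    estimate_psd,
    log_rebin,
    occupancy,
    rts_amplitude,
    simulate_rts,
    synthesize_flicker,
    trap_times,
)


class TestTrapTimes:
    def test_reference_voltage_identity(self, trap, device):
        tau_c, tau_e = trap_times(trap, device, trap.V0)
        assert tau_c == pytest.approx(trap.tau_c0)
        assert tau_e == pytest.approx(trap.tau_e0)

    def test_symmetric_rates_give_half_occupancy(self, device):
        trap = TrapModel(tau_c0=1 / 488, tau_e0=1 / 488)
        tau_c, tau_e = trap_times(trap, device, trap.V0)
        assert 1 / tau_c == pytest.approx(488.0)
        assert 1 / tau_e == pytest.approx(488.0)
        assert occupancy(trap, device, trap.V0) == pytest.approx(0.5)

    def test_thermally_activated_capture(self, device):
        # alpha=0.5, T=300 K, +59.8 mV: exponent q*0.5*0.0598/kT = 1.1565
        trap = TrapModel(tau_c0=1e-3, tau_e0=1e-3, alpha=0.5, V0=0.0)
        dev = DeviceModel(W=device.W, L=device.L, C_G=device.C_G,
                          tg_delta=device.tg_delta, g_m=device.g_m,
                          N_ot=device.N_ot, T=300.0)
        tau_c, tau_e = trap_times(trap, dev, 0.0598)
        assert tau_c == pytest.approx(1e-3 * np.exp(-1.1565), rel=1e-3)
        assert tau_e == pytest.approx(1e-3)

    def test_overflow_guard(self, trap, device):
        with pytest.raises(ValueError, match="exponent"):
            trap_times(trap, device, 1e6)

    def test_emission_constant_capture_monotone(self, trap, device):
        vg = np.linspace(-0.1, 0.1, 11)
        taus = [trap_times(trap, device, v) for v in vg]
        tau_c = np.array([t[0] for t in taus])
        tau_e = np.array([t[1] for t in taus])
        assert np.all(np.diff(tau_c) < 0)
        assert np.all(tau_e == trap.tau_e0)


class TestOccupancy:
    def test_ratio(self, device):
        trap = TrapModel(tau_c0=1e-3, tau_e0=3e-3)
        assert occupancy(trap, device, 0.0) == pytest.approx(0.75)

    def test_depleted_limit(self, trap, device):
        assert occupancy(trap, device, -0.5) < 1e-3

    def test_monotone_in_gate_voltage(self, trap, device):
        vg = np.linspace(-0.2, 0.2, 41)
        g = np.array([occupancy(trap, device, v) for v in vg])
        assert np.all(np.diff(g) > 0)
        assert np.all((g > 0) & (g < 1))


class TestSimulateRTS:
    def test_near_absorbing_limit(self):
        trace = simulate_rts(1e-9, 1e3, duration=1.0, dt=1e-3, seed=0, initial_state=0)
        assert np.all(trace.states == 0)

    def test_transition_count_matches_stationary_chain(self):
        # Expected transitions = duration * 2*lam*mu/(lam+mu) = 10_000.
        lam = mu = 100.0
        trace = simulate_rts(lam, mu, duration=100.0, dt=1e-4, seed=7)
        n_trans = np.count_nonzero(np.diff(trace.states))
        assert abs(n_trans - 10_000) < 4 * np.sqrt(10_000)

    def test_ergodic_occupancy(self):
        trace = simulate_rts(488.0, 488.0, duration=50.0, dt=1e-4, seed=3)
        n_trans = np.count_nonzero(np.diff(trace.states))
        g_hat = trace.states.mean()
        assert abs(g_hat - 0.5) <= 4 * np.sqrt(0.25 / n_trans)

    def test_asymmetric_occupancy(self):
        lam, mu = 300.0, 100.0
        trace = simulate_rts(lam, mu, duration=50.0, dt=1e-4, seed=4)
        n_trans = np.count_nonzero(np.diff(trace.states))
        g = lam / (lam + mu)
        assert abs(trace.states.mean() - g) <= 4 * np.sqrt(g * (1 - g) / n_trans)

    def test_dwell_times_exponential(self):
        # KS test against the exponential law with the input mean must not
        # reject at the 1% level on ~1e4 dwells.
        gamma = 100.0
        trace = simulate_rts(gamma, gamma, duration=110.0, dt=5e-5, seed=11)
        dw = dwell_times(trace)
        assert dw.capture_dwells.size > 4500
        for dwells in (dw.capture_dwells, dw.emission_dwells):
            stat = kstest(dwells, "expon", args=(0, 1 / gamma))
            assert stat.pvalue > 0.01

    def test_grid_resampling_retains_events(self):
        # dt at 1% of the mean dwell: < ~1% of transitions may be lost.
        gamma = 50.0
        trace = simulate_rts(gamma, gamma, duration=200.0, dt=2e-4, seed=5)
        n_trans = np.count_nonzero(np.diff(trace.states))
        expected = 200.0 * gamma
        assert n_trans > expected * 0.985 - 4 * np.sqrt(expected)
        assert n_trans < expected + 4 * np.sqrt(expected)

    def test_determinism(self):
        a = simulate_rts(488, 488, 1.0, 1e-4, seed=9)
        b = simulate_rts(488, 488, 1.0, 1e-4, seed=9)
        assert np.array_equal(a.states, b.states)

    @pytest.mark.parametrize("bad", [dict(lambda_rate=-1, mu_rate=1),
                                     dict(lambda_rate=np.inf, mu_rate=1),
                                     dict(lambda_rate=1, mu_rate=0)])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_rts(duration=1.0, dt=1e-3, **bad)

    def test_duration_shorter_than_dt_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_rts(10, 10, duration=1e-4, dt=1e-3)


class TestFlicker:
    def test_zero_level_gives_zeros(self):
        assert np.all(synthesize_flicker(0.0, 1.0, 1e-3, seed=0) == 0)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            synthesize_flicker(-1e-9, 1.0, 1e-3)

    def test_psd_level_and_slope(self):
        # Requested level at 10 Hz recovered within 15%, log-log slope -1 +- 0.1.
        level = 1e-9
        x = synthesize_flicker(level, duration=100.0, dt=1e-3, seed=2)
        psd = estimate_psd(x, dt=1e-3, segment_seconds=25.0)
        band = (psd.f >= 8) & (psd.f <= 12.5)
        level_10 = np.mean(psd.S[band] * psd.f[band] / 10.0)
        assert level_10 == pytest.approx(level / 10.0, rel=0.15)
        sel = (psd.f >= 0.5) & (psd.f <= 250)
        fb, Sb = log_rebin(psd.f[sel], psd.S[sel], n_bins=30)
        slope = np.polyfit(np.log10(fb), np.log10(Sb), 1)[0]
        assert -1.1 <= slope <= -0.9

    def test_variance_matches_log_band_integral(self):
        level = 2e-9
        dt, duration = 1e-3, 100.0
        x = synthesize_flicker(level, duration, dt, seed=6)
        f_low, f_ny = 1.0 / duration, 0.5 / dt
        assert x.var() == pytest.approx(level * np.log(f_ny / f_low), rel=0.15)

    def test_zero_mean(self):
        x = synthesize_flicker(1e-9, 10.0, 1e-3, seed=1)
        assert abs(x.mean()) < 1e-3 * x.std()


class TestComposeTrace:
    def test_amplitude_formula(self):
        # g_m = 1 uS, q* = 0.5 q, C_total = 7.1e-17 F -> ~1.13 nA
        dev = DeviceModel(W=1e-7, L=1e-7, C_G=7.1e-3, tg_delta=3.8e-3,
                          g_m=1e-6, N_ot=1e12, T=300.0)
        trap = TrapModel(tau_c0=1 / 488, tau_e0=1 / 488)
        assert rts_amplitude(dev, trap) == pytest.approx(1.128e-9, rel=1e-3)

    def test_pure_two_level(self, device, trap):
        trace = compose_trace(device, trap, 0.0, 1.0, 1e-4, seed=1,
                              include_dp=False, white_sigma=0.0, baseline=1e-6)
        levels = np.unique(trace.current)
        assert levels.size == 2
        assert levels.max() == pytest.approx(1e-6)
        # occupied state lowers the current by Delta_I
        assert levels.max() - levels.min() == pytest.approx(rts_amplitude(device, trap))
        assert np.array_equal(trace.current == levels.min(), trace.states == 1)

    def test_sign_flag(self, device, trap):
        trace = compose_trace(device, trap, 0.0, 1.0, 1e-4, seed=1,
                              include_dp=False, occupied_lowers_current=False)
        hi = trace.current.max()
        assert np.array_equal(trace.current == hi, trace.states == 1)

    def test_component_flags_and_determinism(self, device, trap):
        a = compose_trace(device, trap, 0.0, 2.0, 1e-3, seed=42, white_sigma=1e-10)
        b = compose_trace(device, trap, 0.0, 2.0, 1e-3, seed=42, white_sigma=1e-10)
        assert np.array_equal(a.current, b.current)
        assert a.components == {"rts": True, "dp": True, "white": True}
        c = compose_trace(device, trap, 0.0, 2.0, 1e-3, seed=43, white_sigma=1e-10)
        assert not np.array_equal(a.current, c.current)

    def test_negative_white_sigma_rejected(self, device, trap):
        with pytest.raises(ValueError):
            compose_trace(device, trap, 0.0, 1.0, 1e-3, white_sigma=-1.0)
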