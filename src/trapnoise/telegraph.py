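"""Synthesis of random-telegraph-signal traces and their noise background.

The trap alternates between empty (state 0) and occupied (state 1) with
exponentially distributed dwell times: mean tau_c in state 0 before a
carrier is captured, mean tau_e in state 1 before it is emitted. State
sequences are generated event-by-event (exponential waiting times) and
only then resampled onto the uniform grid, so the dwell statistics are
exact up to grid quantization.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .models import K_B, Q_E, CurrentTrace, DeviceModel, RTSTrace, TrapModel

__all__ = [
    "trap_times",
    "occupancy",
    "simulate_rts",
    "synthesize_flicker",
    "compose_trace",
]

#: Largest admissible magnitude of the capture-time exponent. Beyond this
#: exp() overflows double precision and the parameters are unphysical.
_MAX_EXPONENT = 700.0


def trap_times(trap: TrapModel, device: DeviceModel, V_G: float) -> Tuple[float, float]:
    """Capture and emission times at gate voltage ``V_G``.

    The emission time is voltage-independent. The capture time is
    thermally activated through the gate-to-trap coupling ``alpha``:

        tau_c(V_G) = tau_c0 * exp(-q * alpha * (V_G - V0) / (k * T))

    so raising the gate voltage (more carriers under the gate) shortens
    the capture time exponentially.
    """
    exponent = -Q_E * trap.alpha * (V_G - trap.V0) / (K_B * device.T)
    if abs(exponent) > _MAX_EXPONENT:
        raise ValueError(
            f"capture-time exponent magnitude {abs(exponent):.3g} exceeds "
            f"{_MAX_EXPONENT:g}; check alpha, T and the voltage range"
        )
    tau_c = trap.tau_c0 * math.exp(exponent)
    return tau_c, trap.tau_e0


def occupancy(trap: TrapModel, device: DeviceModel, V_G: float) -> float:
    """Stationary trap occupancy probability g = tau_e / (tau_e + tau_c)."""
    tau_c, tau_e = trap_times(trap, device, V_G)
    return tau_e / (tau_e + tau_c)


def simulate_rts(
    lambda_rate: float,
    mu_rate: float,
    duration: float,
    dt: float,
    seed: Optional[int] = None,
    initial_state: "int | str" = "stationary",
) -> RTSTrace:
    """Simulate a two-state telegraph process on a uniform grid.

    Parameters
    ----------
    lambda_rate:
        Capture rate 1/tau_c (1/s), transitions 0 -> 1.
    mu_rate:
        Emission rate 1/tau_e (1/s), transitions 1 -> 0.
    duration, dt:
        Trace length and sample interval (s). ``dt * max(rate) << 1`` is
        recommended so that few dwells fall below the grid.
    initial_state:
        0, 1, or ``"stationary"`` (draw from the stationary distribution,
        avoiding an initial transient).

    The state at grid time ``k*dt`` is obtained by counting transition
    events up to that instant (point sampling of the event-driven path).
    """
    for name, r in (("lambda_rate", lambda_rate), ("mu_rate", mu_rate)):
        if not (np.isfinite(r) and r > 0):
            raise ValueError(f"{name} must be finite and > 0, got {r}")
    if duration < dt:
        raise ValueError(f"duration {duration} shorter than dt {dt}")

    rng = np.random.default_rng(seed)
    p_occupied = lambda_rate / (lambda_rate + mu_rate)
    if initial_state == "stationary":
        s0 = int(rng.random() < p_occupied)
    elif initial_state in (0, 1):
        s0 = int(initial_state)
    else:
        raise ValueError(f"initial_state must be 0, 1 or 'stationary', got {initial_state!r}")

    n = int(round(duration / dt))
    n = max(n, 1)

    # Dwell means alternate with the state; draw event times in blocks
    # until the path covers the full duration.
    mean_rate = 2.0 * lambda_rate * mu_rate / (lambda_rate + mu_rate)
    block = int(mean_rate * duration * 1.2) + 16
    event_times = np.empty(0)
    t_end = 0.0
    state_at_block_start = s0
    while t_end < duration:
        rates = np.where(
            (np.arange(block) + state_at_block_start) % 2 == 0, lambda_rate, mu_rate
        )
        dwells = rng.exponential(1.0, size=block) / rates
        new = t_end + np.cumsum(dwells)
        event_times = np.concatenate([event_times, new])
        t_end = new[-1]
        state_at_block_start = (state_at_block_start + block) % 2

    grid = np.arange(n) * dt
    n_events_before = np.searchsorted(event_times, grid, side="right")
    states = ((n_events_before + s0) % 2).astype(np.int8)
    return RTSTrace(dt=dt, states=states, seed=seed)


def synthesize_flicker(
    level_at_1Hz: float,
    duration: float,
    dt: float,
    seed: Optional[int] = None,
    f_low_cutoff: Optional[float] = None,
) -> np.ndarray:
    """Zero-mean series with a one-sided 1/f power spectral density.

    The target spectrum is S(f) = level_at_1Hz / f (V^2/Hz) between
    ``f_low_cutoff`` (default: the first Fourier bin, 1/duration) and the
    Nyquist frequency; below the cutoff the spectrum is held flat at the
    cutoff value. Construction is in the frequency domain: deterministic
    amplitudes proportional to f^(-1/2), independent uniform phases and
    conjugate symmetry, giving exact spectral control in O(N log N).
    """
    if level_at_1Hz < 0:
        raise ValueError(f"level_at_1Hz must be >= 0, got {level_at_1Hz}")
    n = int(round(duration / dt))
    if n < 2:
        raise ValueError("duration must cover at least two samples")
    if level_at_1Hz == 0.0:
        return np.zeros(n)

    fs = 1.0 / dt
    f = np.fft.rfftfreq(n, dt)
    if f_low_cutoff is None:
        f_low_cutoff = f[1]
    f_eff = np.maximum(f, f_low_cutoff)
    S = level_at_1Hz / f_eff
    # One-sided periodogram convention: S_k = 2 |X_k|^2 / (fs * n) for
    # interior bins.
    amp = np.sqrt(S * fs * n / 2.0)
    amp[0] = 0.0
    if n % 2 == 0:
        amp[-1] = 0.0  # drop the single Nyquist bin; negligible power
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amp.size)
    spectrum = amp * np.exp(1j * phases)
    return np.fft.irfft(spectrum, n=n)


def rts_amplitude(device: DeviceModel, trap: TrapModel) -> float:
    """RTS current step Delta_I = g_m * q* / (C_G * A) (A)."""
    return device.g_m * trap.q_star / device.C_total


def compose_trace(
    device: DeviceModel,
    trap: TrapModel,
    V_G: float,
    duration: float,
    dt: float,
    seed: Optional[int] = None,
    include_rts: bool = True,
    include_dp: bool = True,
    white_sigma: float = 0.0,
    baseline: float = 0.0,
    occupied_lowers_current: bool = True,
) -> CurrentTrace:
    """Synthesize a drain-current trace with RTS, DP and white components.

    The current is

        I(t) = baseline -/+ Delta_I * X(t) + g_m * v_DP(t) + white,

    where X is the telegraph state, Delta_I = g_m q*/(C_G A), and v_DP is
    dielectric-polarization gate-voltage noise synthesized at the level
    2 k T tg_delta / (pi C_total f). An occupied trap lowers the current
    by default (depletion-mode convention); set
    ``occupied_lowers_current=False`` to flip the sign.
    """
    if white_sigma < 0:
        raise ValueError(f"white_sigma must be >= 0, got {white_sigma}")
    n = int(round(duration / dt))
    if n < 1:
        raise ValueError("duration shorter than dt")

    ss = np.random.SeedSequence(seed)
    seed_rts, seed_dp, seed_white = (int(s.generate_state(1, dtype=np.uint64)[0] >> 33) for s in ss.spawn(3))

    current = np.full(n, baseline, dtype=float)
    states = None
    if include_rts:
        tau_c, tau_e = trap_times(trap, device, V_G)
        rts = simulate_rts(1.0 / tau_c, 1.0 / tau_e, duration, dt, seed=seed_rts)
        states = rts.states
        delta_i = rts_amplitude(device, trap)
        sign = -1.0 if occupied_lowers_current else 1.0
        current = current + sign * delta_i * states

    if include_dp:
        level = 2.0 * K_B * device.T * device.tg_delta / (np.pi * device.C_total)
        v_dp = synthesize_flicker(level, duration, dt, seed=seed_dp)
        current = current + device.g_m * v_dp

    if white_sigma > 0:
        rng = np.random.default_rng(seed_white)
        current = current + rng.normal(0.0, white_sigma, size=n)

    return CurrentTrace(
        dt=dt,
        current=current,
        V_G=V_G,
        components={"rts": include_rts, "dp": include_dp, "white": white_sigma > 0},
        seed=seed,
        states=states,
    )
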