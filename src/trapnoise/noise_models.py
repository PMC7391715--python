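"""Closed-form noise and signal models for transistor biosensors.

Four power spectral densities cover the relevant noise sources:

* trap-number fluctuation noise, S_q = q^2 N_ot A / f and its
  input-referred counterpart S_VG = q^2 N_ot / (C_G^2 A f) — the
  many-trap 1/f model valid when N_ot * A >> 1;
* dielectric-polarization (DP) noise, S_q = 2 k T tg_delta C / (pi f)
  and S_VG = 2 k T tg_delta / (pi C f) — the thermal limit set by
  dipole fluctuations in the gate insulator;
* the single-trap RTS Lorentzian,
  S_VG = 4 g (1-g)^2 tau_e (q*/C)^2 / (1 + (2 pi (1-g) tau_e f)^2).

All densities are one-sided. ``C`` denotes the *total* gate capacitance
C_G * A; formulas that are often quoted with the per-area symbol are
normalized here to total capacitance for consistency.

The ideal Nernstian ISFET response ln(10) kT/q per pH unit is included as
the reference signal for signal-to-noise comparisons.
"""

from __future__ import annotations

import math

import numpy as np

from .models import K_B, Q_E, DeviceModel

__all__ = [
    "sq_trap_number",
    "svg_trap_number",
    "sq_dp",
    "svg_dp",
    "svg_rts_lorentzian",
    "svg_rts_max",
    "nernst_signal",
    "corner_frequency",
    "RTS_MAX_COEFFICIENT",
    "RTS_MAX_COEFFICIENT_ROUNDED",
]

#: Exact prefactor of the RTS noise maximum at g = 1/2 (see svg_rts_max).
RTS_MAX_COEFFICIENT: float = 1.0 / (4.0 * math.pi)
#: The same prefactor rounded to two decimals, as commonly quoted.
RTS_MAX_COEFFICIENT_ROUNDED: float = 0.08


def _check_f(f):
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive (1/f forms diverge at 0)")
    return f


def sq_trap_number(device: DeviceModel, f) -> np.ndarray:
    """Charge noise density q^2 N_ot A / f (C^2/Hz) from trap-number fluctuations."""
    f = _check_f(f)
    return Q_E**2 * device.N_ot * device.area / f


def svg_trap_number(device: DeviceModel, f) -> np.ndarray:
    """Input-referred trap-number noise q^2 N_ot / (C_G^2 A f) (V^2/Hz).

    Identically equals ``sq_trap_number / C_total^2``.
    """
    f = _check_f(f)
    return Q_E**2 * device.N_ot / (device.C_G**2 * device.area * f)


def sq_dp(C_total: float, tg_delta: float, T: float, f) -> np.ndarray:
    """Dielectric-polarization charge noise 2 k T tg_delta C / (pi f) (C^2/Hz)."""
    if not C_total > 0:
        raise ValueError(f"C_total must be > 0, got {C_total}")
    f = _check_f(f)
    return 2.0 * K_B * T * tg_delta * C_total / (np.pi * f)


def svg_dp(C_total: float, tg_delta: float, T: float, f) -> np.ndarray:
    """Dielectric-polarization voltage noise 2 k T tg_delta / (pi C f) (V^2/Hz)."""
    if not C_total > 0:
        raise ValueError(f"C_total must be > 0, got {C_total}")
    f = _check_f(f)
    return 2.0 * K_B * T * tg_delta / (np.pi * C_total * f)


def svg_rts_lorentzian(g: float, tau_e: float, q_star: float, C_total: float, f) -> np.ndarray:
    """Input-referred RTS noise Lorentzian (V^2/Hz).

    ``g`` is the trap occupancy probability, ``tau_e`` the emission time,
    and ``q_star / C_total`` the single-charge gate-voltage step. The
    spectrum vanishes at g = 0 and g = 1 (no switching).
    """
    if not (0 <= g <= 1):
        raise ValueError(f"g must lie in [0, 1], got {g}")
    if not tau_e > 0:
        raise ValueError(f"tau_e must be > 0, got {tau_e}")
    f = np.asarray(f, dtype=float)
    v = q_star / C_total
    return 4.0 * g * (1.0 - g) ** 2 * tau_e * v**2 / (1.0 + (2.0 * np.pi * (1.0 - g) * tau_e * f) ** 2)


def svg_rts_max(q_star: float, C_total: float, f0: float) -> float:
    """Maximum of the RTS noise relative to the 1/f background (V^2/Hz).

    At g = 1/2 the Lorentzian exceeds a 1/f background the most at its
    corner frequency f0, where it evaluates to

        (1 / (4 pi)) * (q* / C_total)^2 / f0.

    The exact coefficient 1/(4 pi) = 0.0796 is used in the computation;
    its two-decimal rounding 0.08 is exposed as
    :data:`RTS_MAX_COEFFICIENT_ROUNDED`.
    """
    if not f0 > 0:
        raise ValueError(f"f0 must be > 0, got {f0}")
    return RTS_MAX_COEFFICIENT * (q_star / C_total) ** 2 / f0


def nernst_signal(delta_pH: float, T: float = 298.0) -> float:
    """Ideal ISFET threshold-voltage shift ln(10) k T / q * delta_pH (V).

    At 298 K this is 59.2 mV per pH unit; a 0.1 pH change gives 5.9 mV.
    """
    if not T > 0:
        raise ValueError(f"T must be > 0, got {T}")
    return math.log(10.0) * K_B * T / Q_E * delta_pH


def corner_frequency(tau_c: float, tau_e: float) -> float:
    """Lorentzian corner frequency f0 = (1/tau_c + 1/tau_e) / (2 pi) (Hz).

    Equivalently 1/(2 pi tau_eff) with tau_eff = (1-g) tau_e =
    tau_c tau_e / (tau_c + tau_e); for tau_c << tau_e (high occupancy)
    this reduces to 1/(2 pi tau_c).
    """
    if not (tau_c > 0 and tau_e > 0):
        raise ValueError("tau_c and tau_e must be > 0")
    tau_eff = tau_c * tau_e / (tau_c + tau_e)
    return 1.0 / (2.0 * math.pi * tau_eff)
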