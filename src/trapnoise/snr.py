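"""Signal-to-noise analysis: conventional vs. single-trap readout.

The conventional transistor biosensor reads a threshold-voltage shift
delta_V_Th against the input-referred voltage noise S_VG:

    S/N = delta_V_Th / sqrt( int_f1^f2 S_VG df ).

The single-trap readout monitors the trap occupancy instead; its noise is
the occupancy spectral density referred to the gate through the slope
g_g = dg/dV_G:

    S_gg = S_g / g_g^2,     S/N = delta_V_Th / sqrt( int_f1^f2 S_gg df ).

The default integration band is 0.1-100 Hz: it brackets the 10 Hz
reporting frequency, and its lower edge sits at 1/Theta for a 10 s
window so that the full averaging benefit of the occupancy estimator is
inside the band (a band starting at 1 Hz clips that benefit and makes
S/N non-monotonic in the corner frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .gnoise import ONE_SIDED_SCALE, sg_general, sg_general_envelope
from .models import DeviceModel, K_B, PSDResult, Q_E, TrapModel
from .noise_models import corner_frequency, svg_dp
from .telegraph import trap_times

__all__ = ["SNRConfig", "s_gg", "band_power", "snr_voltage", "snr_gfactor",
           "occupancy_noise_power", "snr_gfactor_analytic", "sweep"]


@dataclass(frozen=True)
class SNRConfig:
    """Operating point for S/N evaluation.

    ``delta_V_th`` is the signal (V), [f1, f2] the integration band (Hz),
    ``theta`` the occupancy averaging window (s), ``g`` the operating
    occupancy and ``g_g`` the occupancy slope dg/dV_G (1/V).
    """

    delta_V_th: float
    f1: float = 0.1
    f2: float = 100.0
    theta: float = 10.0
    g: float = 0.5
    g_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta_V_th < 0:
            raise ValueError(f"delta_V_th must be >= 0, got {self.delta_V_th}")
        if not (0 < self.f1 < self.f2):
            raise ValueError(f"need 0 < f1 < f2, got f1={self.f1}, f2={self.f2}")


def logistic_slope(g: float, alpha: float, T: float) -> float:
    """Slope dg/dV_G = g (1-g) q alpha / (k T) of the logistic occupancy curve."""
    return g * (1.0 - g) * Q_E * alpha / (K_B * T)


def s_gg(S_g: Union[np.ndarray, PSDResult], g_g: float) -> Union[np.ndarray, PSDResult]:
    """Input-referred occupancy noise S_gg = S_g / g_g^2 (V^2/Hz), pointwise."""
    if g_g == 0:
        raise ValueError("g_g = 0: operating point has no sensitivity")
    if isinstance(S_g, PSDResult):
        return PSDResult(f=S_g.f, S=S_g.S / g_g**2, meta={**S_g.meta, "g_g": g_g})
    return np.asarray(S_g, dtype=float) / g_g**2


def band_power(f: np.ndarray, S: np.ndarray, f1: float, f2: float) -> float:
    """Trapezoid integral of a sampled density over [f1, f2].

    The grid must cover the band; band-edge values are obtained by
    interpolation.
    """
    f = np.asarray(f, dtype=float)
    S = np.asarray(S, dtype=float)
    if f1 < f.min() or f2 > f.max():
        raise ValueError(
            f"band [{f1}, {f2}] Hz outside spectrum grid [{f.min():g}, {f.max():g}] Hz"
        )
    inside = (f > f1) & (f < f2)
    fi = np.concatenate([[f1], f[inside], [f2]])
    Si = np.concatenate([[np.interp(f1, f, S)], S[inside], [np.interp(f2, f, S)]])
    return float(np.trapezoid(Si, fi))


def snr_voltage(config: SNRConfig, psd: PSDResult) -> float:
    """S/N of voltage-shift readout against the supplied S_VG spectrum."""
    power = band_power(psd.f, psd.S, config.f1, config.f2)
    if power <= 0:
        raise ValueError("noise power in band is not positive")
    return config.delta_V_th / np.sqrt(power)


def snr_gfactor(config: SNRConfig, psd_gg: PSDResult) -> float:
    """S/N of occupancy readout against the supplied S_gg spectrum.

    Formally identical to :func:`snr_voltage`; the distinction is which
    density is integrated.
    """
    return snr_voltage(config, psd_gg)


def occupancy_noise_power(
    lam: float, mu: float, theta: float, f1: float, f2: float
) -> float:
    """Integral of the one-sided occupancy density S_g over [f1, f2] (dimensionless).

    Integrates the exact oscillatory form below f = 1/theta and its
    smooth envelope (mean of the oscillation) above, which agrees with
    the exact integral to within a fraction of one oscillation period.
    """
    if not (0 < f1 < f2):
        raise ValueError("need 0 < f1 < f2")
    fc = 1.0 / theta
    total = 0.0
    if f1 < fc:
        hi = min(fc, f2)
        val, _ = quad(lambda f: sg_general(2 * np.pi * f, lam, mu, theta), f1, hi,
                      epsrel=1e-9, limit=400)
        total += val
    if f2 > fc:
        lo = max(fc, f1)
        # Integrate in log-frequency: the envelope spans many decades.
        val, _ = quad(
            lambda u: np.exp(u) * sg_general_envelope(np.exp(u), lam, mu, theta),
            np.log(lo), np.log(f2), epsrel=1e-9, limit=400,
        )
        total += val
    return ONE_SIDED_SCALE * total


def snr_gfactor_analytic(config: SNRConfig, lam: float, mu: float) -> float:
    """S/N of occupancy readout from the closed-form occupancy spectrum."""
    if config.g_g is None:
        raise ValueError("config.g_g is required for the analytic S/N")
    power = occupancy_noise_power(lam, mu, config.theta, config.f1, config.f2) / config.g_g**2
    return config.delta_V_th / np.sqrt(power)


def _dp_band_power(device: DeviceModel, f1: float, f2: float) -> float:
    # Closed-form integral of the 1/f DP density.
    return float(svg_dp(device.C_total, device.tg_delta, device.T, 1.0)) * np.log(f2 / f1)


def sweep(
    axis: str,
    values: Sequence[float],
    config: SNRConfig,
    device: DeviceModel,
    trap: TrapModel,
    report_f: float = 10.0,
) -> pd.DataFrame:
    """Parameter sweep of the occupancy-readout noise and S/N.

    ``axis`` is one of:

    * ``"f0"`` — RTS corner frequency (Hz), symmetric chain at g = 1/2
      (gamma = pi f0);
    * ``"g"`` — operating occupancy at fixed emission time ``trap.tau_e0``
      (the corner frequency then rises with g, approaching
      1/(2 pi tau_c) at high g); the slope g_g follows the logistic
      model at each g;
    * ``"theta"`` — occupancy averaging window (s) at the trap's own rates.

    Each row reports the one-sided S_gg at ``report_f`` and the occupancy
    S/N, alongside the DP (thermal-limit) references for the same device:
    S_VG at ``report_f`` and the voltage-readout S/N.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty sweep range")
    if axis not in ("f0", "g", "theta"):
        raise ValueError(f"axis must be 'f0', 'g' or 'theta', got {axis!r}")

    dp_10 = float(svg_dp(device.C_total, device.tg_delta, device.T, report_f))
    dp_snr = config.delta_V_th / np.sqrt(_dp_band_power(device, config.f1, config.f2))

    rows = []
    for v in values:
        theta = config.theta
        if axis == "f0":
            gamma = np.pi * v
            lam = mu = gamma
            g = 0.5
            f0 = v
            g_g = config.g_g if config.g_g is not None else logistic_slope(g, trap.alpha, device.T)
        elif axis == "g":
            g = float(v)
            if not (0 < g < 1):
                raise ValueError(f"g values must lie in (0, 1), got {g}")
            tau_e = trap.tau_e0
            tau_c = tau_e * (1.0 - g) / g
            lam, mu = 1.0 / tau_c, 1.0 / tau_e
            f0 = corner_frequency(tau_c, tau_e)
            g_g = logistic_slope(g, trap.alpha, device.T)
        else:  # theta
            theta = float(v)
            tau_c, tau_e = trap_times(trap, device, trap.V0)
            lam, mu = 1.0 / tau_c, 1.0 / tau_e
            g = lam / (lam + mu)
            f0 = corner_frequency(tau_c, tau_e)
            g_g = config.g_g if config.g_g is not None else logistic_slope(g, trap.alpha, device.T)

        if report_f < 1.0 / theta:
            sg_10 = ONE_SIDED_SCALE * float(sg_general(2 * np.pi * report_f, lam, mu, theta))
        else:
            sg_10 = ONE_SIDED_SCALE * float(sg_general_envelope(report_f, lam, mu, theta))
        sgg_10 = sg_10 / g_g**2
        power = occupancy_noise_power(lam, mu, theta, config.f1, config.f2) / g_g**2
        rows.append(
            {
                axis: float(v),
                "f0_Hz": float(f0),
                "g": float(g),
                "g_g_per_V": float(g_g),
                "S_g_at_report_f": sg_10,
                "S_gg_at_report_f": sgg_10,
                "snr_gfactor": config.delta_V_th / np.sqrt(power),
                "S_vg_dp_at_report_f": dp_10,
                "snr_voltage_dp": dp_snr,
            }
        )
    return pd.DataFrame(rows)
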