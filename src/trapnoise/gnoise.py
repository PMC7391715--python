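"""Analytic model of the sliding-window occupancy ("g-factor") noise.

The telegraph state X_t is a two-state continuous-time Markov chain with
capture rate lambda (0 -> 1) and emission rate mu (1 -> 0). The windowed
occupancy g^Theta(t) is X_t filtered by a boxcar of width Theta. Its
transition probabilities, autocorrelation and power spectral density have
closed forms; a brute-force simulation oracle is provided alongside.

For the symmetric chain (lambda = mu = gamma, occupancy 1/2):

    S_g(omega) = 2 gamma (1 - cos(Theta omega))
                 / (Theta^2 omega^2 (4 gamma^2 + omega^2)),

with the finite limit 1/(4 gamma) at omega = 0. This expression is the
two-sided spectral density in angular frequency; the one-sided density in
ordinary frequency that a Welch estimator measures on the sliding-g trace
is ONE_SIDED_SCALE * S_g(2 pi f). The factor was fixed once by
calibration against :func:`sg_numeric_oracle` and is pinned by a
regression test.

The (1 - cos) factor has exact nulls at f = k/Theta, so pointwise
comparison with estimated spectra is meaningless there; comparisons use
either :func:`sg_theta_band_mean` (quadrature mean over a frequency bin,
valid at all f) or the smooth envelope :func:`sg_theta_envelope`
(replacing 1 - cos by its mean 1; valid for f >= 1/Theta).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.integrate import quad

from .models import PSDResult
from .spectral import estimate_psd
from .telegraph import simulate_rts

__all__ = [
    "ONE_SIDED_SCALE",
    "transition_matrix",
    "autocorr_g",
    "sg_theta",
    "sg_general",
    "sg_theta_envelope",
    "sg_general_envelope",
    "sg_theta_band_mean",
    "sg_numeric_oracle",
]

#: Conversion from the two-sided angular-frequency density sg_theta to the
#: one-sided density in f measured by a Welch estimator on sliding-g data.
ONE_SIDED_SCALE: float = 2.0


def _check_rates(lam: float, mu: float) -> None:
    if not (lam > 0 and mu > 0 and np.isfinite(lam) and np.isfinite(mu)):
        raise ValueError(f"rates must be finite and > 0, got lambda={lam}, mu={mu}")


def transition_matrix(lam: float, mu: float, t: float) -> np.ndarray:
    """Transition probabilities P_ij(t) = P(X_t = j | X_0 = i).

    P(t) decomposes into the stationary part and a transient decaying as
    exp(-(lambda + mu) t); rows sum to 1 for every t >= 0.
    """
    _check_rates(lam, mu)
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    r = lam + mu
    stationary = np.array([[mu, lam], [mu, lam]]) / r
    transient = np.array([[-lam, lam], [mu, -mu]]) / r
    return stationary - np.exp(-r * t) * transient


def autocorr_g(lam: float, mu: float, theta: float, s: float) -> float:
    """Autocorrelation C(s) = E[g^Theta(t) g^Theta(t + s)] of the occupancy.

    Computed by numeric double integration of the joint occupation
    probability over the two windows,

        C(s) = (1/Theta^2) int_0^Theta int_s^{s+Theta}
               P(X_max(u,v) = 1 | X_min(u,v) = 1) P(X_min(u,v) = 1) du dv,

    using :func:`transition_matrix` for the conditional and the
    stationary probability lambda/(lambda+mu) for the marginal. Valid for
    general lambda != mu. The inner integration domain is split at u = v
    to keep the |u - v| kink away from the quadrature. Relative tolerance
    1e-8 on each level.
    """
    _check_rates(lam, mu)
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    if s < 0:
        raise ValueError(f"s must be >= 0, got {s}")
    g_stat = lam / (lam + mu)

    def p11(tau: float) -> float:
        return transition_matrix(lam, mu, tau)[1, 1]

    def inner(u: float) -> float:
        lo, hi = s, s + theta
        if lo < u < hi:
            a, _ = quad(lambda v: p11(u - v), lo, u, epsrel=1e-8, limit=200)
            b, _ = quad(lambda v: p11(v - u), u, hi, epsrel=1e-8, limit=200)
            val = a + b
        else:
            val, _ = quad(lambda v: p11(abs(v - u)), lo, hi, epsrel=1e-8, limit=200)
        return val

    outer, _ = quad(inner, 0.0, theta, epsrel=1e-8, limit=200)
    return g_stat * outer / theta**2


def sg_theta(omega, gamma: float, theta: float):
    """Spectral density of g^Theta for the symmetric chain (lambda = mu = gamma).

    Two-sided density in angular frequency omega (rad/s); multiply by
    :data:`ONE_SIDED_SCALE` and evaluate at omega = 2 pi f for the
    one-sided density a spectrum estimator measures. The omega -> 0 limit
    is 1/(4 gamma). Exact nulls occur at Theta omega = 2 pi k.
    """
    if not (gamma > 0 and theta > 0):
        raise ValueError("gamma and theta must be > 0")
    omega = np.asarray(omega, dtype=float)
    scalar = omega.ndim == 0
    omega = np.atleast_1d(omega)
    out = np.empty_like(omega)
    small = np.abs(theta * omega) < 1e-6
    w = omega[~small]
    out[~small] = 2.0 * gamma * (1.0 - np.cos(theta * w)) / (theta**2 * w**2 * (4.0 * gamma**2 + w**2))
    # Taylor limit: (1 - cos x)/x^2 -> 1/2, so S -> gamma/(4 gamma^2 + w^2).
    ws = omega[small]
    out[small] = gamma / (4.0 * gamma**2 + ws**2)
    return out[0] if scalar else out


def sg_general(omega, lam: float, mu: float, theta: float):
    """Occupancy spectral density for a general (possibly asymmetric) chain.

    The telegraph autocovariance is g(1-g) exp(-(lambda+mu)|s|), so the
    boxcar-filtered process has two-sided density

        S_g(omega) = [2 g (1-g) r / (r^2 + omega^2)]
                     * [2 (1 - cos(Theta omega)) / (Theta omega)^2]

    with r = lambda + mu. Reduces exactly to :func:`sg_theta` when
    lambda = mu (cross-checked against :func:`autocorr_g` in the tests).
    """
    _check_rates(lam, mu)
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    r = lam + mu
    g = lam / r
    omega = np.asarray(omega, dtype=float)
    scalar = omega.ndim == 0
    omega = np.atleast_1d(omega)
    source = 2.0 * g * (1.0 - g) * r / (r**2 + omega**2)
    x = theta * omega
    filt = np.ones_like(x)
    big = np.abs(x) >= 1e-6
    filt[big] = 2.0 * (1.0 - np.cos(x[big])) / x[big] ** 2
    out = source * filt
    return out[0] if scalar else out


def sg_general_envelope(f, lam: float, mu: float, theta: float):
    """Smooth envelope of :func:`sg_general`: (1 - cos) replaced by its mean 1.

    Valid for f >= 1/Theta, like :func:`sg_theta_envelope`. Two-sided in
    omega.
    """
    _check_rates(lam, mu)
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    r = lam + mu
    g = lam / r
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    return 2.0 * g * (1.0 - g) * r / (r**2 + w**2) * 2.0 / (theta * w) ** 2


def sg_theta_envelope(f, gamma: float, theta: float):
    """Band-averaged envelope of sg_theta: (1 - cos) replaced by its mean 1.

    Matches the local frequency average of the exact expression once the
    oscillation is faster than the analysis bandwidth, i.e. for
    f >= 1/Theta; below that the exact form should be used instead.
    Two-sided in omega, like :func:`sg_theta`.
    """
    if not (gamma > 0 and theta > 0):
        raise ValueError("gamma and theta must be > 0")
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    return 2.0 * gamma / (theta**2 * w**2 * (4.0 * gamma**2 + w**2))


def sg_theta_band_mean(gamma: float, theta: float, f_lo: float, f_hi: float) -> float:
    """Mean of the exact sg_theta over the frequency band [f_lo, f_hi].

    Used when comparing against estimated spectra, whose bins average over
    many Fourier frequencies and therefore never see the (1 - cos) nulls.
    Two-sided in omega, like :func:`sg_theta`.
    """
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    # Dense trapezoid with ~200 samples per oscillation period of the
    # (1 - cos) term; adaptive quadrature misjudges this integrand.
    n_osc = (f_hi - f_lo) * theta
    n = max(2001, int(200 * n_osc) | 1)
    f = np.linspace(f_lo, f_hi, n)
    return float(np.trapezoid(sg_theta(2.0 * np.pi * f, gamma, theta), f)) / (f_hi - f_lo)


def sg_numeric_oracle(
    gamma: float,
    theta: float,
    duration: float,
    dt: float,
    n_reps: int = 1,
    seed: Optional[int] = None,
    segment_seconds: Optional[float] = None,
) -> PSDResult:
    """Brute-force occupancy spectrum: simulate, slide the window, Welch.

    Simulates ``n_reps`` symmetric telegraph traces, computes the
    sliding-window occupancy with stride dt, and averages the Welch
    spectra. The result is a one-sided density in f, directly comparable
    to ``ONE_SIDED_SCALE * sg_theta(2 pi f, ...)``.
    """
    from .extraction import sliding_g  # local import to avoid a cycle

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if duration < 10 * theta:
        raise ValueError(f"duration {duration} too short for window {theta} (need >= 10x)")
    ss = np.random.SeedSequence(seed)
    spectra = []
    f = None
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1, dtype=np.uint64)[0] >> 33)
        rts = simulate_rts(gamma, gamma, duration, dt, seed=rep_seed)
        g = sliding_g(rts, theta, stride=dt)
        psd = estimate_psd(g, segment_seconds=segment_seconds)
        f = psd.f
        spectra.append(psd.S)
    return PSDResult(
        f=f,
        S=np.mean(spectra, axis=0),
        meta={"gamma": gamma, "theta": theta, "n_reps": n_reps, "dt": dt, "one_sided": True},
    )
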