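"""One-sided PSD estimation and Lorentzian + 1/f model fitting.

Welch averaging (Hann window, 50% overlap by default) keeps the estimator
variance low enough to compare against the smooth closed forms. Fits are
performed in log space on log-rebinned spectra; otherwise the dense
high-frequency bins dominate the residual and 1/f components are lost.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import welch

from .models import CurrentTrace, GTrace, PSDResult, RTSTrace

__all__ = ["estimate_psd", "log_rebin", "fit_lorentzian_flicker", "input_referred"]

TraceLike = Union[CurrentTrace, RTSTrace, GTrace, np.ndarray]


def _values_and_dt(trace: TraceLike, dt: Optional[float]) -> Tuple[np.ndarray, float]:
    if isinstance(trace, CurrentTrace):
        return trace.current, trace.dt
    if isinstance(trace, RTSTrace):
        return trace.states.astype(float), trace.dt
    if isinstance(trace, GTrace):
        return trace.g, trace.stride
    x = np.asarray(trace, dtype=float)
    if dt is None:
        raise ValueError("dt is required when passing a bare array")
    return x, dt


def estimate_psd(
    trace: TraceLike,
    segment_seconds: Optional[float] = None,
    overlap_fraction: float = 0.5,
    dt: Optional[float] = None,
    detrend: str = "constant",
) -> PSDResult:
    """Averaged-periodogram (Welch) one-sided PSD of a time trace.

    ``segment_seconds`` defaults to one quarter of the trace. The trace
    must be at least two segments long. The estimate satisfies Parseval's
    relation: the integral of S over f approximates the sample variance.
    """
    x, dt = _values_and_dt(trace, dt)
    duration = x.size * dt
    if segment_seconds is None:
        segment_seconds = duration / 4.0
    if duration < 2 * segment_seconds:
        raise ValueError(
            f"trace duration {duration:g} s shorter than two segments "
            f"({2 * segment_seconds:g} s)"
        )
    nperseg = int(round(segment_seconds / dt))
    noverlap = int(nperseg * overlap_fraction)
    f, S = welch(
        x,
        fs=1.0 / dt,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=detrend,
    )
    keep = f > 0
    n_segments = 1 + (x.size - nperseg) // max(nperseg - noverlap, 1)
    return PSDResult(
        f=f[keep],
        S=S[keep],
        meta={
            "segment_seconds": nperseg * dt,
            "overlap_fraction": overlap_fraction,
            "n_segments": int(n_segments),
            "dt": dt,
        },
    )


def log_rebin(f: np.ndarray, S: np.ndarray, n_bins: int = 40) -> Tuple[np.ndarray, np.ndarray]:
    """Average a spectrum into logarithmically spaced frequency bins.

    Returns (bin-centre frequencies, bin-mean S); empty bins are dropped.
    """
    f = np.asarray(f, dtype=float)
    S = np.asarray(S, dtype=float)
    edges = np.geomspace(f.min(), f.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums_S = np.bincount(idx, weights=S, minlength=n_bins)
    sums_f = np.bincount(idx, weights=f, minlength=n_bins)
    nz = counts > 0
    return sums_f[nz] / counts[nz], sums_S[nz] / counts[nz]


def _lorflick(f, plateau, f0, c_flick):
    return plateau / (1.0 + (f / f0) ** 2) + c_flick / f


def fit_lorentzian_flicker(psd: PSDResult, n_bins: int = 40) -> dict:
    """Least-squares fit of S(f) = plateau/(1+(f/f0)^2) + c/f in log space.

    The spectrum is log-rebinned first. Parameters are constrained
    positive by fitting their logarithms. Returns a dict with ``plateau``
    (V^2/Hz or A^2/Hz), ``f0`` (Hz), ``flicker_coeff`` (same units as S
    times Hz), ``converged`` and ``residual`` diagnostics; a ``warnings``
    list flags sparse or poorly spanning grids.
    """
    fb, Sb = log_rebin(psd.f, psd.S, n_bins=n_bins)
    pos = Sb > 0
    fb, Sb = fb[pos], Sb[pos]
    warnings_list = []
    if fb.size < 20:
        warnings_list.append(f"only {fb.size} frequency points after rebinning")

    logS = np.log10(Sb)
    plateau0 = float(np.median(Sb[: max(3, fb.size // 8)]))
    # Corner guess: first frequency where S drops below half the plateau.
    below = np.flatnonzero(Sb < 0.5 * plateau0)
    f0_guess = float(fb[below[0]]) if below.size else float(np.sqrt(fb.min() * fb.max()))
    c0 = max(float(Sb[-1] * fb[-1]), plateau0 * fb.min() * 1e-6)

    def residual(p):
        return np.log10(_lorflick(fb, 10.0 ** p[0], 10.0 ** p[1], 10.0 ** p[2])) - logS

    p0 = np.log10([plateau0, f0_guess, c0])
    sol = least_squares(residual, p0, method="lm", max_nfev=5000)
    plateau, f0, c_flick = (10.0 ** v for v in sol.x)
    if not (fb.min() <= f0 / 10 and f0 * 10 <= fb.max()):
        warnings_list.append("fitted corner not bracketed by a decade on each side")
    return {
        "plateau": plateau,
        "f0": f0,
        "flicker_coeff": c_flick,
        "converged": bool(sol.success),
        "residual": float(np.sqrt(np.mean(sol.fun**2))),
        "warnings": warnings_list,
    }


def input_referred(S_I: Union[np.ndarray, PSDResult], g_m: float) -> Union[np.ndarray, PSDResult]:
    """Convert a current-noise density to input-referred voltage noise.

    S_VG = S_I / g_m^2, applied pointwise.
    """
    if not g_m > 0:
        raise ValueError(f"g_m must be > 0, got {g_m}")
    if isinstance(S_I, PSDResult):
        return PSDResult(f=S_I.f, S=S_I.S / g_m**2, meta={**S_I.meta, "input_referred": True})
    return np.asarray(S_I, dtype=float) / g_m**2
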