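"""Recovery of the telegraph signal from noisy current traces.

A two-state Gaussian hidden Markov model is fitted by expectation-
maximization and decoded with the most-probable-path (Viterbi) algorithm;
per-sample posterior decoding is deliberately avoided because isolated
single-sample switches would fragment the dwell-time statistics, which
are the scientific object here. Dwell times, the sliding-window occupancy
g^Theta(t) and the occupancy-vs-gate-voltage curve follow standard
single-channel-kinetics practice (censored boundary dwells discarded).
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import curve_fit

from .models import (
    CurrentTrace,
    FlatCurveError,
    GCurve,
    GTrace,
    HMMResult,
    NoTwoLevelStructureError,
    RTSTrace,
)

__all__ = [
    "fit_two_state_hmm",
    "dwell_times",
    "DwellResult",
    "sliding_g",
    "g_curve",
]

#: Minimum number of transitions for a statistically reliable occupancy
#: estimate; fewer triggers a warning on dwell-time results.
RELIABLE_TRANSITIONS = 200

#: Fitted levels closer than this many emission sigmas are treated as a
#: single level (no two-level structure).
_MIN_SEPARATION_SIGMA = 3.0


def _histogram_split(x: np.ndarray, iters: int = 25) -> Tuple[float, float, float]:
    """Two-cluster split of the amplitude distribution (1-D Lloyd iteration).

    Returns (low mean, high mean, pooled std).
    """
    # Seed from the mean: strictly between the levels of any two-valued
    # trace, unlike the median which can coincide with one of them.
    thr = float(np.mean(x))
    lo_mean = hi_mean = thr
    for _ in range(iters):
        lo = x[x < thr]
        hi = x[x >= thr]
        if lo.size == 0 or hi.size == 0:
            break
        lo_mean, hi_mean = float(lo.mean()), float(hi.mean())
        new_thr = 0.5 * (lo_mean + hi_mean)
        if new_thr == thr:
            break
        thr = new_thr
    lo = x[x < thr]
    hi = x[x >= thr]
    if lo.size and hi.size:
        pooled = float(np.sqrt((lo.var() * lo.size + hi.var() * hi.size) / x.size))
    else:
        pooled = float(x.std())
    return lo_mean, hi_mean, pooled


def fit_two_state_hmm(
    trace: CurrentTrace,
    seed: Optional[int] = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    occupied_level: str = "low",
) -> HMMResult:
    """Fit a two-state Gaussian HMM to a current trace and decode the states.

    The model is initialized from a two-cluster split of the amplitude
    histogram, fitted by EM, and decoded by the Viterbi algorithm. State 1
    is the trap-occupied level: the lower current level by default
    (``occupied_level="low"``), the upper one with ``occupied_level="high"``.

    Raises
    ------
    NoTwoLevelStructureError
        If the trace variance is zero or the fitted levels are separated
        by less than 3 emission sigmas.
    """
    x = np.asarray(trace.current, dtype=float)
    if x.size < 1000:
        raise ValueError(f"trace too short for HMM fitting: {x.size} < 1000 samples")
    if not np.isfinite(x).all():
        raise ValueError("trace contains non-finite values")
    if occupied_level not in ("low", "high"):
        raise ValueError(f"occupied_level must be 'low' or 'high', got {occupied_level!r}")
    if x.std() == 0:
        raise NoTwoLevelStructureError("trace has zero variance; no two-level structure")

    # Standardize: currents are nA-scale and EM covariance floors would
    # otherwise swamp the emission variance.
    x_loc, x_scale = float(x.mean()), float(x.std())
    z = (x - x_loc) / x_scale

    lo_mean, hi_mean, sigma = _histogram_split(z)
    sigma = max(sigma, 1e-6)

    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        init_params="",
        params="stmc",
        n_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
    model.means_ = np.array([[lo_mean], [hi_mean]])
    model.covars_ = np.array([[sigma**2], [sigma**2]])

    X = z.reshape(-1, 1)
    # hmmlearn's monitor logs sub-float-precision likelihood decreases as
    # non-convergence; silence it for the duration of the fit.
    hmm_logger = logging.getLogger("hmmlearn.base")
    prev_level = hmm_logger.level
    hmm_logger.setLevel(logging.ERROR)
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            model.fit(X)
            logprob, decoded = model.decode(X, algorithm="viterbi")
    finally:
        hmm_logger.setLevel(prev_level)
    converged = bool(model.monitor_.converged)

    means = model.means_.ravel() * x_scale + x_loc
    sigmas = np.sqrt(model.covars_.ravel()).ravel() * x_scale
    order = np.argsort(means)  # order[0] -> low level component
    level_low, level_high = float(means[order[0]]), float(means[order[1]])
    sig_low, sig_high = float(sigmas[order[0]]), float(sigmas[order[1]])
    emission_sigma = 0.5 * (sig_low + sig_high)

    if level_high - level_low < _MIN_SEPARATION_SIGMA * max(sig_low, sig_high):
        raise NoTwoLevelStructureError(
            f"fitted levels separated by {level_high - level_low:.3g} A, less than "
            f"{_MIN_SEPARATION_SIGMA:g} emission sigmas ({max(sig_low, sig_high):.3g} A)"
        )

    # Map decoded component labels to physical states: 1 = occupied.
    occupied_component = order[0] if occupied_level == "low" else order[1]
    states = (decoded == occupied_component).astype(np.int8)

    # Transition matrix in (empty=0, occupied=1) state order.
    empty_component = order[1] if occupied_level == "low" else order[0]
    idx = [empty_component, occupied_component]
    transmat = model.transmat_[np.ix_(idx, idx)]

    warnings_list: List[str] = []
    if not converged:
        warnings_list.append(f"EM did not converge within {max_iter} iterations")

    return HMMResult(
        level_low=level_low,
        level_high=level_high,
        emission_sigma=float(emission_sigma),
        transmat=transmat,
        states=states,
        log_likelihood=float(logprob),
        n_transitions=int(np.count_nonzero(np.diff(states))),
        dt=trace.dt,
        converged=converged,
        warnings=warnings_list,
    )


@dataclass
class DwellResult:
    """Interior dwell times and their means (censored edge runs dropped)."""

    capture_dwells: np.ndarray  # durations in state 0 (waiting for capture)
    emission_dwells: np.ndarray  # durations in state 1 (waiting for emission)
    tau_c_hat: float
    tau_e_hat: float
    n_transitions: int
    warnings: list = field(default_factory=list)


def dwell_times(states: "RTSTrace | np.ndarray", dt: Optional[float] = None) -> DwellResult:
    """Dwell-time statistics of a decoded or simulated state sequence.

    Contiguous runs are converted to durations; the first and last runs
    are censored (their true lengths are unknown) and discarded. The
    arithmetic means of the interior 0-runs and 1-runs estimate tau_c and
    tau_e respectively. A warning is attached when the transition count
    is at or below 200, where the occupancy estimate becomes unreliable.
    """
    if isinstance(states, RTSTrace):
        seq = states.states
        dt = states.dt
    else:
        seq = np.asarray(states)
        if dt is None:
            raise ValueError("dt is required when passing a bare state array")

    change = np.flatnonzero(np.diff(seq) != 0)
    n_trans = change.size
    if n_trans < 2:
        raise ValueError(f"need at least 2 transitions, found {n_trans}")

    # Run i (interior) spans (change[i-1], change[i]]; its state is
    # seq[change[i]] (the value before the i-th transition flips).
    run_lengths = np.diff(change) * dt
    run_states = seq[change[1:]]
    capture = run_lengths[run_states == 0]
    emission = run_lengths[run_states == 1]

    warnings_list = []
    if n_trans <= RELIABLE_TRANSITIONS:
        warnings_list.append(
            f"only {n_trans} transitions (<= {RELIABLE_TRANSITIONS}); "
            "occupancy and dwell estimates may be unreliable"
        )
    for name, arr in (("capture", capture), ("emission", emission)):
        if arr.size == 0:
            warnings_list.append(f"no interior {name} dwells; tau estimate undefined")

    return DwellResult(
        capture_dwells=capture,
        emission_dwells=emission,
        tau_c_hat=float(capture.mean()) if capture.size else float("nan"),
        tau_e_hat=float(emission.mean()) if emission.size else float("nan"),
        n_transitions=n_trans,
        warnings=warnings_list,
    )


def sliding_g(states: RTSTrace, theta: float, stride: Optional[float] = None) -> GTrace:
    """Sliding-window occupancy g^Theta(t).

    g^Theta(t) is the fraction of samples in state 1 within [t, t+Theta).
    ``stride`` defaults to dt (a continuous slide), the convention needed
    for unaliased occupancy spectra; coarser strides trade spectral
    fidelity for speed.
    """
    dt = states.dt
    duration = states.duration
    if theta > duration:
        raise ValueError(f"theta {theta} exceeds trace duration {duration}")
    if theta < dt:
        raise ValueError(f"theta {theta} shorter than dt {dt}")
    if stride is None:
        stride = dt

    w = int(round(theta / dt))
    s = max(int(round(stride / dt)), 1)
    if abs(w * dt - theta) > 1e-9 * theta:
        _warnings.warn(f"theta rounded to {w * dt:g} s ({w} samples)", stacklevel=2)
    if abs(s * dt - stride) > 1e-9 * stride:
        _warnings.warn(f"stride rounded to {s * dt:g} s ({s} samples)", stacklevel=2)

    seq = states.states
    c = np.concatenate([[0.0], np.cumsum(seq, dtype=np.float64)])
    starts = np.arange(0, seq.size - w + 1, s)
    g = (c[starts + w] - c[starts]) / w
    # Clip float accumulation dust at the boundaries of [0, 1].
    np.clip(g, 0.0, 1.0, out=g)
    return GTrace(theta=w * dt, stride=s * dt, g=g, t_start=starts * dt)


def _logistic(V, v0, scale):
    return 1.0 / (1.0 + np.exp(-(V - v0) / scale))


def g_curve(
    traces: Sequence[Tuple[float, RTSTrace]],
    theta: Optional[float] = None,
) -> GCurve:
    """Occupancy vs. gate voltage with a least-squares logistic fit.

    Each trace contributes one point: its time-averaged occupancy. The
    logistic form g(V) = 1/(1 + exp(-(V - v0)/scale)) follows from
    g = tau_e/(tau_e + tau_c) with a thermally activated capture time;
    scale = kT/(q alpha). The slope dg/dV_G is available from the fit
    (:meth:`GCurve.g_g`, analytic, the default) or from central finite
    differences of the raw estimates (:meth:`GCurve.g_g_fd`).
    """
    if len(traces) < 4:
        raise ValueError(f"need at least 4 gate voltages, got {len(traces)}")
    vg = np.array([v for v, _ in traces], dtype=float)
    order = np.argsort(vg)
    vg = vg[order]
    if np.unique(vg).size != vg.size:
        raise ValueError("gate voltages must be distinct")
    g_hat = np.array([float(np.mean(traces[i][1].states)) for i in order])

    if np.allclose(g_hat, g_hat[0]):
        raise FlatCurveError("all occupancy estimates identical; no voltage dependence")

    span = vg.max() - vg.min()
    # Midpoint guess: voltage where g crosses 1/2 (linear interpolation).
    v0_guess = float(np.interp(0.5, g_hat, vg)) if g_hat[0] < g_hat[-1] else float(vg[len(vg) // 2])
    slope_guess = max(span / 10.0, 1e-6)
    (v0, scale), _ = curve_fit(
        _logistic,
        vg,
        g_hat,
        p0=[v0_guess, slope_guess],
        bounds=([vg.min() - span, 1e-9], [vg.max() + span, np.inf]),
        maxfev=10000,
    )
    return GCurve(V_G=vg, g_hat=g_hat, v0=float(v0), scale=float(scale))
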