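"""Domain containers for single-trap RTS noise modelling.

All quantities are SI throughout: seconds, amperes, volts, farads, kelvin.
Power spectral densities are one-sided unless a function explicitly says
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Boltzmann constant, J/K (SI 2019 exact value)
K_B: float = 1.380649e-23
#: Elementary charge, C (SI 2019 exact value)
Q_E: float = 1.602176634e-19


class TrapnoiseError(Exception):
    """Base class for package errors."""


class NoTwoLevelStructureError(TrapnoiseError):
    """Raised when a trace has no resolvable two-level RTS structure."""


class FlatCurveError(TrapnoiseError):
    """Raised when an occupancy-vs-voltage curve carries no slope information."""


class TraceFormatError(TrapnoiseError):
    """Raised for malformed or non-uniformly sampled trace files."""


class ConfigError(TrapnoiseError):
    """Raised for malformed configuration files."""


@dataclass(frozen=True)
class TrapModel:
    """Kinetics of a single oxide trap.

    Parameters
    ----------
    tau_c0:
        Mean capture time (s) at the reference gate voltage ``V0``.
    tau_e0:
        Mean emission time (s); voltage-independent, as observed for
        liquid-gated nanowire FETs.
    alpha:
        Dimensionless gate-to-trap coupling, the ratio of gate capacitance
        to tunneling capacitance. ``0 < alpha <= 1``.
    V0:
        Gate voltage (V) at which the capture time equals ``tau_c0``.
        For symmetric kinetics (``tau_c0 == tau_e0``) this is the voltage
        where the occupancy is 1/2.
    q_star:
        Effective trapped charge (C). Defaults to ``0.5 * Q_E``, the
        image-charge-reduced value appropriate for a trap in SiO2.
    """

    tau_c0: float
    tau_e0: float
    alpha: float = 0.5
    V0: float = 0.0
    q_star: float = 0.5 * Q_E

    def __post_init__(self) -> None:
        if not (self.tau_c0 > 0 and np.isfinite(self.tau_c0)):
            raise ValueError(f"tau_c0 must be finite and > 0, got {self.tau_c0}")
        if not (self.tau_e0 > 0 and np.isfinite(self.tau_e0)):
            raise ValueError(f"tau_e0 must be finite and > 0, got {self.tau_e0}")
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (self.q_star > 0):
            raise ValueError(f"q_star must be > 0, got {self.q_star}")


@dataclass(frozen=True)
class DeviceModel:
    """Geometry and electrical parameters of a (nano)transistor sensor.

    Attributes
    ----------
    W, L:
        Channel width and length (m).
    C_G:
        Gate capacitance per unit area (F/m^2).
    tg_delta:
        Dielectric loss tangent of the gate insulator (dimensionless);
        3.8e-3 is typical for SiO2.
    g_m:
        Transconductance (S).
    N_ot:
        Area density of active oxide traps (1/m^2).
    T:
        Temperature (K).
    """

    W: float
    L: float
    C_G: float
    tg_delta: float
    g_m: float
    N_ot: float
    T: float = 300.0

    def __post_init__(self) -> None:
        for name in ("W", "L", "C_G", "tg_delta", "g_m", "N_ot", "T"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def area(self) -> float:
        """Gate area W*L (m^2)."""
        return self.W * self.L

    @property
    def C_total(self) -> float:
        """Total gate capacitance C_G * W * L (F)."""
        return self.C_G * self.area


@dataclass
class RTSTrace:
    """Uniformly sampled two-level state sequence (1 = trap occupied)."""

    dt: float
    states: np.ndarray
    V_G: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError(f"dt must be > 0, got {self.dt}")
        self.states = np.asarray(self.states)
        if self.states.size == 0:
            raise ValueError("states must be nonempty")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must contain only 0 and 1")
        self.states = self.states.astype(np.int8)

    @property
    def duration(self) -> float:
        return self.states.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.states.size) * self.dt

    def __len__(self) -> int:
        return self.states.size


@dataclass
class CurrentTrace:
    """Uniformly sampled drain-current time series.

    ``components`` flags which synthetic ingredients are present
    (``rts``, ``dp``, ``white``). ``states`` carries the generating
    ground-truth state sequence when the trace was synthesized.
    """

    dt: float
    current: np.ndarray
    V_G: float = 0.0
    components: dict = field(default_factory=dict)
    seed: Optional[int] = None
    states: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError(f"dt must be > 0, got {self.dt}")
        self.current = np.asarray(self.current, dtype=float)
        if self.current.size == 0:
            raise ValueError("current must be nonempty")
        if self.states is not None and len(self.states) != self.current.size:
            raise ValueError("states and current must have the same length")

    @property
    def duration(self) -> float:
        return self.current.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.current.size) * self.dt

    def __len__(self) -> int:
        return self.current.size


@dataclass
class GTrace:
    """Sliding-window trap occupancy g^Theta(t).

    ``g[i]`` is the fraction of samples in state 1 within the window
    starting at ``t_start[i]`` of duration ``theta``; consecutive windows
    are ``stride`` apart.
    """

    theta: float
    stride: float
    g: np.ndarray
    t_start: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.size and (self.g.min() < 0 or self.g.max() > 1):
            raise ValueError("g values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.g.size


@dataclass
class GCurve:
    """Occupancy vs. gate voltage with a fitted logistic model.

    The logistic model is g(V) = 1 / (1 + exp(-(V - v0) / scale)); for
    thermally activated capture the scale equals kT / (q * alpha).
    """

    V_G: np.ndarray
    g_hat: np.ndarray
    v0: float
    scale: float

    def g_model(self, V: np.ndarray) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        return 1.0 / (1.0 + np.exp(-(V - self.v0) / self.scale))

    def g_g(self, V: np.ndarray) -> np.ndarray:
        """Analytic slope dg/dV_G (1/V) of the fitted logistic."""
        g = self.g_model(V)
        return g * (1.0 - g) / self.scale

    def g_g_fd(self) -> np.ndarray:
        """Central finite differences of the raw estimates on the V_G grid."""
        return np.gradient(self.g_hat, self.V_G)

    @property
    def g_g_max(self) -> float:
        """Peak slope, attained at g = 1/2 for the logistic model."""
        return 0.25 / self.scale


@dataclass
class PSDResult:
    """One-sided power spectral density on a positive frequency grid."""

    f: np.ndarray
    S: np.ndarray
    meta: dict = field(default_factory=dict)
    fit: Optional[dict] = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.f.size != self.S.size:
            raise ValueError("f and S must have the same length")
        if self.f.size and (self.f.min() <= 0 or np.any(np.diff(self.f) <= 0)):
            raise ValueError("frequencies must be strictly positive and increasing")


@dataclass
class HMMResult:
    """Two-state Gaussian HMM fit of a current trace."""

    level_low: float
    level_high: float
    emission_sigma: float
    transmat: np.ndarray
    states: np.ndarray
    log_likelihood: float
    n_transitions: int
    dt: float
    converged: bool = True
    warnings: list = field(default_factory=list)

    @property
    def delta_i(self) -> float:
        """Fitted RTS amplitude |level_high - level_low| (A)."""
        return self.level_high - self.level_low
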