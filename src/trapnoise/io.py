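"""Trace, spectrum and configuration file I/O.

Traces are plain CSV with a ``time_s,current_A`` (current trace) or
``time_s,state`` (state trace) header; uniform sampling is enforced on
read. Configurations are YAML with ``device``, ``trap``, ``simulation``
and optional ``analysis`` sections, SI units throughout; unknown keys are
rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .models import ConfigError, CurrentTrace, DeviceModel, PSDResult, RTSTrace, TraceFormatError, TrapModel

__all__ = [
    "read_trace",
    "write_trace",
    "read_psd_csv",
    "write_psd_csv",
    "RunConfig",
    "load_config",
]

_CURRENT_HEADER = ["time_s", "current_A"]
_STATE_HEADER = ["time_s", "state"]
_MAX_REL_JITTER = 1e-6


def read_trace(path: Union[str, Path]) -> Union[CurrentTrace, RTSTrace]:
    """Read a time-trace CSV; the header decides the returned type."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols not in (_CURRENT_HEADER, _STATE_HEADER):
        raise TraceFormatError(
            f"{path}: header {cols} is neither {_CURRENT_HEADER} nor {_STATE_HEADER}"
        )
    if len(df) < 2:
        raise TraceFormatError(f"{path}: need at least 2 rows, found {len(df)}")
    values = df[cols[1]].to_numpy()
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise TraceFormatError(f"{path}: non-finite value at data row {bad[0] + 1}")
    t = df["time_s"].to_numpy(dtype=float)
    if not np.isfinite(t).all():
        raise TraceFormatError(f"{path}: non-finite time value")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0:
        raise TraceFormatError(f"{path}: time stamps not strictly increasing")
    if np.max(np.abs(dts - dt)) > _MAX_REL_JITTER * dt:
        raise TraceFormatError(
            f"{path}: non-uniform sampling (relative jitter > {_MAX_REL_JITTER:g})"
        )
    if cols == _CURRENT_HEADER:
        return CurrentTrace(dt=dt, current=values.astype(float))
    if not np.isin(values, (0, 1)).all():
        raise TraceFormatError(f"{path}: state column must contain only 0 and 1")
    return RTSTrace(dt=dt, states=values.astype(np.int8))


def write_trace(path: Union[str, Path], trace: Union[CurrentTrace, RTSTrace]) -> None:
    """Write a trace as CSV, preserving values to 12 significant digits."""
    path = Path(path)
    t = trace.times
    if isinstance(trace, CurrentTrace):
        header = ",".join(_CURRENT_HEADER)
        data = np.column_stack([t, trace.current])
        fmt = ["%.12g", "%.12g"]
    else:
        header = ",".join(_STATE_HEADER)
        data = np.column_stack([t, trace.states])
        fmt = ["%.12g", "%d"]
    np.savetxt(path, data, fmt=fmt, delimiter=",", header=header, comments="")


def write_psd_csv(path: Union[str, Path], psd: PSDResult) -> None:
    np.savetxt(
        path,
        np.column_stack([psd.f, psd.S]),
        fmt="%.12g",
        delimiter=",",
        header="f_Hz,S",
        comments="",
    )


def read_psd_csv(path: Union[str, Path]) -> PSDResult:
    df = pd.read_csv(path)
    if list(df.columns) != ["f_Hz", "S"]:
        raise TraceFormatError(f"{path}: expected header f_Hz,S")
    return PSDResult(f=df["f_Hz"].to_numpy(float), S=df["S"].to_numpy(float))


_DEVICE_KEYS = {"W", "L", "C_G", "tg_delta", "g_m", "N_ot", "T"}
_TRAP_KEYS = {"tau_c0", "tau_e0", "alpha", "V0", "q_star"}
_SIM_KEYS = {"duration", "dt", "seed", "V_G", "white_sigma", "include_dp", "baseline"}
_ANALYSIS_KEYS = {"theta", "stride", "band", "occupied_level"}


@dataclass
class RunConfig:
    """Parsed configuration: device/trap models plus run settings."""

    device: DeviceModel
    trap: TrapModel
    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)


def _check_keys(section: str, mapping: dict, allowed: set) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in section '{section}'")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys("<top>", raw, {"device", "trap", "simulation", "analysis"})
    for required in ("device", "trap"):
        if required not in raw:
            raise ConfigError(f"{path}: missing required section '{required}'")
    _check_keys("device", raw["device"], _DEVICE_KEYS)
    _check_keys("trap", raw["trap"], _TRAP_KEYS)
    sim = raw.get("simulation", {}) or {}
    ana = raw.get("analysis", {}) or {}
    _check_keys("simulation", sim, _SIM_KEYS)
    _check_keys("analysis", ana, _ANALYSIS_KEYS)
    try:
        device = DeviceModel(**{k: float(v) for k, v in raw["device"].items()})
        trap = TrapModel(**{k: float(v) for k, v in raw["trap"].items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return RunConfig(device=device, trap=trap, simulation=dict(sim), analysis=dict(ana))
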