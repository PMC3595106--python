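"""Subcutaneous CGM sensor model (Guardian-style).

The sensor reads interstitial glucose every 5 minutes after a warm-up
(run-in) period. The displayed value is::

    value = gain * drift(t) * g_isf + noise,
    drift(t) = 1 + drift_per_h * (t - last_cal) / 60

i.e. a multiplicative sensitivity drift since the last calibration plus
additive Gaussian reading noise. Calibration against an arterial
reference is a single-point gain rescale (the manufacturer's algorithm
is proprietary; a gain reset reproduces the protocol-relevant behaviour:
error collapses at calibration and grows with drift). Failure is an
absorbing state sampled as a per-step Bernoulli hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "SensorParams",
    "SensorState",
    "CgmReading",
    "SensorFailedError",
    "new_sensor",
    "read",
    "calibrate",
    "maybe_fail",
]


class SensorFailedError(RuntimeError):
    """Raised when an operation requires a working sensor."""


class SensorParams(BaseModel):
    """Error-model parameters of the CGM sensor.

    Defaults are calibrated so that simulated paired CGM/arterial points
    land ~95-98% in Clarke zones A+B, the accuracy class reported for
    this device in ICU use; they are not device datasheet values.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    #: additive reading noise SD, mmol/L
    noise_sd_mmol_l: float = Field(default=0.4, ge=0)
    #: multiplicative sensitivity drift, fraction/h (signed)
    drift_per_h: float = 0.005
    #: residual error retained at calibration, mmol/L
    cal_error_sd: float = Field(default=0.15, ge=0)
    #: probability of sensor failure within 24 h
    fail_prob_per_24h: float = Field(default=1.0 / 12.0, ge=0, lt=1)
    #: warm-up before the first valid reading, min
    runin_min: float = Field(default=105.0, ge=0)
    #: log-SD of the uncalibrated initial gain
    init_gain_sd: float = Field(default=0.2, ge=0)


@dataclass(frozen=True)
class SensorState:
    """Internal calibration/drift state of one inserted sensor."""

    gain: float
    last_cal_min: float
    failed: bool
    t_start_min: float


@dataclass(frozen=True)
class CgmReading:
    """One timestamped displayed glucose value."""

    t_min: float
    value_mmol_l: float | None
    valid: bool


def new_sensor(
    params: SensorParams, t_start_min: float, rng: np.random.Generator
) -> SensorState:
    """Insert a fresh sensor: raw gain is unknown until first calibration."""
    gain = float(np.exp(rng.normal(0.0, params.init_gain_sd)))
    return SensorState(gain=gain, last_cal_min=t_start_min, failed=False, t_start_min=t_start_min)


def read(
    state: SensorState,
    params: SensorParams,
    g_isf: float,
    t_min: float,
    rng: np.random.Generator,
) -> CgmReading:
    """Displayed glucose at ``t_min`` (invalid during run-in or after failure)."""
    if state.failed or (t_min - state.t_start_min) < params.runin_min:
        return CgmReading(t_min=t_min, value_mmol_l=None, valid=False)
    drift = 1.0 + params.drift_per_h * (t_min - state.last_cal_min) / 60.0
    noise = float(rng.normal(0.0, params.noise_sd_mmol_l)) if params.noise_sd_mmol_l > 0 else 0.0
    value = state.gain * drift * g_isf + noise
    return CgmReading(t_min=t_min, value_mmol_l=max(value, 0.1), valid=True)


def calibrate(
    state: SensorState,
    params: SensorParams,
    reference_g: float,
    g_isf: float,
    t_min: float,
    rng: np.random.Generator,
) -> SensorState:
    """Single-point calibration against an arterial reference.

    The gain is reset so the next noiseless reading equals the reference
    to within ``cal_error_sd``; the drift clock restarts.
    """
    if state.failed:
        raise SensorFailedError("cannot calibrate a failed sensor")
    if reference_g <= 0:
        raise ValueError("reference glucose must be positive")
    eps = float(rng.normal(0.0, params.cal_error_sd)) if params.cal_error_sd > 0 else 0.0
    gain = max((reference_g + eps) / max(g_isf, 1e-6), 1e-3)
    return replace(state, gain=gain, last_cal_min=t_min)


def maybe_fail(
    state: SensorState,
    params: SensorParams,
    dt_min: float,
    rng: np.random.Generator,
) -> SensorState:
    """Sample failure over ``dt_min`` minutes; failure is absorbing.

    The per-step hazard is chosen so that the failure probability over a
    full 24 h equals ``fail_prob_per_24h``.
    """
    if state.failed:
        return state
    if params.fail_prob_per_24h <= 0:
        return state
    p_step = 1.0 - (1.0 - params.fail_prob_per_24h) ** (dt_min / 1440.0)
    if rng.random() < p_step:
        return replace(state, failed=True)
    return state
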