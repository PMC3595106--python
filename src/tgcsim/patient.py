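"""Virtual post-cardiac-surgery ICU patient.

Glucose-insulin dynamics are a Bergman-style minimal model extended with

* an interstitial glucose compartment (first-order lag ``tau_sen_min``)
  that a subcutaneous sensor reads, and
* a decaying insulin-resistance multiplier modelling the "diabetes of
  injury": surgical stress depresses insulin sensitivity by a factor
  ``ir_mult0`` that relaxes back to 1 with time constant ``ir_decay_h``.

State (plasma glucose ``g``, remote insulin action ``x``, interstitial
glucose ``g_isf``) evolves as::

    dg/dt     = -(p1 + x) * g + (egp + ra) / (v_g * weight)
    dx/dt     = p2 * (s_i_eff * u - x),    s_i_eff = s_i / ir_mult(t)
    dg_isf/dt = (g - g_isf) * 60 / tau_sen_min

with rates per hour, ``u`` the IV insulin rate (IU/h) and ``ra`` the
exogenous glucose appearance (mmol/h) from the dextrose/carbohydrate
inputs. Integration is fixed-step RK4 (default 1 min).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._rng import rng_for
from .units import glucose_g_to_mmol

logger = logging.getLogger(__name__)

__all__ = [
    "PatientParams",
    "PatientState",
    "ExogenousInput",
    "IntegrationError",
    "ideal_body_weight",
    "dextrose_rate",
    "derivatives",
    "step",
    "simulate",
    "steady_state_glucose",
    "make_cohort",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters a non-finite state."""


class PatientParams(BaseModel):
    """Kinetic and anthropometric parameters of one virtual patient.

    ``egp_mmol_h`` defaults to ``p1 * g0 * v_g * weight`` so that the
    baseline glucose ``g0`` is the steady state of the unforced system
    (no insulin, no infusion) -- the patient arrives at the ICU at that
    level and stress plus the dextrose infusion push glycemia upward
    until the controller intervenes.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    weight_kg: float = Field(default=80.0, gt=0)
    height_cm: float = Field(default=170.0, gt=100)
    #: glucose effectiveness, 1/h (insulin-independent clearance)
    p1: float = Field(default=0.25, gt=0)
    #: insulin-action rate constant, 1/h
    p2: float = Field(default=0.5, gt=0)
    #: insulin sensitivity, (1/h) per (IU/h)
    s_i: float = Field(default=0.2, gt=0)
    #: endogenous glucose production, mmol/h (None -> steady-state default)
    egp_mmol_h: float | None = Field(default=None, gt=0)
    #: glucose distribution volume, L/kg
    v_g_l_per_kg: float = Field(default=0.16, gt=0)
    #: interstitial lag time constant, min (0 = no lag, g_isf tracks g)
    tau_sen_min: float = Field(default=10.0, ge=0)
    #: decay time constant of post-surgical insulin resistance, h
    ir_decay_h: float = Field(default=12.0, gt=0)
    #: initial insulin-resistance multiplier (>= 1, divides s_i)
    ir_mult0: float = Field(default=2.0, ge=1)
    #: baseline plasma glucose at ICU admission, mmol/L
    g0_mmol_l: float = Field(default=9.0, gt=0)
    diabetic: bool = False

    @model_validator(mode="after")
    def _fill_egp(self) -> "PatientParams":
        if self.egp_mmol_h is None:
            egp = self.p1 * self.g0_mmol_l * self.v_g_l_per_kg * self.weight_kg
            object.__setattr__(self, "egp_mmol_h", egp)
        return self

    @property
    def glucose_volume_l(self) -> float:
        return self.v_g_l_per_kg * self.weight_kg

    def ir_mult(self, t_min: float) -> float:
        """Insulin-resistance multiplier at time ``t_min`` since admission."""
        return 1.0 + (self.ir_mult0 - 1.0) * math.exp(-(t_min / 60.0) / self.ir_decay_h)


@dataclass(frozen=True)
class PatientState:
    """Instantaneous physiological state."""

    t_min: float
    g_mmol_l: float
    x_per_h: float
    g_isf_mmol_l: float


@dataclass(frozen=True)
class ExogenousInput:
    """IV insulin, IV dextrose and enteral carbohydrate rates."""

    insulin_iu_h: float = 0.0
    dextrose_g_h: float = 0.0
    carb_g_h: float = 0.0


def initial_state(params: PatientParams) -> PatientState:
    """Patient state at ICU admission (t = 0)."""
    return PatientState(
        t_min=0.0,
        g_mmol_l=params.g0_mmol_l,
        x_per_h=0.0,
        g_isf_mmol_l=params.g0_mmol_l,
    )


def ideal_body_weight(height_cm: float) -> float:
    """Ideal body weight (kg): height in centimeters minus 100."""
    if height_cm <= 100:
        raise ValueError(f"height_cm must exceed 100, got {height_cm}")
    return height_cm - 100.0


def dextrose_rate(params: PatientParams, dose_g_per_kg_day: float = 2.5) -> float:
    """Continuous 10% dextrose infusion rate in g/h.

    The dose is prescribed per kg of ideal body weight per 24 h
    (default 2.5 g/kg IBW/day).
    """
    if dose_g_per_kg_day <= 0:
        raise ValueError("dose_g_per_kg_day must be positive")
    return dose_g_per_kg_day * ideal_body_weight(params.height_cm) / 24.0


def derivatives(
    state: PatientState, params: PatientParams, inp: ExogenousInput
) -> tuple[float, float, float]:
    """Time derivatives (per hour) of (g, x, g_isf)."""
    ra = glucose_g_to_mmol(inp.dextrose_g_h + inp.carb_g_h)  # mmol/h
    s_i_eff = params.s_i / params.ir_mult(state.t_min)
    dg = (
        -(params.p1 + state.x_per_h) * state.g_mmol_l
        + (params.egp_mmol_h + ra) / params.glucose_volume_l
    )
    dx = params.p2 * (s_i_eff * inp.insulin_iu_h - state.x_per_h)
    if params.tau_sen_min > 0:
        disf = (state.g_mmol_l - state.g_isf_mmol_l) * 60.0 / params.tau_sen_min
    else:
        disf = 0.0
    return dg, dx, disf


def steady_state_glucose(
    params: PatientParams, x_per_h: float = 0.0, ra_mmol_h: float = 0.0
) -> float:
    """Analytic plasma-glucose steady state for fixed insulin action."""
    return (params.egp_mmol_h + ra_mmol_h) / (
        (params.p1 + x_per_h) * params.glucose_volume_l
    )


def step(
    state: PatientState,
    params: PatientParams,
    inp: ExogenousInput,
    dt_min: float = 1.0,
) -> PatientState:
    """Advance the patient state by ``dt_min`` minutes (RK4, inputs held).

    Negative components are clamped at 0 with a logged warning; a
    non-finite state raises :class:`IntegrationError`.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    if not all(
        math.isfinite(v) for v in (state.g_mmol_l, state.x_per_h, state.g_isf_mmol_l)
    ):
        raise IntegrationError(f"non-finite state at t={state.t_min} min: {state}")

    h = dt_min / 60.0  # hours

    def f(t_min: float, y: tuple[float, float, float]) -> tuple[float, float, float]:
        s = PatientState(t_min, y[0], y[1], y[2])
        return derivatives(s, params, inp)

    y0 = (state.g_mmol_l, state.x_per_h, state.g_isf_mmol_l)
    t0 = state.t_min
    k1 = f(t0, y0)
    k2 = f(t0 + dt_min / 2, tuple(y0[i] + h / 2 * k1[i] for i in range(3)))
    k3 = f(t0 + dt_min / 2, tuple(y0[i] + h / 2 * k2[i] for i in range(3)))
    k4 = f(t0 + dt_min, tuple(y0[i] + h * k3[i] for i in range(3)))
    y1 = [
        y0[i] + h / 6 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i]) for i in range(3)
    ]

    if not all(math.isfinite(v) for v in y1):
        raise IntegrationError(f"integration diverged at t={t0} min")
    for i, v in enumerate(y1):
        if v < 0:
            logger.warning(
                "state component %d clamped to 0 at t=%.1f min (was %.3g)", i, t0, v
            )
            y1[i] = 0.0

    g, x, g_isf = y1
    if params.tau_sen_min <= 0:
        g_isf = g
    return PatientState(t0 + dt_min, g, x, g_isf)


def simulate(
    params: PatientParams,
    input_fn: Callable[[float], ExogenousInput],
    t_end_min: float,
    t0_min: float = 0.0,
    dt_min: float = 1.0,
    state: PatientState | None = None,
) -> pd.DataFrame:
    """Open-loop simulation; returns the minute-resolution trace.

    ``input_fn(t)`` gives the exogenous rates applied over ``[t, t+dt)``.
    """
    if state is None:
        state = replace(initial_state(params), t_min=t0_min)
    rows = []
    t = t0_min
    while True:
        inp = input_fn(t)
        rows.append(
            {
                "t_min": state.t_min,
                "g_mmol_l": state.g_mmol_l,
                "g_isf_mmol_l": state.g_isf_mmol_l,
                "insulin_iu_h": inp.insulin_iu_h,
                "dextrose_g_h": inp.dextrose_g_h,
                "carb_g_h": inp.carb_g_h,
            }
        )
        if t >= t_end_min:
            break
        state = step(state, params, inp, min(dt_min, t_end_min - t))
        t = state.t_min
    return pd.DataFrame(rows)


def make_cohort(
    n: int, seed: int, arm_profile: dict | None = None
) -> list[PatientParams]:
    """Sample ``n`` virtual post-cardiac-surgery patients.

    Defaults emulate the source population: elderly elective cardiac-surgery
    patients with stress hyperglycemia (baseline glucose lognormal, median
    ~9 mmol/L), BMI around 28.5 kg/m^2, ~25% with known type 2 diabetes
    (diabetics get lower insulin sensitivity and higher baseline glucose).
    ``arm_profile`` can override the sampling medians/SDs by name.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    prof = {
        "g0_median": 9.0,
        "g0_log_sd": 0.17,
        "s_i_median": 0.2,
        "s_i_log_sd": 0.3,
        "ir_mult0_excess_median": 1.0,  # ir_mult0 = 1 + lognormal
        "ir_mult0_log_sd": 0.4,
        "ir_decay_median_h": 12.0,
        "ir_decay_log_sd": 0.25,
        "height_mean_cm": 170.0,
        "height_sd_cm": 8.0,
        "bmi_mean": 28.5,
        "bmi_sd": 3.0,
        "tau_sen_mean_min": 10.0,
        "tau_sen_sd_min": 2.0,
        "diabetic_prevalence": 0.25,
        "diabetic_s_i_factor": 0.6,
        "diabetic_g0_factor": 1.15,
    }
    if arm_profile:
        unknown = set(arm_profile) - set(prof)
        if unknown:
            raise ValueError(f"unknown arm_profile keys: {sorted(unknown)}")
        prof.update(arm_profile)

    rng = rng_for(seed, "cohort")
    cohort = []
    for _ in range(n):
        height = float(np.clip(rng.normal(prof["height_mean_cm"], prof["height_sd_cm"]), 150, 200))
        bmi = float(np.clip(rng.normal(prof["bmi_mean"], prof["bmi_sd"]), 19, 42))
        weight = bmi * (height / 100.0) ** 2
        diabetic = bool(rng.random() < prof["diabetic_prevalence"])
        g0 = prof["g0_median"] * math.exp(rng.normal(0.0, prof["g0_log_sd"]))
        s_i = prof["s_i_median"] * math.exp(rng.normal(0.0, prof["s_i_log_sd"]))
        if diabetic:
            g0 *= prof["diabetic_g0_factor"]
            s_i *= prof["diabetic_s_i_factor"]
        ir_mult0 = 1.0 + prof["ir_mult0_excess_median"] * math.exp(
            rng.normal(0.0, prof["ir_mult0_log_sd"])
        )
        ir_decay = prof["ir_decay_median_h"] * math.exp(
            rng.normal(0.0, prof["ir_decay_log_sd"])
        )
        tau_sen = float(
            np.clip(rng.normal(prof["tau_sen_mean_min"], prof["tau_sen_sd_min"]), 5, 18)
        )
        cohort.append(
            PatientParams(
                weight_kg=weight,
                height_cm=height,
                s_i=s_i,
                g0_mmol_l=g0,
                ir_mult0=ir_mult0,
                ir_decay_h=ir_decay,
                tau_sen_min=tau_sen,
                diabetic=diabetic,
            )
        )
    return cohort
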