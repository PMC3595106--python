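"""Two-arm 24-hour tight-glycemic-control trial on a virtual patient.

Both arms start insulin after a 105-min run-in (the CGM warm-up period)
and run to 24 h from ICU admission, with a continuous 10% dextrose
infusion (2.5 g/kg IBW per day) for the first 18 h.

* **EMPC_ONLY** (control): arterial glucose is sampled at the
  controller-computed variable intervals and fed to the controller.
* **EMPC_CGM**: the CGM display value is entered every 15 min. Every
  60 min an arterial reference is drawn and the simultaneous CGM value
  classified on the Clarke grid; on a zone C/D/E result the reference
  replaces the CGM value as controller input and the sensor is
  recalibrated. The sensor is otherwise recalibrated every 12 h from
  its last calibration (any recalibration resets that clock). On sensor
  failure, control falls back to arterial sampling at the
  controller-computed intervals.

Hourly checks are anchored at insulin start. Arterial sampling is
modelled as instantaneous, error-free plasma glucose (blood-gas
analyzer treated as gold standard).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._rng import child_seeds, rng_for
from .cega import EgaSummary, acceptable, classify, summarize
from .empc import (
    ControlOutput,
    ControllerConfig,
    ControllerState,
    new_controller,
    recommend,
    update,
)
from .metrics import EndpointReport, endpoint_report
from .patient import (
    ExogenousInput,
    PatientParams,
    dextrose_rate,
    initial_state,
    make_cohort,
    step,
)
from .sensor import SensorParams, calibrate, maybe_fail, new_sensor, read

logger = logging.getLogger(__name__)

__all__ = [
    "Arm",
    "TrialConfig",
    "Event",
    "TrialLog",
    "ArmResult",
    "CohortResult",
    "schedule_events",
    "run_trial",
    "run_cohort",
]


class Arm(str, Enum):
    EMPC_ONLY = "empc"
    EMPC_CGM = "empc-cgm"


class TrialConfig(BaseModel):
    """Configuration of one simulated trial."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    arm: Arm = Arm.EMPC_CGM
    #: total monitored duration from ICU admission, min
    duration_min: int = Field(default=1440, gt=0)
    #: sensor run-in / insulin start, min
    runin_min: int = Field(default=105, ge=0)
    #: CGM entry interval into the controller, min
    cgm_entry_min: int = Field(default=15, gt=0)
    #: arterial reference / C-EGA check interval, min
    reference_check_min: int = Field(default=60, gt=0)
    #: scheduled calibration interval, min
    routine_cal_min: int = Field(default=720, gt=0)
    #: dextrose infusion duration from admission, min
    dextrose_duration_min: int = Field(default=1080, ge=0)
    #: dextrose dose, g per kg ideal body weight per 24 h
    dextrose_dose_g_per_kg_day: float = Field(default=2.5, gt=0)
    seed: int = Field(default=0, ge=0)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    sensor: SensorParams = Field(default_factory=SensorParams)
    #: fault injection hooks for robustness experiments
    fault_gain_min: int | None = None
    fault_gain_factor: float = Field(default=1.0, gt=0)
    fault_fail_min: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "TrialConfig":
        if self.runin_min > self.duration_min:
            raise ValueError("runin_min must not exceed duration_min")
        if self.reference_check_min % self.cgm_entry_min != 0:
            raise ValueError("cgm_entry_min must divide reference_check_min")
        return self


@dataclass(frozen=True)
class Event:
    """One logged protocol event."""

    t_min: int
    kind: str
    payload: dict


@dataclass
class TrialLog:
    """Time-ordered event log plus the 1-min-resolution trace."""

    events: list[Event]
    trace: pd.DataFrame

    def events_df(self) -> pd.DataFrame:
        import json

        return pd.DataFrame(
            {
                "t_min": [e.t_min for e in self.events],
                "kind": [e.kind for e in self.events],
                "payload": [json.dumps(e.payload, sort_keys=True) for e in self.events],
            }
        )


@dataclass
class ArmResult:
    """Outcome of one simulated trial."""

    arm: Arm
    log: TrialLog
    endpoints: EndpointReport
    ega: EgaSummary | None
    controller: ControllerState


@dataclass
class CohortResult:
    """Paired-cohort outcome: per-arm results and endpoint summary."""

    cohort: list[PatientParams]
    results: dict[str, list[ArmResult]]
    summary: pd.DataFrame


def schedule_events(config: TrialConfig) -> dict[str, list[int]]:
    """Deterministic timetable of entries, checks and planned calibrations.

    Returns minute marks for CGM entries, hourly reference checks and the
    statically planned calibrations (initial + every 12 h assuming no
    intervening recalibration). Degenerate configs (run-in consuming the
    whole trial) yield empty timetables.
    """
    if config.runin_min >= config.duration_min:
        return {"cgm_entries": [], "ega_checks": [], "routine_calibrations": []}
    entries = list(
        range(config.runin_min, config.duration_min + 1, config.cgm_entry_min)
    )
    checks = list(
        range(
            config.runin_min + config.reference_check_min,
            config.duration_min + 1,
            config.reference_check_min,
        )
    )
    cals = list(
        range(config.runin_min, config.duration_min + 1, config.routine_cal_min)
    )
    return {"cgm_entries": entries, "ega_checks": checks, "routine_calibrations": cals}


def run_trial(patient: PatientParams, config: TrialConfig) -> ArmResult:
    """Simulate one patient through one arm of the protocol."""
    ctrl_cfg = config.controller
    sensor_params = config.sensor
    sensor_rng = rng_for(config.seed, "sensor")

    state = initial_state(patient)
    dext_g_h = dextrose_rate(patient, config.dextrose_dose_g_per_kg_day)

    def exo(t_min: float, insulin: float) -> ExogenousInput:
        on = t_min < config.dextrose_duration_min
        return ExogenousInput(insulin, dext_g_h if on else 0.0, 0.0)

    def future_inputs(t_min: float) -> ExogenousInput:
        return exo(t_min, 0.0)

    cgm_arm = config.arm == Arm.EMPC_CGM
    sensor = new_sensor(sensor_params, 0.0, sensor_rng) if cgm_arm else None
    ctrl = new_controller(ctrl_cfg, patient.weight_kg)
    sched = schedule_events(config)
    entry_times = set(sched["cgm_entries"])
    check_times = set(sched["ega_checks"])

    insulin = 0.0
    arterial_mode = not cgm_arm  # EMPC_ONLY behaves like permanent fallback
    next_due = config.runin_min
    last_feed_t: float | None = None
    last_reading = None
    events: list[Event] = []
    trace_rows: list[dict] = []
    ega_pairs: list[tuple[float, float]] = []

    def log(t: int, kind: str, **payload) -> None:
        events.append(Event(t_min=t, kind=kind, payload=payload))
        logger.info("t=%4d %s %s", t, kind, payload)

    def input_segments(t0: float, t1: float):
        bnd = config.dextrose_duration_min
        if t1 <= bnd or t0 >= bnd:
            return [(t0, t1, exo(t0, insulin))]
        return [(t0, bnd, exo(t0, insulin)), (bnd, t1, exo(bnd, insulin))]

    def feed(t: int, value: float) -> ControlOutput:
        nonlocal ctrl, insulin, last_feed_t
        segments = input_segments(last_feed_t, t) if last_feed_t is not None else []
        ctrl = update(ctrl, ctrl_cfg, t, value, segments)
        log(t, "empc_input", glucose_mmol_l=value)
        out = recommend(ctrl, ctrl_cfg, future_inputs)
        ctrl = dataclasses.replace(ctrl, last_u=out.insulin_iu_h)
        insulin = out.insulin_iu_h
        last_feed_t = t
        log(
            t,
            "empc_output",
            insulin_iu_h=out.insulin_iu_h,
            next_sample_min=out.next_sample_min,
        )
        log(t, "insulin_set", insulin_iu_h=insulin)
        return out

    for t in range(0, config.duration_min + 1):
        cgm_value = np.nan

        if cgm_arm and not arterial_mode:
            if config.fault_fail_min is not None and t == config.fault_fail_min:
                sensor = dataclasses.replace(sensor, failed=True)
            if config.fault_gain_min is not None and t == config.fault_gain_min:
                sensor = dataclasses.replace(
                    sensor, gain=sensor.gain * config.fault_gain_factor
                )
            # calibrations happen before the same-minute read
            if not sensor.failed and t >= config.runin_min:
                initial = t == config.runin_min
                due = t == sensor.last_cal_min + config.routine_cal_min
                if initial or due:
                    sensor = calibrate(
                        sensor,
                        sensor_params,
                        state.g_mmol_l,
                        state.g_isf_mmol_l,
                        t,
                        sensor_rng,
                    )
                    log(
                        t,
                        "routine_calibration",
                        reference_mmol_l=state.g_mmol_l,
                        initial=initial,
                    )
            if t % 5 == 0:
                if t > 0:
                    sensor = maybe_fail(sensor, sensor_params, 5.0, sensor_rng)
                reading = read(sensor, sensor_params, state.g_isf_mmol_l, t, sensor_rng)
                if reading.valid:
                    last_reading = reading
                    cgm_value = reading.value_mmol_l
                if sensor.failed:
                    log(t, "sensor_failure")
                    log(t, "fallback_start")
                    arterial_mode = True
                    next_due = max(t, config.runin_min)

        if not arterial_mode and cgm_arm and t in entry_times and last_reading is not None:
            value = last_reading.value_mmol_l
            if t in check_times:
                ref = state.g_mmol_l
                log(t, "arterial_sample", glucose_mmol_l=ref)
                zone = classify(ref, value)
                ega_pairs.append((ref, value))
                log(t, "ega_check", reference_mmol_l=ref, cgm_mmol_l=value, zone=zone.value)
                if not acceptable(zone):
                    sensor = calibrate(
                        sensor, sensor_params, ref, state.g_isf_mmol_l, t, sensor_rng
                    )
                    log(t, "recalibration", reference_mmol_l=ref, zone=zone.value)
                    value = ref
            feed(t, value)
        elif arterial_mode and t == next_due and t >= config.runin_min:
            ref = state.g_mmol_l
            log(t, "arterial_sample", glucose_mmol_l=ref)
            out = feed(t, ref)
            next_due = t + out.next_sample_min

        current_input = exo(t, insulin)
        trace_rows.append(
            {
                "t_min": t,
                "g_mmol_l": state.g_mmol_l,
                "g_isf_mmol_l": state.g_isf_mmol_l,
                "insulin_iu_h": current_input.insulin_iu_h,
                "dextrose_g_h": current_input.dextrose_g_h,
                "carb_g_h": current_input.carb_g_h,
                "cgm_mmol_l": cgm_value,
            }
        )
        if t < config.duration_min:
            state = step(state, patient, current_input, 1.0)

    trace = pd.DataFrame(trace_rows)
    endpoints = endpoint_report(
        trace,
        lo=ctrl_cfg.target_lo,
        hi=ctrl_cfg.target_hi,
        insulin_start_min=config.runin_min,
        total_h=config.duration_min / 60.0,
    )
    ega = summarize(ega_pairs) if (cgm_arm and ega_pairs) else None
    return ArmResult(
        arm=config.arm,
        log=TrialLog(events=events, trace=trace),
        endpoints=endpoints,
        ega=ega,
        controller=ctrl,
    )


_SUMMARY_METRICS = (
    "mean_bg_mmol_l",
    "time_to_target_h",
    "pct_in",
    "pct_above",
    "pct_below",
    "hypo_count",
)


def run_cohort(
    n_per_arm: int,
    seed: int,
    config: TrialConfig | None = None,
    arms: tuple[Arm, ...] = (Arm.EMPC_ONLY, Arm.EMPC_CGM),
) -> CohortResult:
    """Paired in-silico trial: the same cohort simulated under each arm.

    Sharing patients and per-patient seeds across arms gives a
    low-variance paired comparison. Returns per-arm results and a
    mean +/- SEM endpoint summary.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    base = config if config is not None else TrialConfig()
    cohort = make_cohort(n_per_arm, seed)
    seeds = child_seeds(seed, "trials", n_per_arm)

    results: dict[str, list[ArmResult]] = {}
    for arm in arms:
        arm_results = []
        for patient, trial_seed in zip(cohort, seeds):
            cfg = base.model_copy(update={"arm": arm, "seed": trial_seed})
            arm_results.append(run_trial(patient, cfg))
        results[arm.value] = arm_results

    rows = []
    for arm_name, arm_results in results.items():
        for metric in _SUMMARY_METRICS:
            vals = np.array(
                [
                    getattr(r.endpoints, metric)
                    for r in arm_results
                    if getattr(r.endpoints, metric) is not None
                ],
                dtype=float,
            )
            n = len(vals)
            mean = float(vals.mean()) if n else float("nan")
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            rows.append(
                {"arm": arm_name, "metric": metric, "mean": mean, "sem": sem, "n": n}
            )
    summary = pd.DataFrame(rows)
    return CohortResult(cohort=cohort, results=results, summary=summary)
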