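"""Model-predictive insulin controller with recursive sensitivity estimation.

The controller keeps an internal glucose model of the same structural
family as the virtual patient but with *fixed population kinetics*
(p1, p2, v_g) and a single estimated parameter, the effective insulin
sensitivity ``s_i_hat``. At each glucose input it

1. propagates its one-step prediction from the previous measurement
   through the recorded insulin/carbohydrate inputs,
2. updates ``s_i_hat`` by regularized recursive least squares (RLS) with
   a forgetting factor on the prediction residual (projected to >= 0), and
3. recommends the IV insulin rate by exhaustive grid search over
   piecewise-constant candidates (0 to ``u_max`` in ``u_grid_step``
   steps, held over the prediction horizon), minimizing

   ``sum_k (g_hat_k - setpoint)^2 + lambda_du * (u - last_u)^2``.

Hypoglycemia protection is layered. Candidate selection prefers rates
whose predicted trajectory stays at or above ``target_lo`` over the
whole simulated look-ahead (the longer of the cost horizon and the
largest menu interval -- the rate may be held that long before the next
measurement); treating the bottom of the target range as a hard
constraint stops the quadratic cost from choosing descents that skim
the suspend threshold with no margin for model error. When no candidate
can stay above ``target_lo``, the one with the greatest predicted
minimum (still above ``safety_lo``) is chosen; when even that fails, or
the current glucose is already below ``safety_lo``, insulin is 0. The
recommended interval to the next measurement is the largest entry of
the allowed menu for which the predicted trajectory stays inside the
surveillance band [``pred_band_lo``, ``pred_band_hi``].

Because the patient's effective insulin sensitivity is time varying
(stress insulin resistance decays over hours), the forgetting factor is
applied per elapsed ``control_dt_min`` rather than per update, so a
4-hour sampling gap discounts old information 16 times more than a
15-minute one; the estimator variance is capped so that periods with no
insulin (no identifiability) cannot inflate it without bound.

The controller model is deliberately mismatched from the virtual
patient: it does not know the patient's endogenous glucose production,
insulin-resistance decay, or true sensitivity, so closed-loop tests
exercise robustness rather than self-fulfilling prediction. The
controller itself is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .patient import ExogenousInput
from .units import glucose_g_to_mmol

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "ControlOutput",
    "InputSegment",
    "NotInitializedError",
    "OrderingError",
    "new_controller",
    "rls_update",
    "update",
    "recommend",
]


class NotInitializedError(RuntimeError):
    """recommend() called before any glucose observation."""


class OrderingError(ValueError):
    """Glucose inputs must arrive in strictly increasing time order."""


class ControllerConfig(BaseModel):
    """Tuning and internal-model parameters of the controller."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    #: target range, mmol/L
    target_lo: float = Field(default=4.4, gt=0)
    target_hi: float = Field(default=6.1, gt=0)
    #: control setpoint (defaults to the range midpoint), mmol/L
    setpoint: float = Field(default=5.25, gt=0)
    #: prediction horizon for the cost, min
    horizon_min: float = Field(default=120.0, gt=0)
    #: spacing of the cost evaluation points, min
    control_dt_min: float = Field(default=15.0, gt=0)
    #: insulin ceiling, IU/h
    u_max_iu_h: float = Field(default=50.0, gt=0)
    #: candidate grid spacing, IU/h
    u_grid_step: float = Field(default=0.5, gt=0)
    #: rate-change penalty weight, (mmol/L)^2 per (IU/h)^2
    lambda_du: float = Field(default=0.01, ge=0)
    #: RLS forgetting factor (1 = no forgetting)
    forgetting: float = Field(default=0.98, gt=0, le=1)
    #: menu of allowed sampling intervals, min
    allowed_intervals_min: tuple[int, ...] = (15, 30, 60, 120, 180, 240)
    #: suspend threshold, mmol/L
    safety_lo: float = Field(default=3.5, gt=0)
    #: surveillance band for the variable sampling interval, mmol/L
    pred_band_lo: float = Field(default=4.0, gt=0)
    pred_band_hi: float = Field(default=10.0, gt=0)
    #: prior for the estimated insulin sensitivity, (1/h) per (IU/h)
    s_i_prior: float = Field(default=0.1, gt=0)
    #: prior variance of the sensitivity estimate
    p_cov_prior: float = Field(default=0.04, gt=0)
    #: cap on the estimator variance, as a multiple of the prior
    p_cov_cap_factor: float = Field(default=25.0, ge=1)
    #: fixed population kinetics of the internal model
    model_p1: float = Field(default=0.25, gt=0)
    model_p2: float = Field(default=0.5, gt=0)
    model_v_g_l_per_kg: float = Field(default=0.16, gt=0)
    #: reference glycemia used to scale the model's endogenous production
    model_egp_ref_mmol_l: float = Field(default=9.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "ControllerConfig":
        if not (self.target_lo < self.setpoint < self.target_hi):
            raise ValueError("require target_lo < setpoint < target_hi")
        if not self.allowed_intervals_min:
            raise ValueError("allowed_intervals_min must be non-empty")
        if self.pred_band_lo >= self.pred_band_hi:
            raise ValueError("require pred_band_lo < pred_band_hi")
        return self


#: one piecewise-constant exogenous-input segment: (t0_min, t1_min, input)
InputSegment = tuple[float, float, ExogenousInput]


@dataclass(frozen=True)
class ControllerState:
    """Estimates plus observation history of one controller instance."""

    weight_kg: float
    s_i_hat: float
    p_cov: float
    x_hat: float
    #: (t_min, glucose_mmol_l, insulin_iu_h, carb_g_h) per observation
    history: tuple[tuple[float, float, float, float], ...]
    last_u: float


@dataclass(frozen=True)
class ControlOutput:
    """Commanded insulin rate, next sampling interval, and prediction."""

    insulin_iu_h: float
    next_sample_min: int
    #: (t_min, predicted glucose) over the simulated look-ahead
    predicted_trajectory: tuple[tuple[float, float], ...]


def new_controller(config: ControllerConfig, weight_kg: float) -> ControllerState:
    """Fresh controller state for a patient of known body weight."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return ControllerState(
        weight_kg=weight_kg,
        s_i_hat=config.s_i_prior,
        p_cov=config.p_cov_prior,
        x_hat=0.0,
        history=(),
        last_u=0.0,
    )


def rls_update(
    theta: float, p: float, phi: float, y: float, forgetting: float
) -> tuple[float, float]:
    """One scalar recursive-least-squares step.

    ``y`` is the residual (observation minus prediction at the current
    ``theta``), ``phi`` the regressor (sensitivity of the prediction to
    ``theta``). With ``forgetting == 1`` the recursion is algebraically
    identical to regularized (ridge) least squares on the whole residual
    history with prior precision ``1/p0``.
    """
    denom = forgetting + phi * phi * p
    k = p * phi / denom
    theta_new = theta + k * y
    p_new = (p - k * phi * p) / forgetting
    return theta_new, p_new


def _model_egp(config: ControllerConfig, weight_kg: float) -> float:
    return (
        config.model_p1
        * config.model_egp_ref_mmol_l
        * config.model_v_g_l_per_kg
        * weight_kg
    )


def _propagate(
    g0: float,
    x0: float,
    s_i: float,
    segments: Sequence[InputSegment],
    config: ControllerConfig,
    weight_kg: float,
    dt_min: float = 5.0,
) -> tuple[float, float]:
    """Integrate the internal model over the input segments (scalar RK4)."""
    vol = config.model_v_g_l_per_kg * weight_kg
    egp = _model_egp(config, weight_kg)
    p1, p2 = config.model_p1, config.model_p2
    g, x = g0, x0
    for t0, t1, inp in segments:
        ra = glucose_g_to_mmol(inp.dextrose_g_h + inp.carb_g_h)
        u = inp.insulin_iu_h
        t = t0
        while t < t1 - 1e-9:
            h = min(dt_min, t1 - t) / 60.0

            def f(gv: float, xv: float) -> tuple[float, float]:
                return (-(p1 + xv) * gv + (egp + ra) / vol, p2 * (s_i * u - xv))

            k1 = f(g, x)
            k2 = f(g + h / 2 * k1[0], x + h / 2 * k1[1])
            k3 = f(g + h / 2 * k2[0], x + h / 2 * k2[1])
            k4 = f(g + h * k3[0], x + h * k3[1])
            g = g + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            x = x + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            t += h * 60.0
        g = max(g, 0.0)
        x = max(x, 0.0)
    return g, x


def update(
    state: ControllerState,
    config: ControllerConfig,
    t_min: float,
    glucose_mmol_l: float,
    inputs_since_last: Sequence[InputSegment] = (),
) -> ControllerState:
    """Assimilate one glucose observation.

    ``inputs_since_last`` describes the exogenous inputs actually applied
    since the previous observation as piecewise-constant segments. On the
    first call the observation is stored and the prior left untouched
    (there is no residual yet).
    """
    if glucose_mmol_l <= 0:
        raise ValueError("glucose must be positive")
    last_inp = inputs_since_last[-1][2] if inputs_since_last else ExogenousInput()
    record = (float(t_min), float(glucose_mmol_l), last_inp.insulin_iu_h, last_inp.carb_g_h)

    if not state.history:
        return replace(state, history=(record,))

    t_prev, g_prev = state.history[-1][0], state.history[-1][1]
    if t_min <= t_prev:
        raise OrderingError(f"time must increase: got {t_min} after {t_prev}")
    segments = [
        (max(t0, t_prev), min(t1, t_min), inp)
        for (t0, t1, inp) in inputs_since_last
        if min(t1, t_min) > max(t0, t_prev)
    ]
    if not segments:
        segments = [(t_prev, t_min, ExogenousInput())]

    s = state.s_i_hat
    g_pred, _ = _propagate(g_prev, state.x_hat, s, segments, config, state.weight_kg)
    ds = max(1e-4, 1e-3 * s)
    g_pred_ds, _ = _propagate(
        g_prev, state.x_hat, s + ds, segments, config, state.weight_kg
    )
    phi = (g_pred_ds - g_pred) / ds
    y = glucose_mmol_l - g_pred

    # discount per elapsed time, not per update: the sensitivity drifts
    # in real time, so a long sampling gap must forget more
    lam = config.forgetting ** ((t_min - t_prev) / config.control_dt_min)
    s_new, p_new = rls_update(s, state.p_cov, phi, y, lam)
    s_new = max(s_new, 0.0)
    p_new = min(p_new, config.p_cov_cap_factor * config.p_cov_prior)
    # keep x_hat consistent with the updated sensitivity
    _, x_new = _propagate(g_prev, state.x_hat, s_new, segments, config, state.weight_kg)
    return replace(
        state,
        s_i_hat=s_new,
        p_cov=p_new,
        x_hat=x_new,
        history=state.history + (record,),
    )


def _simulate_candidates(
    g0: float,
    x0: float,
    s_i: float,
    u_grid: np.ndarray,
    t0: float,
    sim_end_min: float,
    config: ControllerConfig,
    weight_kg: float,
    future_inputs: Callable[[float], ExogenousInput],
    dt_min: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict glucose for every candidate rate simultaneously.

    Returns (times relative to t0 including 0, glucose matrix of shape
    (n_times, n_candidates)).
    """
    vol = config.model_v_g_l_per_kg * weight_kg
    egp = _model_egp(config, weight_kg)
    p1, p2 = config.model_p1, config.model_p2
    n = len(u_grid)
    g = np.full(n, g0, dtype=float)
    x = np.full(n, x0, dtype=float)
    times = [0.0]
    traj = [g.copy()]
    t = 0.0
    while t < sim_end_min - 1e-9:
        step_min = min(dt_min, sim_end_min - t)
        h = step_min / 60.0
        inp = future_inputs(t0 + t)
        ra = glucose_g_to_mmol(inp.dextrose_g_h + inp.carb_g_h)

        def f(gv: np.ndarray, xv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            return (-(p1 + xv) * gv + (egp + ra) / vol, p2 * (s_i * u_grid - xv))

        k1 = f(g, x)
        k2 = f(g + h / 2 * k1[0], x + h / 2 * k1[1])
        k3 = f(g + h / 2 * k2[0], x + h / 2 * k2[1])
        k4 = f(g + h * k3[0], x + h * k3[1])
        g = g + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        x = x + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        np.maximum(g, 0.0, out=g)
        np.maximum(x, 0.0, out=x)
        t += step_min
        times.append(t)
        traj.append(g.copy())
    return np.array(times), np.vstack(traj)


def recommend(
    state: ControllerState,
    config: ControllerConfig,
    future_inputs: Callable[[float], ExogenousInput] | None = None,
) -> ControlOutput:
    """Recommend the insulin rate and the interval to the next measurement.

    ``future_inputs(t_min)`` gives the planned dextrose/carbohydrate
    schedule over the look-ahead (the insulin field is ignored; each
    candidate rate is substituted). Defaults to no exogenous input.
    """
    if not state.history:
        raise NotInitializedError("no glucose observation yet")
    t0, g0 = state.history[-1][0], state.history[-1][1]
    if future_inputs is None:
        future_inputs = lambda t: ExogenousInput()  # noqa: E731

    menu = sorted(config.allowed_intervals_min)
    sim_end = max(config.horizon_min, max(menu))
    n_grid = int(round(config.u_max_iu_h / config.u_grid_step)) + 1
    u_grid = np.linspace(0.0, config.u_max_iu_h, n_grid)

    times, traj = _simulate_candidates(
        g0, state.x_hat, state.s_i_hat, u_grid, t0, sim_end, config, state.weight_kg,
        future_inputs,
    )

    if g0 < config.safety_lo:
        u_star_idx = 0
        u_star = 0.0
        path = traj[:, 0]
        return ControlOutput(
            insulin_iu_h=0.0,
            next_sample_min=int(min(menu)),
            predicted_trajectory=tuple(
                (t0 + float(t), float(gv)) for t, gv in zip(times, path)
            ),
        )

    cost_times = np.arange(
        config.control_dt_min, config.horizon_min + 1e-9, config.control_dt_min
    )
    cost_idx = np.searchsorted(times, cost_times - 1e-9)
    dev = traj[cost_idx] - config.setpoint
    costs = (dev * dev).sum(axis=0) + config.lambda_du * (u_grid - state.last_u) ** 2

    min_pred = traj.min(axis=0)
    in_range = min_pred >= config.target_lo
    above_suspend = min_pred >= config.safety_lo
    if in_range.any():
        # hard constraint at the bottom of the target range
        u_star_idx = int(np.argmin(np.where(in_range, costs, np.inf)))
    elif above_suspend.any():
        # a dip below range is unavoidable: minimize its predicted depth
        u_star_idx = int(np.argmax(np.where(above_suspend, min_pred, -np.inf)))
    else:
        u_star_idx = 0
    u_star = float(u_grid[u_star_idx]) if (in_range.any() or above_suspend.any()) else 0.0

    path = traj[:, u_star_idx]
    next_sample = int(min(menu))
    for delta in sorted(menu, reverse=True):
        mask = (times > 0) & (times <= delta + 1e-9)
        seg = path[mask]
        if len(seg) and (seg >= config.pred_band_lo).all() and (
            seg <= config.pred_band_hi
        ).all():
            next_sample = int(delta)
            break

    return ControlOutput(
        insulin_iu_h=u_star,
        next_sample_min=next_sample,
        predicted_trajectory=tuple(
            (t0 + float(t), float(gv)) for t, gv in zip(times, path)
        ),
    )
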