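"""MPC controller: estimator algebra, recommendation optimality, safety."""

import dataclasses

import numpy as np
import pytest

from tgcsim.empc import (
    ControllerConfig,
    NotInitializedError,
    OrderingError,
    _propagate,
    new_controller,
    recommend,
    rls_update,
    update,
)
from tgcsim.patient import ExogenousInput
from tgcsim.units import glucose_g_to_mmol

WEIGHT = 80.0


def _dextrose(rate_g_h):
    return lambda t: ExogenousInput(0.0, rate_g_h, 0.0)


def test_first_observation_stores_without_estimator_update():
    cfg = ControllerConfig()
    state = new_controller(cfg, WEIGHT)
    state = update(state, cfg, 105.0, 9.0)
    assert state.s_i_hat == cfg.s_i_prior
    assert state.p_cov == cfg.p_cov_prior
    assert state.history[-1][:2] == (105.0, 9.0)


def test_nonmonotone_time_rejected():
    cfg = ControllerConfig()
    state = new_controller(cfg, WEIGHT)
    state = update(state, cfg, 105.0, 9.0)
    with pytest.raises(OrderingError):
        update(state, cfg, 105.0, 8.0)


def test_recommend_requires_observation():
    cfg = ControllerConfig()
    with pytest.raises(NotInitializedError):
        recommend(new_controller(cfg, WEIGHT), cfg)


def test_rls_with_unit_forgetting_equals_regularized_least_squares():
    """lambda = 1 reproduces ridge regression with prior precision 1/P0."""
    theta0, p0 = 0.1, 0.04
    phi = [1.0, -2.0, 0.5]
    z = [0.3, -0.1, 0.2]
    theta, p = theta0, p0
    for f, zz in zip(phi, z):
        theta, p = rls_update(theta, p, f, zz - f * theta, forgetting=1.0)
    closed = (theta0 / p0 + sum(f * zz for f, zz in zip(phi, z))) / (
        1 / p0 + sum(f * f for f in phi)
    )
    assert theta == pytest.approx(closed, rel=1e-12)
    assert p == pytest.approx(1.0 / (1 / p0 + sum(f * f for f in phi)), rel=1e-12)


def test_sensitivity_recovered_from_own_model_data():
    """Noiseless data from the internal model: s_i_hat converges within 5%."""
    cfg = ControllerConfig()
    s_true = 0.15
    dext = 7.0
    state = new_controller(cfg, WEIGHT)
    g, x = 9.0, 0.0
    t_prev = 105.0
    state = update(state, cfg, t_prev, g)
    rng = np.random.default_rng(3)
    u_prev = 0.0
    for k in range(1, 90):
        t = 105.0 + 15.0 * k
        u_prev = float(rng.choice([1.0, 3.0, 5.0, 8.0]))
        seg = [(t_prev, t, ExogenousInput(u_prev, dext, 0.0))]
        g, x = _propagate(g, x, s_true, seg, cfg, WEIGHT, dt_min=1.0)
        state = update(state, cfg, t, g, seg)
        t_prev = t
    assert abs(state.s_i_hat - s_true) / s_true < 0.05


def test_equilibrium_recommendation_is_flat():
    """At setpoint with a matching steady rate on the grid, the controller
    recommends that rate and predicts a flat trajectory."""
    cfg = ControllerConfig()
    u_star = 2.0
    x_star = cfg.s_i_prior * u_star
    # dextrose chosen so (p1 + x*) * setpoint balances production exactly
    egp = cfg.model_p1 * cfg.model_egp_ref_mmol_l * cfg.model_v_g_l_per_kg * WEIGHT
    ra = (cfg.model_p1 + x_star) * cfg.setpoint * cfg.model_v_g_l_per_kg * WEIGHT - egp
    dext_g_h = ra / (1000.0 / 180.16)
    state = new_controller(cfg, WEIGHT)
    state = update(state, cfg, 0.0, cfg.setpoint)
    state = dataclasses.replace(state, x_hat=x_star, last_u=u_star)
    out = recommend(state, cfg, _dextrose(dext_g_h))
    assert out.insulin_iu_h == u_star
    pred = np.array([g for _, g in out.predicted_trajectory])
    assert np.abs(pred - cfg.setpoint).max() < 1e-6
    assert out.next_sample_min == max(cfg.allowed_intervals_min)


def test_hypoglycemia_suspends_insulin():
    """Measured glucose below the suspend threshold: zero insulin, 15 min."""
    cfg = ControllerConfig()
    state = new_controller(cfg, WEIGHT)
    state = update(state, cfg, 0.0, 3.2)
    out = recommend(state, cfg)
    assert out.insulin_iu_h == 0.0
    assert out.next_sample_min == 15


def _oracle_recommend(state, cfg, future_inputs):
    """Independent brute force: per-candidate scalar simulation + the same
    two-tier selection rule, written without the vectorized path."""
    t0, g0 = state.history[-1][0], state.history[-1][1]
    menu = sorted(cfg.allowed_intervals_min)
    sim_end = max(cfg.horizon_min, max(menu))
    n = int(round(cfg.u_max_iu_h / cfg.u_grid_step)) + 1
    vol = cfg.model_v_g_l_per_kg * WEIGHT
    egp = cfg.model_p1 * cfg.model_egp_ref_mmol_l * vol
    results = []
    for i in range(n):
        u = i * cfg.u_grid_step
        g, x = g0, state.x_hat
        t = 0.0
        path = [(0.0, g)]
        while t < sim_end - 1e-9:
            h = min(5.0, sim_end - t) / 60.0
            inp = future_inputs(t0 + t)
            ra = glucose_g_to_mmol(inp.dextrose_g_h + inp.carb_g_h)

            def f(gv, xv):
                return (
                    -(cfg.model_p1 + xv) * gv + (egp + ra) / vol,
                    cfg.model_p2 * (state.s_i_hat * u - xv),
                )

            k1 = f(g, x)
            k2 = f(g + h / 2 * k1[0], x + h / 2 * k1[1])
            k3 = f(g + h / 2 * k2[0], x + h / 2 * k2[1])
            k4 = f(g + h * k3[0], x + h * k3[1])
            g = max(g + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]), 0.0)
            x = max(x + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]), 0.0)
            t += h * 60.0
            path.append((t, g))
        cost = sum(
            (gv - cfg.setpoint) ** 2
            for tv, gv in path
            if tv > 0
            and tv <= cfg.horizon_min + 1e-9
            and abs(tv / cfg.control_dt_min - round(tv / cfg.control_dt_min)) < 1e-9
        ) + cfg.lambda_du * (u - state.last_u) ** 2
        results.append((u, min(gv for _, gv in path), cost))
    tier1 = [r for r in results if r[1] >= cfg.target_lo]
    if tier1:
        return min(tier1, key=lambda r: r[2])[0]
    tier2 = [r for r in results if r[1] >= cfg.safety_lo]
    if tier2:
        return max(tier2, key=lambda r: r[1])[0]
    return 0.0


@pytest.mark.parametrize("glucose,last_u", [(9.5, 0.0), (5.2, 3.0), (7.8, 6.0), (4.6, 1.0)])
def test_grid_search_matches_exhaustive_oracle(glucose, last_u):
    cfg = ControllerConfig()
    state = new_controller(cfg, WEIGHT)
    state = update(state, cfg, 0.0, glucose)
    state = dataclasses.replace(state, last_u=last_u, x_hat=0.3)
    fut = _dextrose(7.29)
    out = recommend(state, cfg, fut)
    assert out.insulin_iu_h == pytest.approx(_oracle_recommend(state, cfg, fut))


def test_recommended_rate_monotone_in_glucose():
    """Sweeping measured glucose 4 -> 12 mmol/L never decreases the rate."""
    cfg = ControllerConfig()
    fut = _dextrose(7.29)
    rates = []
    for g in np.arange(4.0, 12.01, 0.25):
        state = new_controller(cfg, WEIGHT)
        state = update(state, cfg, 0.0, float(g))
        rates.append(recommend(state, cfg, fut).insulin_iu_h)
    assert all(b >= a for a, b in zip(rates, rates[1:]))
    assert rates[-1] > rates[0]


def test_output_clipping_and_menu_membership(rng):
    cfg = ControllerConfig()
    for _ in range(25):
        state = new_controller(cfg, WEIGHT)
        state = update(state, cfg, 0.0, float(rng.uniform(3.0, 15.0)))
        state = dataclasses.replace(state, x_hat=float(rng.uniform(0, 1.5)))
        out = recommend(state, cfg, _dextrose(float(rng.uniform(0, 10))))
        assert 0.0 <= out.insulin_iu_h <= cfg.u_max_iu_h
        assert out.next_sample_min in cfg.allowed_intervals_min


def test_controller_is_deterministic():
    cfg = ControllerConfig()
    state = new_controller(cfg, WEIGHT)
    state = update(state, cfg, 0.0, 8.2)
    out1 = recommend(state, cfg, _dextrose(7.29))
    out2 = recommend(state, cfg, _dextrose(7.29))
    assert out1 == out2
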