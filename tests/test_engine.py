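"""ODE engine: disposition, binding, effect-site link, mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmbsim import (
    DoseEvent,
    InputError,
    Simulation,
    SimulationError,
    default_params,
    effect_site_concentration,
    ode_rhs,
    simulate,
)
from nmbsim.engine import N_STATES


def two_compartment_bolus(t_min, dose_ug, v1, v2, cl, q):
    """Independent closed-form oracle: central concentration (ug/mL) after
    a bolus, from the eigenvalues of the 2x2 disposition matrix."""
    k10, k12, k21 = cl / v1, q / v1, q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    lam1, lam2 = (s + disc) / 2.0, (s - disc) / 2.0
    a = dose_ug / v1 * (lam1 - k21) / (lam1 - lam2)
    b = dose_ug / v1 * (k21 - lam2) / (lam1 - lam2)
    return (a * np.exp(-lam1 * t_min) + b * np.exp(-lam2 * t_min)) / 1000.0


# ----------------------------------------------------------------- rhs ----
def test_empty_system_is_at_equilibrium(params):
    dy = ode_rhs(0.0, np.zeros(N_STATES), params, 0.0, 0.0)
    assert np.all(dy == 0.0)


def test_zero_kon_decouples_the_species(params):
    """With binding disabled the rocuronium derivatives ignore sugammadex."""
    p = params.replace(kon=0.0)
    y = np.array([5e3, 2e3, 0.0, 0.0, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0])
    y_with_sgx = y.copy()
    y_with_sgx[2] = 8e4
    y_with_sgx[3] = 1e4
    d0 = ode_rhs(0.0, y, p, 100.0, 0.0)
    d1 = ode_rhs(0.0, y_with_sgx, p, 100.0, 0.0)
    rb_states = [0, 1, 6, 7]
    assert np.allclose(d0[rb_states], d1[rb_states], rtol=0, atol=0)


def test_rhs_mass_balance_identity(params):
    """Summed per-species derivatives equal the infusion rates exactly."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        y = rng.uniform(0.0, 1e4, N_STATES)
        rb_rate, sgx_rate = rng.uniform(0.0, 500.0, 2)
        dy = ode_rhs(0.0, y, params, rb_rate, sgx_rate) * 60.0  # per minute
        d_rb_total = dy[0] + dy[1] + params.mw_rb * (dy[4] + dy[5] + dy[9]) + dy[7]
        d_sgx_total = dy[2] + dy[3] + params.mw_sgx * (dy[4] + dy[5] + dy[9]) + dy[8]
        assert d_rb_total == pytest.approx(rb_rate, rel=1e-9, abs=1e-9)
        assert d_sgx_total == pytest.approx(sgx_rate, rel=1e-9, abs=1e-9)


def test_rhs_guards_against_negative_state(params):
    y = np.zeros(N_STATES)
    y[0] = -5.0
    with pytest.raises(SimulationError):
        ode_rhs(0.0, y, params, 0.0, 0.0)


# ----------------------------------------------------- closed-form PK ----
def test_bolus_matches_biexponential_closed_form(ref_params):
    """Single bolus, binding disabled: the engine agrees with the analytic
    bi-exponential two-compartment solution over two hours."""
    p = ref_params.replace(kon=0.0)
    dose = 30000.0
    traj = simulate(
        [DoseEvent(0.0, "rb", "bolus", dose)], p, duration_s=7200.0, grid_dt_s=12.0
    )
    exact = two_compartment_bolus(
        traj.time_s / 60.0, dose, p.v1_rb, p.v2_rb, p.cl_rb, p.q_rb
    )
    rel = np.abs(traj.c_rb - exact) / exact.max()
    assert rel.max() < 1e-4


def test_bolus_closed_form_on_stiff_solver_path(ref_params):
    """Same oracle, but with inert sugammadex on board so every step goes
    through the stiff ODE solver instead of the linear fast path."""
    p = ref_params.replace(kon=0.0)
    dose = 30000.0
    events = [
        DoseEvent(0.0, "sgx", "bolus", 1000.0),  # decoupled (kon = 0)
        DoseEvent(0.0, "rb", "bolus", dose),
    ]
    traj = simulate(events, p, duration_s=1800.0, grid_dt_s=12.0)
    exact = two_compartment_bolus(
        traj.time_s / 60.0, dose, p.v1_rb, p.v2_rb, p.cl_rb, p.q_rb
    )
    rel = np.abs(traj.c_rb - exact) / exact.max()
    assert rel.max() < 1e-4


def test_linear_pk_homogeneity(ref_params):
    """Doubling every dose doubles every concentration (no binding)."""
    events = [
        DoseEvent(0.0, "rb", "bolus", 20000.0),
        DoseEvent(600.0, "rb", "infusion_rate", 250.0),
        DoseEvent(3000.0, "rb", "infusion_rate", 0.0),
    ]
    doubled = [DoseEvent(e.time_s, e.drug, e.kind, 2.0 * e.magnitude) for e in events]
    t1 = simulate(events, ref_params, 3600.0)
    t2 = simulate(doubled, ref_params, 3600.0)
    assert np.allclose(t2.c_rb, 2.0 * t1.c_rb, rtol=1e-9, atol=1e-12)
    assert np.allclose(t2.ce_rb, 2.0 * t1.ce_rb, rtol=1e-9, atol=1e-12)


def test_antagonist_bolus_binds_free_drug(ref_params):
    """A sugammadex bolus into a rocuronium steady state pulls free drug
    down and complex up on the first grid step; the signs agree with an
    independent small-step Euler integration."""
    sim = Simulation(ref_params)
    sim.bolus("rb", 2e4)
    sim.set_rate("rb", 280.0)
    sim.run_until(3600.0)
    c_before = sim.y[0] / ref_params.v1_rb
    y0 = sim.y.copy()
    sim.bolus("sgx", 1.2e5)
    y_dosed = sim.y.copy()
    sim.step()
    c_after = sim.y[0] / ref_params.v1_rb
    comp_after = sim.y[4]
    assert c_after < c_before
    assert comp_after > 0.0

    # Euler oracle at 1 ms resolution over the same 12 s
    y = y_dosed.copy()
    for _ in range(12000):
        y = y + 1e-3 * ode_rhs(0.0, y, ref_params, 280.0, 0.0)
    assert np.sign(y[0] - y0[0]) == -1.0
    assert y[4] > 0.0
    # Euler endpoint agrees loosely with the stiff solver
    assert y[4] == pytest.approx(sim.y[4], rel=0.05)


def test_full_binding_run_conserves_mass(ref_params):
    """Infusion + antagonist bolus: mass balance holds at every tick."""
    sim = Simulation(ref_params)
    sim.bolus("rb", 3e4)
    sim.set_rate("rb", 250.0)
    sim.run_until(1200.0, bulk=False)
    sim.set_rate("rb", 0.0)
    sim.bolus("sgx", 1.2e5)
    sim.run_until(3600.0)
    err_rb, err_sgx = sim.trajectory().mass_balance_error()
    assert err_rb.max() < 1e-6
    assert err_sgx.max() < 1e-6


def test_concentrations_never_negative(ref_params):
    rng = np.random.default_rng(11)
    events = []
    t = 0.0
    for _ in range(10):
        t += float(rng.integers(1, 50)) * 12.0
        drug = "rb" if rng.random() < 0.6 else "sgx"
        if rng.random() < 0.5:
            events.append(DoseEvent(t, drug, "bolus", float(rng.uniform(0, 5e4))))
        else:
            events.append(DoseEvent(t, "rb", "infusion_rate", float(rng.uniform(0, 500))))
    traj = simulate(events, ref_params, duration_s=t + 1800.0)
    for channel in (traj.c_rb, traj.c_sgx, traj.c_comp, traj.ce_rb):
        assert channel.min() >= 0.0


# ------------------------------------------------------- effect site ----
def test_effect_site_step_response():
    """Constant plasma input: Ce follows C0 (1 - exp(-ke0 t)) exactly."""
    ke0 = 0.72
    t = np.arange(0.0, 1200.0, 12.0)
    c = np.full_like(t, 2.0)
    ce = effect_site_concentration(t, c, ke0)
    exact = 2.0 * (1.0 - np.exp(-ke0 * t / 60.0))
    assert np.abs(ce - exact).max() < 1e-6


def test_effect_site_fast_equilibration_limit():
    t = np.arange(0.0, 600.0, 1.0)
    c = 1.0 + 0.5 * np.sin(t / 80.0)
    ce = effect_site_concentration(t, c, ke0_per_min=1e3)
    assert np.abs(ce[5:] - c[5:]).max() < 5e-3


def test_effect_site_zero_input_stays_zero():
    t = np.arange(0.0, 600.0, 12.0)
    ce = effect_site_concentration(t, np.zeros_like(t), 0.72)
    assert np.all(ce == 0.0)


def test_effect_site_lags_and_converges_monotonically():
    t = np.arange(0.0, 3600.0, 12.0)
    c = np.full_like(t, 1.5)
    ce = effect_site_concentration(t, c, 0.3)
    assert np.all(np.diff(ce) > 0.0)
    assert np.all(ce <= 1.5)
    assert ce[-1] == pytest.approx(1.5, rel=1e-3)


# ---------------------------------------------------------- contracts ----
def test_simulate_rejects_unsorted_events(ref_params):
    events = [
        DoseEvent(100.0, "rb", "bolus", 1.0),
        DoseEvent(0.0, "rb", "bolus", 1.0),
    ]
    with pytest.raises(InputError):
        simulate(events, ref_params, 600.0)


def test_dose_event_validation():
    with pytest.raises(InputError):
        DoseEvent(-1.0, "rb", "bolus", 1.0)
    with pytest.raises(InputError):
        DoseEvent(0.0, "rb", "bolus", -1.0)
    with pytest.raises(InputError):
        DoseEvent(0.0, "propofol", "bolus", 1.0)


def test_simulate_grid_and_duration(ref_params):
    traj = simulate([DoseEvent(0.0, "rb", "bolus", 1e4)], ref_params, 600.0, 60.0)
    assert np.allclose(traj.time_s, np.arange(0.0, 601.0, 60.0))
    with pytest.raises(InputError):
        simulate([], ref_params, -5.0)
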