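"""Mechanistic PK-PD engine for free rocuronium, free sugammadex and
their 1:1 complex.

Model structure
---------------
Each of the three species follows linear two-compartment disposition
(central volume V1, peripheral volume V2, elimination clearance CL,
inter-compartmental clearance Q).  Free rocuronium and free sugammadex
associate in the central compartment at the mass-action rate
``kon * [Rb] * [SGX]`` (molar), and the complex dissociates at ``koff``.
The complex distributes and is eliminated with sugammadex-like (renal)
parameters.  Binding fluxes are converted between mass and molar units
through the two molecular weights; the complex itself is tracked in
micromoles so that the 1:1 stoichiometry is exact by construction.
The rocuronium effect site is linked to the free central concentration
by the first-order constant ``ke0``.

State vector (10 entries)::

    0  free rocuronium, central amount        ug
    1  free rocuronium, peripheral amount     ug
    2  free sugammadex, central amount        ug
    3  free sugammadex, peripheral amount     ug
    4  complex, central amount                umol
    5  complex, peripheral amount             umol
    6  rocuronium effect-site concentration   ug/mL
    7  cumulative eliminated free rocuronium  ug
    8  cumulative eliminated free sugammadex  ug
    9  cumulative eliminated complex          umol

Internal time is in seconds; all rate constants in the parameter set
are per minute and are converted here.

Integration strategy
--------------------
While no sugammadex is on board the system is linear, and each step is
propagated exactly with a cached matrix exponential (including the
constant-rate infusion response and the cumulative-elimination state, so
mass balance is preserved to machine precision).  Once sugammadex
appears, the binding terms make the system stiff and steps fall back to
a stiff-capable ``solve_ivp`` integrator with tight tolerances.  The
integration is restarted at every dose event; bolus doses are
instantaneous increments of the central amount, never interpolated
across.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import InputError, SimulationError
from .params import PKPDParameters
from .pd_model import tof_from_ce

RB = "rb"
SGX = "sgx"
BOLUS = "bolus"
INFUSION_RATE = "infusion_rate"

N_STATES = 10
_LIN_IDX = np.array([0, 1, 6, 7])  # rocuronium-only linear subsystem


@dataclass(frozen=True, order=True)
class DoseEvent:
    """A timestamped bolus (ug) or infusion-rate (ug/min) event."""

    time_s: float
    drug: str
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.time_s < 0.0:
            raise InputError(f"dose event time must be >= 0, got {self.time_s}")
        if self.drug not in (RB, SGX):
            raise InputError(f"drug must be {RB!r} or {SGX!r}, got {self.drug!r}")
        if self.kind not in (BOLUS, INFUSION_RATE):
            raise InputError(f"kind must be {BOLUS!r} or {INFUSION_RATE!r}")
        if self.magnitude < 0.0:
            raise InputError(f"dose magnitude must be >= 0, got {self.magnitude}")


class TOFObservation(NamedTuple):
    time_s: float
    t1_pct: float
    tofc: int
    tofr: float
    ce_rb: float


def ode_rhs(
    t: float,
    y: np.ndarray,
    params: PKPDParameters,
    rb_rate_ug_min: float = 0.0,
    sgx_rate_ug_min: float = 0.0,
) -> np.ndarray:
    """Right-hand side of the coupled disposition/binding system (per second).

    Raises :class:`SimulationError` if the state is unphysically negative
    (beyond transient solver noise).
    """
    p = params
    if y.min() < -1.0:
        raise SimulationError(f"state became negative during integration: {y}")

    c1r = y[0] / p.v1_rb  # ug/L
    c2r = y[1] / p.v2_rb
    c1s = y[2] / p.v1_sgx
    c2s = y[3] / p.v2_sgx
    c1c = y[4] / p.v1_cpx  # umol/L == uM
    c2c = y[5] / p.v2_cpx

    # molar central concentrations, uM (ug/L divided by g/mol)
    rb_um = c1r / p.mw_rb
    sgx_um = c1s / p.mw_sgx
    # net association flux, umol/min, in the complex central volume
    bind = (p.kon * rb_um * sgx_um - p.koff * c1c) * p.v1_cpx

    dy = np.empty(N_STATES)
    dy[0] = rb_rate_ug_min - p.cl_rb * c1r - p.q_rb * (c1r - c2r) - p.mw_rb * bind
    dy[1] = p.q_rb * (c1r - c2r)
    dy[2] = sgx_rate_ug_min - p.cl_sgx * c1s - p.q_sgx * (c1s - c2s) - p.mw_sgx * bind
    dy[3] = p.q_sgx * (c1s - c2s)
    dy[4] = bind - p.cl_cpx * c1c - p.q_cpx * (c1c - c2c)
    dy[5] = p.q_cpx * (c1c - c2c)
    dy[6] = p.ke0 * (c1r / 1000.0 - y[6])  # effect site, ug/mL
    dy[7] = p.cl_rb * c1r
    dy[8] = p.cl_sgx * c1s
    dy[9] = p.cl_cpx * c1c
    return dy / 60.0  # per-minute -> per-second


def effect_site_concentration(
    time_s: np.ndarray, c_free: np.ndarray, ke0_per_min: float, ce0: float = 0.0
) -> np.ndarray:
    """Integrate dCe/dt = ke0 (C - Ce) along a sampled plasma profile.

    The plasma profile is taken piecewise-linear between samples and the
    link equation solved exactly on each interval (an exponential
    integrator), so a constant input reproduces the analytic
    ``C0 (1 - exp(-ke0 t))`` to round-off.
    """
    if ke0_per_min <= 0.0:
        raise InputError(f"ke0 must be positive, got {ke0_per_min}")
    time_s = np.asarray(time_s, dtype=float)
    c_free = np.asarray(c_free, dtype=float)
    if time_s.shape != c_free.shape:
        raise InputError("time and concentration grids must have equal length")
    k = ke0_per_min / 60.0
    ce = np.empty_like(c_free)
    ce[0] = ce0
    for i in range(len(ce) - 1):
        h = time_s[i + 1] - time_s[i]
        if h <= 0.0:
            raise InputError("time grid must be strictly increasing")
        em = -math.expm1(-k * h)  # 1 - exp(-k h)
        slope_term = 1.0 - em / (k * h)
        c0, c1 = c_free[i], c_free[i + 1]
        ce[i + 1] = ce[i] * (1.0 - em) + c0 * em + (c1 - c0) * slope_term
    return ce


@dataclass
class Trajectory:
    """Time-gridded concentrations and TOF channels for one simulation."""

    time_s: np.ndarray
    c_rb: np.ndarray      # free rocuronium, central, ug/mL
    c_sgx: np.ndarray     # free sugammadex, central, ug/mL
    c_comp: np.ndarray    # complex, central, ug/mL (mass of complex)
    ce_rb: np.ndarray     # effect-site rocuronium, ug/mL
    t1_pct: np.ndarray
    tofc: np.ndarray
    tofr: np.ndarray
    states: np.ndarray | None = None          # (N, 10) raw state history
    administered_rb: np.ndarray | None = None  # cumulative ug at each time
    administered_sgx: np.ndarray | None = None
    params: PKPDParameters | None = None

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("c_rb", "c_sgx", "c_comp", "ce_rb", "t1_pct", "tofc", "tofr"):
            if len(getattr(self, name)) != n:
                raise InputError(f"trajectory channel {name!r} has mismatched length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "c_rb": self.c_rb,
                "c_sgx": self.c_sgx,
                "c_comp": self.c_comp,
                "ce_rb": self.ce_rb,
                "t1_pct": self.t1_pct,
                "tofc": self.tofc,
                "tofr": self.tofr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def mass_balance_error(self) -> tuple[np.ndarray, np.ndarray]:
        """Relative mass-balance error per species at every output time.

        ``administered - (free + peripheral + complex-bound + eliminated)``
        scaled by the administered amount (zero where nothing was given).
        """
        if self.states is None or self.administered_rb is None:
            raise InputError("trajectory was recorded without raw state history")
        y = self.states
        p = self.params
        rb_total = y[:, 0] + y[:, 1] + p.mw_rb * (y[:, 4] + y[:, 5] + y[:, 9]) + y[:, 7]
        sgx_total = y[:, 2] + y[:, 3] + p.mw_sgx * (y[:, 4] + y[:, 5] + y[:, 9]) + y[:, 8]
        with np.errstate(divide="ignore", invalid="ignore"):
            err_rb = np.where(
                self.administered_rb > 0,
                np.abs(self.administered_rb - rb_total) / self.administered_rb,
                np.abs(rb_total),
            )
            err_sgx = np.where(
                self.administered_sgx > 0,
                np.abs(self.administered_sgx - sgx_total) / self.administered_sgx,
                np.abs(sgx_total),
            )
        return err_rb, err_sgx


class Simulation:
    """A live simulation that a dosing controller can drive tick by tick.

    The controller interface is three methods: :meth:`bolus`,
    :meth:`set_rate` and :meth:`step`, plus :meth:`observe` for the
    TOF channels.  Every visited time point is recorded; points updated
    by a dose event at an already-recorded time overwrite that record,
    so grid values are always post-event.
    """

    def __init__(
        self,
        params: PKPDParameters,
        tick_s: float = 12.0,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        method: str = "LSODA",
    ) -> None:
        params.validate()
        if tick_s <= 0.0:
            raise InputError(f"tick must be positive, got {tick_s}")
        self.params = params
        self.tick_s = tick_s
        self.rtol = rtol
        self.atol = atol
        self.method = method
        self.t = 0.0
        self.y = np.zeros(N_STATES)
        self.rb_rate_ug_min = 0.0
        self.sgx_rate_ug_min = 0.0
        self.dosed_rb_ug = 0.0
        self.dosed_sgx_ug = 0.0
        self.events: list[DoseEvent] = []
        self._hist_t: list[float] = []
        self._hist_y: list[np.ndarray] = []
        self._hist_dosed: list[tuple[float, float]] = []
        self._lin_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        self._record()

    # ------------------------------------------------------------------
    def _record(self) -> None:
        if self._hist_t and math.isclose(self._hist_t[-1], self.t, abs_tol=1e-9):
            self._hist_y[-1] = self.y.copy()
            self._hist_dosed[-1] = (self.dosed_rb_ug, self.dosed_sgx_ug)
        else:
            self._hist_t.append(self.t)
            self._hist_y.append(self.y.copy())
            self._hist_dosed.append((self.dosed_rb_ug, self.dosed_sgx_ug))

    def _linear_propagator(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        key = round(dt, 9)
        hit = self._lin_cache.get(key)
        if hit is not None:
            return hit
        p = self.params
        # per-second dynamics of [a1r, a2r, ce, elim_r]
        a = np.zeros((4, 4))
        a[0, 0] = -(p.cl_rb + p.q_rb) / p.v1_rb
        a[0, 1] = p.q_rb / p.v2_rb
        a[1, 0] = p.q_rb / p.v1_rb
        a[1, 1] = -p.q_rb / p.v2_rb
        a[2, 0] = p.ke0 / (1000.0 * p.v1_rb)
        a[2, 2] = -p.ke0
        a[3, 0] = p.cl_rb / p.v1_rb
        a /= 60.0
        # augmented exponential gives the constant-infusion response:
        # for x' = A x + b u with u in ug/min, b = e1 / 60 (ug/s)
        m = np.zeros((5, 5))
        m[:4, :4] = a
        m[0, 4] = 1.0 / 60.0
        phi = expm(m * dt)
        e, w = phi[:4, :4], phi[:4, 4]
        self._lin_cache[key] = (e, w)
        return e, w

    def _sgx_free(self) -> bool:
        y = self.y
        return (
            self.sgx_rate_ug_min == 0.0
            and y[2] == 0.0
            and y[3] == 0.0
            and y[4] == 0.0
            and y[5] == 0.0
            and y[9] == 0.0
        )

    # ------------------------------------------------------------------
    def bolus(self, drug: str, amount_ug: float) -> None:
        event = DoseEvent(self.t, drug, BOLUS, amount_ug)
        self.events.append(event)
        if drug == RB:
            self.y[0] += amount_ug
            self.dosed_rb_ug += amount_ug
        else:
            self.y[2] += amount_ug
            self.dosed_sgx_ug += amount_ug
        self._record()

    def set_rate(self, drug: str, rate_ug_min: float) -> None:
        event = DoseEvent(self.t, drug, INFUSION_RATE, rate_ug_min)
        self.events.append(event)
        if drug == RB:
            self.rb_rate_ug_min = rate_ug_min
        else:
            self.sgx_rate_ug_min = rate_ug_min

    def observe(self) -> TOFObservation:
        ce = max(0.0, float(self.y[6]))
        t1, tofc, tofr = tof_from_ce(ce, self.params)
        return TOFObservation(self.t, float(t1), int(tofc), float(tofr), ce)

    def step(self, dt: float | None = None) -> None:
        """Advance the state by ``dt`` seconds (one controller tick by
        default) with the current infusion rates held constant."""
        dt = self.tick_s if dt is None else dt
        if dt <= 0.0:
            raise InputError(f"step must be positive, got {dt}")
        if self._sgx_free():
            e, w = self._linear_propagator(dt)
            x = self.y[_LIN_IDX]
            self.y[_LIN_IDX] = e @ x + self.rb_rate_ug_min * w
        else:
            self._solve(self.t, self.t + dt, t_eval=None)
        self.dosed_rb_ug += self.rb_rate_ug_min * dt / 60.0
        self.dosed_sgx_ug += self.sgx_rate_ug_min * dt / 60.0
        self.t += dt
        self._clip_negatives()
        self._record()

    def _solve(self, t0: float, t1: float, t_eval) -> np.ndarray | None:
        sol = solve_ivp(
            ode_rhs,
            (t0, t1),
            self.y,
            method=self.method,
            rtol=self.rtol,
            atol=self.atol,
            t_eval=t_eval,
            args=(self.params, self.rb_rate_ug_min, self.sgx_rate_ug_min),
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        self.y = sol.y[:, -1].copy()
        return sol.y if t_eval is not None else None

    def _clip_negatives(self) -> None:
        floor = self.y.min()
        if floor < 0.0:
            scale = max(1.0, self.dosed_rb_ug + self.dosed_sgx_ug)
            if floor < -1e-6 * scale:
                raise SimulationError(
                    f"integration produced a significantly negative state ({floor:g})"
                )
            np.clip(self.y, 0.0, None, out=self.y)

    def run_until(self, t_end: float, bulk: bool = True) -> None:
        """Advance to ``t_end``, recording on the tick grid.

        With ``bulk`` (and sugammadex on board) a single solver call with
        dense tick-grid output is used instead of per-tick restarts --
        only valid when no dose event occurs before ``t_end``.
        """
        if t_end <= self.t:
            return
        n_ticks = int(math.floor((t_end - self.t) / self.tick_s + 1e-9))
        grid = self.t + self.tick_s * np.arange(1, n_ticks + 1)
        if bulk and not self._sgx_free() and len(grid) > 1:
            t0 = self.t
            ys = self._solve(t0, grid[-1], t_eval=grid)
            for i, tg in enumerate(grid):
                self.y = ys[:, i].copy()
                self.dosed_rb_ug += self.rb_rate_ug_min * self.tick_s / 60.0
                self.dosed_sgx_ug += self.sgx_rate_ug_min * self.tick_s / 60.0
                self.t = float(tg)
                self._clip_negatives()
                self._record()
        else:
            for _ in range(n_ticks):
                self.step()
        if self.t < t_end - 1e-9:
            self.step(t_end - self.t)

    # ------------------------------------------------------------------
    def trajectory(self) -> Trajectory:
        return _build_trajectory(
            np.asarray(self._hist_t),
            np.asarray(self._hist_y),
            np.asarray(self._hist_dosed),
            self.params,
        )


def _build_trajectory(
    times: np.ndarray, states: np.ndarray, dosed: np.ndarray, params: PKPDParameters
) -> Trajectory:
    c_rb = np.maximum(states[:, 0], 0.0) / (params.v1_rb * 1000.0)
    c_sgx = np.maximum(states[:, 2], 0.0) / (params.v1_sgx * 1000.0)
    mw_complex = params.mw_rb + params.mw_sgx
    c_comp = np.maximum(states[:, 4], 0.0) * mw_complex / (params.v1_cpx * 1000.0)
    ce = np.maximum(states[:, 6], 0.0)
    t1, tofc, tofr = tof_from_ce(ce, params)
    return Trajectory(
        time_s=times,
        c_rb=c_rb,
        c_sgx=c_sgx,
        c_comp=c_comp,
        ce_rb=ce,
        t1_pct=t1,
        tofc=tofc,
        tofr=tofr,
        states=states,
        administered_rb=dosed[:, 0],
        administered_sgx=dosed[:, 1],
        params=params,
    )


def simulate(
    events: Sequence[DoseEvent],
    params: PKPDParameters,
    duration_s: float,
    grid_dt_s: float = 12.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Open-loop simulation of a dose-event schedule.

    Events must be sorted by time; infusion-rate events persist until
    superseded.  The returned trajectory is sampled on the requested
    grid (grid values at event times are post-event); integration
    restarts at every event.
    """
    if duration_s <= 0.0:
        raise InputError(f"duration must be positive, got {duration_s}")
    if grid_dt_s <= 0.0:
        raise InputError(f"grid step must be positive, got {grid_dt_s}")
    events = list(events)
    times = [e.time_s for e in events]
    if times != sorted(times):
        raise InputError("dose events must be sorted by time")

    sim = Simulation(params, tick_s=grid_dt_s, rtol=rtol, atol=atol, method=method)
    n_grid = int(math.floor(duration_s / grid_dt_s + 1e-9))
    grid = grid_dt_s * np.arange(n_grid + 1)
    breakpoints = np.unique(
        np.concatenate([grid, [t for t in times if 0.0 <= t <= duration_s], [duration_s]])
    )

    i_event = 0
    # drop superseded rate events within one timestamp: apply in order
    for t_next in breakpoints:
        while i_event < len(events) and events[i_event].time_s <= sim.t + 1e-9:
            e = events[i_event]
            if e.kind == BOLUS:
                sim.bolus(e.drug, e.magnitude)
            else:
                sim.set_rate(e.drug, e.magnitude)
            i_event += 1
        if t_next > sim.t + 1e-9:
            sim.step(t_next - sim.t)
    while i_event < len(events) and events[i_event].time_s <= sim.t + 1e-9:
        e = events[i_event]
        if e.kind == BOLUS:
            sim.bolus(e.drug, e.magnitude)
        else:
            sim.set_rate(e.drug, e.magnitude)
        i_event += 1

    traj = sim.trajectory()
    # subselect the requested grid
    mask = np.isclose(traj.time_s[:, None], grid[None, :], rtol=0.0, atol=1e-6).any(axis=1)
    return Trajectory(
        time_s=traj.time_s[mask],
        c_rb=traj.c_rb[mask],
        c_sgx=traj.c_sgx[mask],
        c_comp=traj.c_comp[mask],
        ce_rb=traj.ce_rb[mask],
        t1_pct=traj.t1_pct[mask],
        tofc=traj.tofc[mask],
        tofr=traj.tofr[mask],
        states=traj.states[mask],
        administered_rb=traj.administered_rb[mask],
        administered_sgx=traj.administered_sgx[mask],
        params=params,
    )
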