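"""Closed-loop rocuronium dosing and the stepped sugammadex reversal.

Emulates the behaviour of an automated TIVA device's neuromuscular arm:

* induction -- 0.6 mg/kg (ideal body weight) rocuronium bolus; if the
  TOF count has not reached 0 one minute later, a 0.3 mg/kg rescue
  bolus; if block is still absent 3 min after the rescue dose, a
  7 ug/kg/min fallback infusion is started and handed to the
  auto-adjust loop after one 12-s cycle;
* maintenance -- the infusion rate is adjusted every 12-s TOF cycle to
  hold a TOF count of 1 (the device's internal law is proprietary; here
  a bounded step-rate rule is used: count 0 -> one step down, count 1 ->
  hold, count >= 2 -> one step up, with a configurable jump-start rate
  when dosing resumes from zero).  Two abnormal-state warnings are
  issued: no block after 12 min of continuous fallback dosing, and a
  TOF count >= 3 sustained for 5 min;
* reversal -- sugammadex 2 mg/kg (actual body weight) bolus after the
  rocuronium infusion stops; if the TOF ratio has not reached 0.9 after
  3 min, 0.5 mg/kg supplements every minute until it does.

All timers are quantized to the 12-s TOF observation cadence, matching
the device: nothing is observable between ticks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import PatientCovariates
from .engine import RB, SGX, BOLUS, INFUSION_RATE, DoseEvent, Simulation, TOFObservation
from .errors import ConfigError, ProtocolFailureError

WARN_NO_BLOCK = "no_block_after_continuous_dosing"
WARN_HIGH_TOFC = "tofc_ge_3_sustained"


@dataclass(frozen=True)
class ControllerConfig:
    """Protocol constants (doses per kg, timers in seconds)."""

    induction_dose_mg_kg: float = 0.6      # of ideal body weight
    rescue_dose_mg_kg: float = 0.3
    rescue_check_s: float = 60.0
    fallback_rate_ug_kg_min: float = 7.0
    fallback_delay_s: float = 180.0
    tof_interval_s: float = 12.0
    target_tofc: int = 1
    warn_no_block_s: float = 720.0
    warn_high_tofc_count: int = 3
    warn_high_tofc_s: float = 300.0
    # step-rate adjustment law (the published device exposes no law;
    # granularity chosen so the loop settles without hunting)
    rate_step_ug_kg_min: float = 0.02      # per 12-s adjustment
    rate_start_ug_kg_min: float = 5.0      # jump-start when rising from zero
    rate_max_ug_kg_min: float = 20.0
    # reversal protocol
    sgx_initial_mg_kg: float = 2.0         # of actual body weight
    sgx_supplement_mg_kg: float = 0.5
    sgx_check_s: float = 180.0
    sgx_supplement_interval_s: float = 60.0
    tofr_target: float = 0.9
    reversal_cap_s: float = 1800.0
    sgx_delay_s: float = 0.0               # manual-injection delay after stop

    def validate(self) -> None:
        for name in (
            "induction_dose_mg_kg", "rescue_dose_mg_kg", "rescue_check_s",
            "fallback_rate_ug_kg_min", "fallback_delay_s", "tof_interval_s",
            "warn_no_block_s", "warn_high_tofc_s", "rate_step_ug_kg_min",
            "rate_start_ug_kg_min", "rate_max_ug_kg_min", "sgx_initial_mg_kg",
            "sgx_supplement_mg_kg", "sgx_check_s", "sgx_supplement_interval_s",
            "tofr_target", "reversal_cap_s",
        ):
            if getattr(self, name) <= 0.0:
                raise ConfigError(f"{name} must be positive")
        tick = self.tof_interval_s
        for name in ("rescue_check_s", "fallback_delay_s", "sgx_check_s",
                     "sgx_supplement_interval_s", "warn_no_block_s",
                     "warn_high_tofc_s"):
            if abs(getattr(self, name) / tick - round(getattr(self, name) / tick)) > 1e-9:
                raise ConfigError(f"{name} must be a multiple of the TOF interval")


@dataclass
class ControllerLog:
    """TOF observations, emitted dose events, and warnings."""

    observations: list[TOFObservation] = field(default_factory=list)
    events: list[DoseEvent] = field(default_factory=list)
    warnings: list[tuple[str, float]] = field(default_factory=list)
    rb_rate_trace: list[tuple[float, float]] = field(default_factory=list)  # (t, ug/min)

    def extend(self, other: "ControllerLog") -> "ControllerLog":
        self.observations.extend(other.observations)
        self.events.extend(other.events)
        self.warnings.extend(other.warnings)
        self.rb_rate_trace.extend(other.rb_rate_trace)
        return self

    def to_record(self) -> pd.DataFrame:
        """Device-dialect dosing record: one row per TOF tick."""
        rows = {o.time_s: o for o in self.observations}
        times = sorted(rows)
        rate_t = np.array([t for t, _ in self.rb_rate_trace])
        rate_v = np.array([v for _, v in self.rb_rate_trace])
        rb_bolus = {}
        sgx_bolus = {}
        for e in self.events:
            if e.kind == BOLUS:
                target = rb_bolus if e.drug == RB else sgx_bolus
                target[e.time_s] = target.get(e.time_s, 0.0) + e.magnitude
        records = []
        for t in times:
            o = rows[t]
            if len(rate_t):
                idx = np.searchsorted(rate_t, t + 1e-9) - 1
                rate = float(rate_v[idx]) if idx >= 0 else 0.0
            else:
                rate = 0.0
            records.append(
                {
                    "time_s": t,
                    "rb_ug_per_min": rate,
                    "rb_bolus_ug": rb_bolus.get(t, 0.0),
                    "sgx_bolus_ug": sgx_bolus.get(t, 0.0),
                    "tofc": o.tofc,
                    "tofr": o.tofr,
                }
            )
        return pd.DataFrame.from_records(
            records,
            columns=["time_s", "rb_ug_per_min", "rb_bolus_ug", "sgx_bolus_ug", "tofc", "tofr"],
        )


@dataclass
class ReversalOutcome:
    """Reversal-phase summary recorded by the controller."""

    sgx_t0_s: float                 # time of the initial sugammadex bolus
    recovery_time_s: float          # first TOFR >= target, relative to t0
    ce_r_ug_ml: float               # effect-site concentration at recovery
    total_sgx_mg_kg: float
    n_supplements: int


class WarningMonitor:
    """Implements the device's two abnormal-state rules on a TOF stream."""

    def __init__(self, config: ControllerConfig) -> None:
        self.config = config
        self._high_since: float | None = None
        self._high_fired = False
        self._no_block_since: float | None = None
        self._no_block_fired = False

    def arm_no_block(self, t_s: float) -> None:
        """Start the continuous-dosing no-block timer (fallback infusion)."""
        self._no_block_since = t_s
        self._no_block_fired = False

    def disarm_no_block(self) -> None:
        self._no_block_since = None

    def update(self, t_s: float, tofc: int) -> list[tuple[str, float]]:
        cfg = self.config
        fired: list[tuple[str, float]] = []
        if tofc >= cfg.warn_high_tofc_count:
            if self._high_since is None:
                self._high_since = t_s
            elif (not self._high_fired) and t_s - self._high_since >= cfg.warn_high_tofc_s:
                fired.append((WARN_HIGH_TOFC, t_s))
                self._high_fired = True
        else:
            self._high_since = None
            self._high_fired = False
        if self._no_block_since is not None:
            if tofc == 0:
                self._no_block_since = None
            elif (not self._no_block_fired) and t_s - self._no_block_since >= cfg.warn_no_block_s:
                fired.append((WARN_NO_BLOCK, t_s))
                self._no_block_fired = True
        return fired


def _observe(sim, log: ControllerLog) -> TOFObservation:
    obs = sim.observe()
    log.observations.append(obs)
    return obs


def _bolus(sim, log: ControllerLog, drug: str, amount_ug: float) -> None:
    sim.bolus(drug, amount_ug)
    log.events.append(DoseEvent(sim.t, drug, BOLUS, amount_ug))


def _set_rate(sim, log: ControllerLog, rate_ug_min: float) -> None:
    sim.set_rate(RB, rate_ug_min)
    log.events.append(DoseEvent(sim.t, RB, INFUSION_RATE, rate_ug_min))
    log.rb_rate_trace.append((sim.t, rate_ug_min))


def run_induction(
    sim: Simulation,
    patient: PatientCovariates,
    config: ControllerConfig | None = None,
    monitor: WarningMonitor | None = None,
) -> ControllerLog:
    """Induction bolus, optional rescue bolus, optional fallback infusion.

    Returns when block (TOF count 0) is observed, or immediately after
    the fallback infusion starts.  The simulation clock is left at the
    last observed tick; maintenance takes over from there.
    """
    config = config or ControllerConfig()
    config.validate()
    log = ControllerLog()
    ibw = patient.ibw_kg
    tick = config.tof_interval_s

    _bolus(sim, log, RB, config.induction_dose_mg_kg * ibw * 1000.0)
    _observe(sim, log)

    rescue_given_at: float | None = None
    t0 = sim.t
    while True:
        sim.step(tick)
        obs = _observe(sim, log)
        if monitor is not None:
            for w in monitor.update(obs.time_s, obs.tofc):
                log.warnings.append(w)
        elapsed = sim.t - t0
        if obs.tofc == 0:
            return log
        if rescue_given_at is None and elapsed >= config.rescue_check_s - 1e-9:
            _bolus(sim, log, RB, config.rescue_dose_mg_kg * ibw * 1000.0)
            rescue_given_at = sim.t
        elif (
            rescue_given_at is not None
            and sim.t - rescue_given_at >= config.fallback_delay_s - 1e-9
        ):
            _set_rate(sim, log, config.fallback_rate_ug_kg_min * ibw)
            if monitor is not None:
                monitor.arm_no_block(sim.t)
            sim.step(tick)
            _observe(sim, log)
            return log


def run_maintenance(
    sim: Simulation,
    duration_s: float,
    patient: PatientCovariates,
    config: ControllerConfig | None = None,
    monitor: WarningMonitor | None = None,
) -> ControllerLog:
    """TOF-count-1 closed loop for ``duration_s`` seconds.

    Observes every TOF interval and applies the bounded step-rate law.
    The rocuronium infusion is stopped (rate set to zero) when the
    horizon is reached.
    """
    config = config or ControllerConfig()
    config.validate()
    if duration_s <= 0.0:
        raise ConfigError(f"maintenance duration must be positive, got {duration_s}")
    log = ControllerLog()
    monitor = monitor or WarningMonitor(config)
    ibw = patient.ibw_kg
    tick = config.tof_interval_s
    step = config.rate_step_ug_kg_min * ibw
    rate_max = config.rate_max_ug_kg_min * ibw
    t_end = sim.t + duration_s

    while sim.t < t_end - 1e-9:
        obs = _observe(sim, log)
        for w in monitor.update(obs.time_s, obs.tofc):
            log.warnings.append(w)
        rate = sim.rb_rate_ug_min
        if obs.tofc == 0:
            new_rate = max(0.0, rate - step)
        elif obs.tofc == config.target_tofc:
            new_rate = rate
        else:  # recovering block: one step up, or jump-start from zero
            if rate == 0.0:
                new_rate = config.rate_start_ug_kg_min * ibw
            else:
                new_rate = min(rate_max, rate + step)
        if new_rate != rate:
            _set_rate(sim, log, new_rate)
        sim.step(tick)
    _observe(sim, log)
    _set_rate(sim, log, 0.0)
    return log


def run_reversal(
    sim: Simulation,
    patient: PatientCovariates,
    config: ControllerConfig | None = None,
) -> tuple[ReversalOutcome, ControllerLog]:
    """Stepped sugammadex reversal until the TOF ratio reaches target.

    The initial 2 mg/kg (actual body weight) bolus is given at entry
    (after the configured manual delay); while the target ratio is not
    observed, 0.5 mg/kg supplements are given at the 3-min check and
    every minute thereafter.  No dose is given at or after the tick on
    which the target is first observed.
    """
    config = config or ControllerConfig()
    config.validate()
    if sim.rb_rate_ug_min != 0.0:
        raise ProtocolFailureError("rocuronium infusion must be stopped before reversal")
    log = ControllerLog()
    tick = config.tof_interval_s
    weight = patient.weight_kg

    if config.sgx_delay_s > 0.0:
        sim.run_until(sim.t + config.sgx_delay_s, bulk=False)
    t0 = sim.t
    _bolus(sim, log, SGX, config.sgx_initial_mg_kg * weight * 1000.0)
    total_mg_kg = config.sgx_initial_mg_kg
    n_supp = 0
    next_supplement = config.sgx_check_s

    while True:
        sim.step(tick)
        obs = _observe(sim, log)
        elapsed = sim.t - t0
        if obs.tofr >= config.tofr_target:
            outcome = ReversalOutcome(
                sgx_t0_s=t0,
                recovery_time_s=elapsed,
                ce_r_ug_ml=obs.ce_rb,
                total_sgx_mg_kg=total_mg_kg,
                n_supplements=n_supp,
            )
            return outcome, log
        if elapsed > config.reversal_cap_s + 1e-9:
            raise ProtocolFailureError(
                f"TOFR did not reach {config.tofr_target} within "
                f"{config.reversal_cap_s / 60.0:.0f} min of sugammadex"
            )
        if elapsed >= next_supplement - 1e-9:
            _bolus(sim, log, SGX, config.sgx_supplement_mg_kg * weight * 1000.0)
            total_mg_kg += config.sgx_supplement_mg_kg
            n_supp += 1
            next_supplement += config.sgx_supplement_interval_s
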