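"""End-to-end protocol simulation: induction -> maintenance -> reversal
-> endpoint extraction, for one patient or a whole synthetic cohort."""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import (
    AnalysisError,
    CohortSummary,
    RecoveryMetrics,
    classify_correlation,
    cohort_summary,
    compare_groups,
    metrics_to_frame,
    pearson_r,
    recovery_metrics,
    target_ce,
)
from .cohort import CohortConfig, CohortMember, cohort_to_frame, generate_cohort
from .controller import (
    ControllerConfig,
    ControllerLog,
    ReversalOutcome,
    WarningMonitor,
    run_induction,
    run_maintenance,
    run_reversal,
)
from .covariates import PatientCovariates
from .engine import Simulation, Trajectory
from .errors import ConfigError, NMBSimError
from .params import PKPDParameters, default_params
from .recordio import write_dosing_record

logger = logging.getLogger("nmbsim")


@dataclass
class PatientResult:
    """Everything produced for one simulated patient."""

    patient_id: int
    covariates: PatientCovariates
    params: PKPDParameters
    operation_time_h: float
    trajectory: Trajectory
    log: ControllerLog
    reversal: ReversalOutcome
    metrics: RecoveryMetrics
    maintenance_end_s: float


def simulate_patient(
    covariates: PatientCovariates,
    params: PKPDParameters,
    operation_time_h: float,
    controller_config: ControllerConfig | None = None,
    horizon_min: float = 60.0,
    patient_id: int = 0,
) -> PatientResult:
    """Run the full protocol for one patient.

    Induction (bolus +/- rescue), TOF-count-1 maintenance for the
    operation time, stepped sugammadex reversal, then an undisturbed
    observation tail out to the analysis horizon after the sugammadex
    bolus.  Endpoints are extracted from the resulting trajectory.
    """
    cfg = controller_config or ControllerConfig()
    cfg.validate()
    if operation_time_h <= 0.0:
        raise ConfigError(f"operation time must be positive, got {operation_time_h}")

    sim = Simulation(params, tick_s=cfg.tof_interval_s)
    monitor = WarningMonitor(cfg)
    log = run_induction(sim, covariates, cfg, monitor)
    log.extend(run_maintenance(sim, operation_time_h * 3600.0, covariates, cfg, monitor))
    maintenance_end_s = sim.t
    reversal, rev_log = run_reversal(sim, covariates, cfg)
    log.extend(rev_log)
    sim.run_until(reversal.sgx_t0_s + horizon_min * 60.0)

    traj = sim.trajectory()
    metrics = recovery_metrics(
        traj, reversal.sgx_t0_s, horizon_min=horizon_min, tofr_target=cfg.tofr_target
    )
    metrics.total_sgx_mg_kg = reversal.total_sgx_mg_kg
    metrics.n_supplements = reversal.n_supplements
    try:
        metrics.target_ce = target_ce(traj, maintenance_end_s)
    except AnalysisError:
        metrics.target_ce = None  # block never reached count 1 (short case)
    return PatientResult(
        patient_id=patient_id,
        covariates=covariates,
        params=params,
        operation_time_h=operation_time_h,
        trajectory=traj,
        log=log,
        reversal=reversal,
        metrics=metrics,
        maintenance_end_s=maintenance_end_s,
    )


@dataclass
class PipelineResult:
    """Cohort-level bundle returned by :func:`run_pipeline`."""

    members: list[CohortMember]
    results: list[PatientResult]
    failures: list[tuple[int, str]]
    metrics_frame: pd.DataFrame
    summary: CohortSummary
    correlations: pd.DataFrame
    group_comparison: pd.DataFrame | None


def _correlation_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Correlations of age / eCCr / intraoperative target Ce with Ce_r."""
    rows = []
    for var in ("age_y", "eccr_ml_min", "target_ce"):
        sub = frame[[var, "ce_r"]].dropna()
        try:
            r = pearson_r(sub[var], sub["ce_r"])
            rows.append(
                {"variable": var, "r": r, "n": len(sub), "class": classify_correlation(r)}
            )
        except NMBSimError as exc:
            rows.append({"variable": var, "r": np.nan, "n": len(sub), "class": str(exc)})
    return pd.DataFrame.from_records(rows)


def run_pipeline(
    n: int = 74,
    seed: int = 0,
    cohort_config: CohortConfig | None = None,
    base_params: PKPDParameters | None = None,
    controller_config: ControllerConfig | None = None,
    horizon_min: float = 60.0,
    outdir: str | pathlib.Path | None = None,
    save_trajectories: bool = False,
    make_plots: bool = False,
) -> PipelineResult:
    """Simulate a synthetic cohort end-to-end and assemble the report.

    Per-patient failures are recorded and the pipeline continues; it
    raises only if every patient fails.  When ``outdir`` is given the
    cohort table, per-patient metrics, dosing records, summary and
    (optionally) trajectory CSVs and figures are written there.
    """
    if n < 1:
        raise ConfigError(f"cohort size must be >= 1, got {n}")
    base = base_params or default_params()
    members = generate_cohort(n, seed, cohort_config, base)

    results: list[PatientResult] = []
    failures: list[tuple[int, str]] = []
    for m in members:
        try:
            results.append(
                simulate_patient(
                    m.covariates,
                    m.params,
                    m.operation_time_h,
                    controller_config,
                    horizon_min=horizon_min,
                    patient_id=m.patient_id,
                )
            )
        except NMBSimError as exc:
            logger.warning("patient %d failed: %s", m.patient_id, exc)
            failures.append((m.patient_id, str(exc)))
    if not results:
        raise ConfigError("all patients failed; check configuration")

    metrics = [r.metrics for r in results]
    frame = metrics_to_frame(metrics, ids=[r.patient_id for r in results])
    cov_frame = cohort_to_frame([members[r.patient_id] for r in results])
    frame = frame.merge(
        cov_frame[["id", "age_y", "eccr_ml_min", "weight_kg", "op_time_h"]], on="id"
    )
    summary = cohort_summary(metrics)
    correlations = _correlation_table(frame)
    supplemented = frame["n_supplements"].fillna(0) > 0
    comparison = None
    if 2 <= supplemented.sum() <= len(frame) - 2:
        comparison = compare_groups(
            frame,
            supplemented.to_numpy(),
            variables=["age_y", "weight_kg", "eccr_ml_min", "target_ce", "ce_r"],
        )

    result = PipelineResult(
        members=members,
        results=results,
        failures=failures,
        metrics_frame=frame,
        summary=summary,
        correlations=correlations,
        group_comparison=comparison,
    )
    if outdir is not None:
        _write_bundle(result, pathlib.Path(outdir), save_trajectories, make_plots)
    return result


def summary_markdown(result: PipelineResult) -> str:
    """Human-readable cohort report (narrative block + tables)."""
    s = result.summary
    lines = [
        "# Simulated cohort report",
        "",
        f"Patients simulated: {s.n} (failures: {len(result.failures)})",
        f"Supplemented patients: {s.n_supplemented}",
        f"Rebound cases: {s.n_rebound}",
        f"Recurarization-risk cases (Ce_max > Ce_r): {s.n_recur}",
        "",
        "## Endpoint summary (mean / SD / min / max)",
        "",
        "```",
        s.to_frame().to_string(float_format=lambda v: f"{v:.3f}"),
        "```",
        "",
        "## Correlations with Ce_r",
        "",
        "```",
        result.correlations.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        "```",
    ]
    if result.group_comparison is not None:
        lines += [
            "",
            "## Supplemented (A) vs not (NA)",
            "",
            "```",
            result.group_comparison.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "```",
        ]
    return "\n".join(lines) + "\n"


def _write_bundle(
    result: PipelineResult, outdir: pathlib.Path, save_trajectories: bool, make_plots: bool
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(result.members).to_csv(outdir / "cohort.csv", index=False)
    result.metrics_frame.to_csv(outdir / "metrics.csv", index=False)
    result.correlations.to_csv(outdir / "correlations.csv", index=False)
    if result.group_comparison is not None:
        result.group_comparison.to_csv(outdir / "group_comparison.csv", index=False)
    (outdir / "summary.md").write_text(summary_markdown(result))
    records_dir = outdir / "records"
    records_dir.mkdir(exist_ok=True)
    for r in result.results:
        write_dosing_record(
            r.log.to_record(), records_dir / f"patient_{r.patient_id:03d}.csv"
        )
    if save_trajectories:
        traj_dir = outdir / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        for r in result.results:
            r.trajectory.to_csv(traj_dir / f"patient_{r.patient_id:03d}.csv")
    if make_plots:
        from . import plots

        fig_dir = outdir / "figures"
        fig_dir.mkdir(exist_ok=True)
        if result.results:
            plots.plot_trajectory(result.results[0]).savefig(
                fig_dir / "example_trajectory.png", dpi=120
            )
            plots.plot_reversal(result.results[0]).savefig(
                fig_dir / "example_reversal.png", dpi=120
            )
        plots.plot_correlations(result.metrics_frame).savefig(
            fig_dir / "correlations.png", dpi=120
        )
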