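"""Recurarization-risk endpoints and cohort statistics.

From a simulated (or replayed) trajectory the module extracts the
recovery concentration Ce_r (free rocuronium effect-site concentration
at the first TOFR >= 0.9 observation), the post-recovery nadir
(t_min, Ce_min), the rebound peak after the nadir (t_max, Ce_max), and
the recurarization flag Ce_max > Ce_r.  Cohort-level helpers compute
the summary block, correlation classification, and the two-group
comparison (supplemented vs not) with a pooled-variance t-test.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import Trajectory
from .errors import AnalysisError, InputError

#: relative rise above the nadir required to call a rebound (filters
#: numerical ripple; the clinical series reported rebounds in nearly
#: every subject without printing a detection rule)
REBOUND_REL_TOL = 0.01

#: default post-reversal analysis horizon, min
DEFAULT_HORIZON_MIN = 60.0


@dataclass
class RecoveryMetrics:
    """Per-patient reversal endpoints (times in minutes from sugammadex)."""

    t_r_min: float                    # sugammadex -> first TOFR >= 0.9
    ce_r: float                       # ug/mL at recovery
    t_min_min: float                  # recovery -> Ce nadir
    ce_min: float
    t_max_min: float | None           # recovery -> rebound peak (if any)
    ce_max: float | None
    rebound: bool
    recur_flag: bool                  # Ce_max > Ce_r
    total_sgx_mg_kg: float | None = None
    n_supplements: int | None = None
    target_ce: float | None = None    # intraoperative plateau, ug/mL

    def to_dict(self) -> dict:
        return asdict(self)


def recovery_metrics(
    traj: Trajectory,
    sgx_t0_s: float,
    horizon_min: float = DEFAULT_HORIZON_MIN,
    tofr_target: float = 0.9,
    rebound_rel_tol: float = REBOUND_REL_TOL,
) -> RecoveryMetrics:
    """Extract recovery/rebound endpoints after a sugammadex bolus.

    Ce_r is read at the first grid point with TOFR >= target; the nadir
    is the global minimum of Ce after that point within the horizon;
    the rebound peak is the maximum after the nadir, declared only when
    it exceeds the nadir by ``rebound_rel_tol`` (relative).
    """
    t = np.asarray(traj.time_s, dtype=float)
    ce = np.asarray(traj.ce_rb, dtype=float)
    tofr = np.asarray(traj.tofr, dtype=float)
    horizon_s = sgx_t0_s + horizon_min * 60.0

    window = (t >= sgx_t0_s - 1e-9) & (t <= horizon_s + 1e-9)
    if not window.any():
        raise AnalysisError("trajectory does not cover the reversal window")
    tw, cew, tofrw = t[window], ce[window], tofr[window]

    recovered = np.flatnonzero(tofrw >= tofr_target)
    if len(recovered) == 0:
        raise AnalysisError("not recovered: TOFR never reached target in the window")
    i_r = recovered[0]
    t_r = tw[i_r]
    ce_r = cew[i_r]

    seg_t, seg_ce = tw[i_r:], cew[i_r:]
    i_min = int(np.argmin(seg_ce))
    t_min, ce_min = seg_t[i_min], seg_ce[i_min]

    post_t, post_ce = seg_t[i_min + 1 :], seg_ce[i_min + 1 :]
    rebound = False
    t_max: float | None = None
    ce_max: float | None = None
    if len(post_ce):
        i_max = int(np.argmax(post_ce))
        if post_ce[i_max] > ce_min * (1.0 + rebound_rel_tol):
            rebound = True
            t_max = float(post_t[i_max])
            ce_max = float(post_ce[i_max])

    recur = bool(rebound and ce_max > ce_r)
    return RecoveryMetrics(
        t_r_min=float((t_r - sgx_t0_s) / 60.0),
        ce_r=float(ce_r),
        t_min_min=float((t_min - t_r) / 60.0),
        ce_min=float(ce_min),
        t_max_min=None if t_max is None else float((t_max - t_r) / 60.0),
        ce_max=ce_max,
        rebound=rebound,
        recur_flag=recur,
    )


def target_ce(
    traj: Trajectory,
    maintenance_end_s: float,
    window_min: float = 30.0,
    target_tofc: int = 1,
) -> float:
    """Intraoperative target concentration: mean Ce over the final
    maintenance window, restricted to ticks at the target TOF count."""
    t = np.asarray(traj.time_s, dtype=float)
    mask = (
        (t >= maintenance_end_s - window_min * 60.0 - 1e-9)
        & (t <= maintenance_end_s + 1e-9)
        & (np.asarray(traj.tofc) == target_tofc)
    )
    if not mask.any():
        raise AnalysisError(
            f"no TOFC = {target_tofc} observations in the maintenance window"
        )
    return float(np.mean(np.asarray(traj.ce_rb)[mask]))


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("inputs must be equal-length 1-D samples")
    if len(x) < 3:
        raise InputError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise InputError("correlation undefined for a constant sample")
    return float(stats.pearsonr(x, y).statistic)


#: correlation strength bands on |r| (lower edge inclusive, assigned to
#: the stronger label at shared boundaries)
CORRELATION_BANDS = (
    (0.7, "strong"),
    (0.4, "correlation"),
    (0.2, "weak"),
    (0.0, "none"),
)


def classify_correlation(r: float) -> str:
    """Label a correlation coefficient: strong (|r| >= 0.7),
    correlation (>= 0.4), weak (>= 0.2), none (< 0.2)."""
    if not math.isfinite(r) or abs(r) > 1.0 + 1e-12:
        raise InputError(f"|r| must be <= 1, got {r}")
    a = abs(r)
    for edge, label in CORRELATION_BANDS:
        if a >= edge:
            return label
    return "none"  # pragma: no cover - bands include 0


def compare_groups(
    frame: pd.DataFrame,
    group_mask,
    variables: list[str] | None = None,
    welch: bool = False,
    group_names: tuple[str, str] = ("A", "NA"),
) -> pd.DataFrame:
    """Two-group comparison table: per-variable mean +/- SD and the
    two-sided t-test p-value (pooled variance by default)."""
    mask = np.asarray(group_mask, dtype=bool)
    if len(mask) != len(frame):
        raise InputError("group mask length must match the table")
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise AnalysisError("both groups need at least 2 members")
    variables = variables or [
        c for c in frame.columns if pd.api.types.is_numeric_dtype(frame[c])
    ]
    rows = []
    for var in variables:
        a = frame.loc[mask, var].dropna().to_numpy(dtype=float)
        b = frame.loc[~mask, var].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise AnalysisError(f"variable {var!r}: a group has < 2 values")
        res = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "variable": var,
                f"mean_{group_names[0]}": a.mean(),
                f"sd_{group_names[0]}": a.std(ddof=1),
                f"n_{group_names[0]}": len(a),
                f"mean_{group_names[1]}": b.mean(),
                f"sd_{group_names[1]}": b.std(ddof=1),
                f"n_{group_names[1]}": len(b),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame.from_records(rows)


@dataclass
class CohortSummary:
    """Cohort-level descriptive block for the reversal endpoints."""

    n: int
    n_rebound: int
    n_recur: int
    n_supplemented: int
    stats: dict[str, dict[str, float]]  # metric -> {mean, sd, min, max}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stats).T


def cohort_summary(metrics: list[RecoveryMetrics]) -> CohortSummary:
    """Means, SDs and ranges of the endpoints plus the headline counts.

    Rebound-conditional metrics (Ce_max, t_max) are summarized over the
    rebound cases only.  With a single value the SD is reported as 0.
    """
    if not metrics:
        raise InputError("metrics list must be non-empty")

    def describe(values: list[float]) -> dict[str, float]:
        arr = np.asarray(values, dtype=float)
        if len(arr) == 0:
            return {"mean": math.nan, "sd": math.nan, "min": math.nan, "max": math.nan, "n": 0}
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return {
            "mean": float(arr.mean()),
            "sd": sd,
            "min": float(arr.min()),
            "max": float(arr.max()),
            "n": len(arr),
        }

    rebound_cases = [m for m in metrics if m.rebound]
    table = {
        "t_r_min": describe([m.t_r_min for m in metrics]),
        "ce_r": describe([m.ce_r for m in metrics]),
        "t_min_min": describe([m.t_min_min for m in metrics]),
        "ce_min": describe([m.ce_min for m in metrics]),
        "t_max_min": describe([m.t_max_min for m in rebound_cases]),
        "ce_max": describe([m.ce_max for m in rebound_cases]),
    }
    totals = [m.total_sgx_mg_kg for m in metrics if m.total_sgx_mg_kg is not None]
    if totals:
        table["total_sgx_mg_kg"] = describe(totals)
    targets = [m.target_ce for m in metrics if m.target_ce is not None]
    if targets:
        table["target_ce"] = describe(targets)
    n_supp = sum(
        1 for m in metrics if (m.n_supplements or 0) > 0
    )
    return CohortSummary(
        n=len(metrics),
        n_rebound=len(rebound_cases),
        n_recur=sum(1 for m in metrics if m.recur_flag),
        n_supplemented=n_supp,
        stats=table,
    )


def metrics_to_frame(metrics: list[RecoveryMetrics], ids=None) -> pd.DataFrame:
    rows = [m.to_dict() for m in metrics]
    frame = pd.DataFrame.from_records(rows)
    if ids is not None:
        frame.insert(0, "id", list(ids))
    return frame
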