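"""Endpoint extraction, correlation classification, group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nmbsim import (
    AnalysisError,
    DoseEvent,
    InputError,
    RecoveryMetrics,
    classify_correlation,
    cohort_summary,
    compare_groups,
    pearson_r,
    recovery_metrics,
    simulate,
    target_ce,
)
from nmbsim.engine import Trajectory
from nmbsim.pd_model import tof_from_ce


def toy_trajectory(ce, tofr, dt_s=60.0, tofc=None):
    ce = np.asarray(ce, dtype=float)
    tofr = np.asarray(tofr, dtype=float)
    n = len(ce)
    tofc = np.full(n, 4) if tofc is None else np.asarray(tofc)
    return Trajectory(
        time_s=dt_s * np.arange(n),
        c_rb=ce.copy(),
        c_sgx=np.zeros(n),
        c_comp=np.zeros(n),
        ce_rb=ce,
        t1_pct=np.full(n, 50.0),
        tofc=tofc,
        tofr=tofr,
    )


# ------------------------------------------------------ recovery metrics ----
def test_hand_traced_toy_trajectory():
    """One-minute grid, recovery at the third sample: Ce_r = 0.20,
    nadir 0.02 at step 4, rebound peak 0.04 at step 5, no recurarization."""
    traj = toy_trajectory(
        ce=[1.0, 0.5, 0.20, 0.05, 0.02, 0.04, 0.03],
        tofr=[0.2, 0.5, 0.93, 0.95, 0.96, 0.97, 0.97],
    )
    m = recovery_metrics(traj, sgx_t0_s=0.0, horizon_min=10.0)
    assert m.ce_r == pytest.approx(0.20)
    assert m.t_r_min == pytest.approx(2.0)
    assert m.ce_min == pytest.approx(0.02)
    assert m.t_min_min == pytest.approx(2.0)  # two steps after recovery
    assert m.rebound
    assert m.ce_max == pytest.approx(0.04)
    assert m.t_max_min == pytest.approx(3.0)
    assert not m.recur_flag


def test_monotone_decay_has_no_rebound():
    ce = np.geomspace(1.0, 0.001, 30)
    tofr = np.where(ce < 0.3, 0.95, 0.1)
    m = recovery_metrics(toy_trajectory(ce, tofr), 0.0, horizon_min=60.0)
    assert not m.rebound
    assert m.ce_max is None and m.t_max_min is None
    assert not m.recur_flag


def test_rise_above_recovery_concentration_flags_recurarization():
    ce = [1.0, 0.3, 0.20, 0.05, 0.02, 0.10, 0.22, 0.21]
    tofr = [0.1, 0.5, 0.93, 0.95, 0.96, 0.9, 0.9, 0.9]
    m = recovery_metrics(toy_trajectory(ce, tofr), 0.0, horizon_min=10.0)
    assert m.rebound
    assert m.ce_max == pytest.approx(0.22)  # 1.1 x Ce_r
    assert m.recur_flag


def test_unrecovered_window_is_an_error():
    traj = toy_trajectory([1.0, 0.9, 0.8], [0.1, 0.2, 0.3])
    with pytest.raises(AnalysisError, match="not recovered"):
        recovery_metrics(traj, 0.0, horizon_min=5.0)


def test_metrics_invariants_on_engine_output(ref_params):
    """On a real engine trajectory the ordering invariants hold:
    t_r < t_min < t_max and Ce_min <= min(Ce_r, Ce_max)."""
    events = [
        DoseEvent(0.0, "rb", "bolus", 2.0e4),
        DoseEvent(0.0, "rb", "infusion_rate", 280.0),
        DoseEvent(3600.0, "rb", "infusion_rate", 0.0),
        DoseEvent(3600.0, "sgx", "bolus", 1.2e5),
    ]
    traj = simulate(events, ref_params, duration_s=3600.0 + 3600.0)
    m = recovery_metrics(traj, sgx_t0_s=3600.0)
    assert 0.0 < m.t_r_min < m.t_r_min + m.t_min_min < m.t_r_min + m.t_max_min
    assert m.ce_min <= m.ce_r
    assert m.ce_min <= m.ce_max
    assert not m.recur_flag


def test_grid_refinement_stability(ref_params):
    """Halving the output grid step moves the extracted concentrations
    by less than 1%."""
    events = [
        DoseEvent(0.0, "rb", "bolus", 2.0e4),
        DoseEvent(0.0, "rb", "infusion_rate", 280.0),
        DoseEvent(3600.0, "rb", "infusion_rate", 0.0),
        DoseEvent(3600.0, "sgx", "bolus", 1.2e5),
    ]
    coarse = recovery_metrics(
        simulate(events, ref_params, 7200.0, grid_dt_s=12.0), 3600.0
    )
    fine = recovery_metrics(
        simulate(events, ref_params, 7200.0, grid_dt_s=6.0), 3600.0
    )
    assert fine.ce_r == pytest.approx(coarse.ce_r, rel=0.01)
    assert fine.ce_min == pytest.approx(coarse.ce_min, rel=0.01)
    assert fine.ce_max == pytest.approx(coarse.ce_max, rel=0.01)


# ------------------------------------------------------------- target Ce ----
def test_target_ce_constant_plateau():
    n = 40
    traj = toy_trajectory(np.full(n, 1.0), np.zeros(n), tofc=np.ones(n))
    assert target_ce(traj, maintenance_end_s=39 * 60.0) == pytest.approx(1.0)


def test_target_ce_alternating_average():
    ce = np.tile([0.8, 1.2], 20)
    traj = toy_trajectory(ce, np.zeros(40), tofc=np.ones(40))
    assert target_ce(traj, maintenance_end_s=39 * 60.0, window_min=40.0) == pytest.approx(1.0)


def test_target_ce_masks_other_counts():
    ce = np.tile([1.0, 5.0], 20)
    tofc = np.tile([1, 0], 20)
    traj = toy_trajectory(ce, np.zeros(40), tofc=tofc)
    assert target_ce(traj, maintenance_end_s=39 * 60.0) == pytest.approx(1.0)
    empty = toy_trajectory(ce, np.zeros(40), tofc=np.zeros(40))
    with pytest.raises(AnalysisError):
        target_ce(empty, maintenance_end_s=39 * 60.0)


# ------------------------------------------------------------ correlation ----
def test_pearson_known_values():
    x = np.arange(10.0)
    assert pearson_r(x, 2.0 * x + 1.0) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)
    with pytest.raises(InputError):
        pearson_r(np.ones(10), x)
    with pytest.raises(InputError):
        pearson_r(x[:3], x[:4])


@pytest.mark.parametrize(
    "r, label",
    [
        (0.55, "correlation"),
        (-0.39, "weak"),
        (0.34, "weak"),
        (0.1, "none"),
        (0.7, "strong"),     # boundary -> stronger band
        (0.4, "correlation"),
        (0.2, "weak"),
        (-1.0, "strong"),
        (0.0, "none"),
    ],
)
def test_classify_correlation_bands(r, label):
    assert classify_correlation(r) == label


def test_classify_rejects_out_of_range():
    with pytest.raises(InputError):
        classify_correlation(1.5)


@settings(deadline=None, max_examples=300)
@given(st.floats(min_value=-1.0, max_value=1.0))
def test_classification_exhaustive_and_exclusive(r):
    assert classify_correlation(r) in {"strong", "correlation", "weak", "none"}


# ---------------------------------------------------------- group compare ----
def test_identical_groups_give_p_one():
    frame = pd.DataFrame({"x": np.tile([1.0, 2.0, 3.0], 2)})
    mask = np.array([True] * 3 + [False] * 3)
    table = compare_groups(frame, mask, ["x"])
    assert table.loc[0, "p_value"] == pytest.approx(1.0)


def test_separated_groups_are_significant():
    rng = np.random.default_rng(5)
    frame = pd.DataFrame({"x": np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 24)])})
    mask = np.array([True] * 50 + [False] * 24)  # unbalanced clinical-series group sizes
    table = compare_groups(frame, mask, ["x"])
    assert table.loc[0, "p_value"] < 1e-3
    assert table.loc[0, "n_A"] == 50 and table.loc[0, "n_NA"] == 24


def test_pooled_t_matches_textbook_formula():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.3, 9)
    frame = pd.DataFrame({"x": np.concatenate([a, b])})
    mask = np.array([True] * 12 + [False] * 9)
    p_pkg = compare_groups(frame, mask, ["x"]).loc[0, "p_value"]
    # independent hand computation of the pooled-variance t-test
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    from scipy import stats

    p_hand = 2.0 * stats.t.sf(abs(t), len(a) + len(b) - 2)
    assert p_pkg == pytest.approx(p_hand, rel=1e-12)


def test_small_group_rejected():
    frame = pd.DataFrame({"x": np.arange(5.0)})
    with pytest.raises(AnalysisError):
        compare_groups(frame, np.array([True] + [False] * 4), ["x"])


# ---------------------------------------------------------------- summary ----
def make_metrics(rebound=True, recur=False, supplements=0):
    return RecoveryMetrics(
        t_r_min=2.0,
        ce_r=0.3,
        t_min_min=6.0,
        ce_min=0.02,
        t_max_min=25.0 if rebound else None,
        ce_max=0.05 if rebound else None,
        rebound=rebound,
        recur_flag=recur,
        total_sgx_mg_kg=2.0 + 0.5 * supplements,
        n_supplements=supplements,
    )


def test_summary_counts_mirror_flags():
    metrics = [make_metrics() for _ in range(72)] + [
        make_metrics(rebound=False),
        make_metrics(rebound=False),
    ]
    s = cohort_summary(metrics)
    assert s.n == 74
    assert s.n_rebound == 72
    assert s.n_recur == 0
    assert s.stats["ce_max"]["n"] == 72


def test_summary_single_patient_sd_zero():
    s = cohort_summary([make_metrics(supplements=1)])
    assert s.n == 1
    assert s.n_supplemented == 1
    assert s.stats["ce_r"]["sd"] == 0.0


def test_recur_count_is_flag_count():
    metrics = [make_metrics(recur=(i % 5 == 0)) for i in range(10)]
    assert cohort_summary(metrics).n_recur == 2
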