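"""Advisory matplotlib figures (concentration timelines, reversal
close-up, endpoint correlations)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_trajectory(result) -> plt.Figure:
    """Blood / effect-site concentrations and TOF channels over the run."""
    traj = result.trajectory
    t_min = traj.time_s / 60.0
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
    ax1.plot(t_min, traj.c_rb, label="C_Rb (free)")
    ax1.plot(t_min, traj.c_sgx, label="C_SGX (free)")
    ax1.plot(t_min, traj.c_comp, label="C_comp")
    ax1.plot(t_min, traj.ce_rb, label="Ce_Rb", ls="--")
    ax1.set_yscale("symlog", linthresh=0.01)
    ax1.set_ylabel("concentration (ug/mL)")
    ax1.legend(loc="upper right", fontsize=8)
    ax2.plot(t_min, traj.tofc, drawstyle="steps-post", label="TOFC")
    ax2.plot(t_min, 4 * traj.tofr, drawstyle="steps-post", label="4 x TOFR")
    ax2.set_xlabel("time (min)")
    ax2.set_ylabel("TOF")
    ax2.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    return fig


def plot_reversal(result, window_min: float = 60.0) -> plt.Figure:
    """Effect-site rebound structure after sugammadex with the endpoint
    markers (Ce_r, nadir, rebound peak)."""
    traj = result.trajectory
    t0 = result.reversal.sgx_t0_s
    m = result.metrics
    mask = (traj.time_s >= t0) & (traj.time_s <= t0 + window_min * 60.0)
    t_rel = (traj.time_s[mask] - t0) / 60.0
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(t_rel, traj.ce_rb[mask], label="Ce_Rb")
    ax.axhline(m.ce_r, color="tab:red", lw=0.8, ls="--", label="Ce_r")
    ax.plot(m.t_r_min + m.t_min_min, m.ce_min, "v", color="tab:green", label="nadir")
    if m.rebound:
        ax.plot(m.t_r_min + m.t_max_min, m.ce_max, "^", color="tab:orange", label="rebound peak")
    ax.set_xlabel("time from sugammadex (min)")
    ax.set_ylabel("Ce_Rb (ug/mL)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_correlations(metrics_frame: pd.DataFrame) -> plt.Figure:
    """Scatter of Ce_r against age, eCCr and intraoperative target Ce."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharey=True)
    for ax, var, label in zip(
        axes,
        ("age_y", "eccr_ml_min", "target_ce"),
        ("age (y)", "eCCr (mL/min)", "target Ce_Rb (ug/mL)"),
    ):
        sub = metrics_frame[[var, "ce_r"]].dropna()
        ax.plot(sub[var], sub["ce_r"], "o", ms=3, alpha=0.7)
        ax.set_xlabel(label)
    axes[0].set_ylabel("Ce_r (ug/mL)")
    fig.tight_layout()
    return fig
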