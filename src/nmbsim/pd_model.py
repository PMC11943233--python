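"""Effect-site concentration -> train-of-four pharmacodynamics.

Each of the four TOF twitches follows an inhibitory sigmoid Emax (Hill)
curve of the rocuronium effect-site concentration.  Fade -- the
progressive depression of later twitches at a given concentration -- is
modelled by giving twitches 2..4 proportionally lower EC50s
(``fade2..fade4`` in the parameter set).  From the four twitch heights:

* T1 is the first-twitch height in % of control,
* TOFC counts the twitches above the detection threshold,
* TOFR is T4/T1, reported only when all four twitches are detectable
  (otherwise 0.0, the device convention for an unmeasurable ratio).
"""

from __future__ import annotations

import numpy as np

from .params import PKPDParameters


def twitch_heights(ce: np.ndarray | float, params: PKPDParameters) -> np.ndarray:
    """Heights of twitches 1..4 (% of control) at effect-site conc. ``ce``.

    Returns an array of shape ``(4,) + shape(ce)``.
    """
    ce = np.asarray(ce, dtype=float)
    if np.any(ce < 0.0):
        raise ValueError("effect-site concentration must be non-negative")
    ec50 = params.ec50_t1 * np.array(
        [1.0, params.fade2, params.fade3, params.fade4]
    )
    gamma = params.hill_gamma
    # 100 * EC50^g / (EC50^g + Ce^g), computed in log space for stability
    with np.errstate(divide="ignore"):
        ratio = np.where(ce[..., None] > 0.0, ce[..., None] / ec50, 0.0) ** gamma
    heights = 100.0 / (1.0 + ratio)
    return np.moveaxis(heights, -1, 0)


def tof_from_ce(
    ce: np.ndarray | float, params: PKPDParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map effect-site concentration to (T1 %, TOF count, TOF ratio).

    Vectorized over ``ce``; scalars in give 0-d arrays out.
    """
    heights = twitch_heights(ce, params)
    t1 = heights[0]
    detected = heights >= params.twitch_threshold_pct
    # twitches disappear in order 4,3,2,1 (EC50s are ordered), so the
    # count of detectable twitches is a plain sum
    tofc = detected.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(t1 > 0.0, heights[3] / t1, 0.0)
    tofr = np.where(tofc == 4, np.minimum(ratio, 1.0), 0.0)
    return t1, tofc.astype(np.int64), tofr


def ce_at_tofr(target_tofr: float, params: PKPDParameters) -> float:
    """Effect-site concentration at which TOFR equals ``target_tofr``.

    Solved by bisection on the closed-form ratio; used for calibration
    checks and diagnostics (TOFR is strictly decreasing in Ce).
    """
    if not 0.0 < target_tofr < 1.0:
        raise ValueError("target TOFR must be in (0, 1)")
    lo, hi = 0.0, 100.0 * params.ec50_t1
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        heights = twitch_heights(mid, params)
        ratio = heights[3] / heights[0]
        if ratio > target_tofr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ce_at_t1(target_t1_pct: float, params: PKPDParameters) -> float:
    """Effect-site concentration at which twitch 1 equals ``target_t1_pct``."""
    if not 0.0 < target_t1_pct < 100.0:
        raise ValueError("target T1 must be in (0, 100)")
    gamma = params.hill_gamma
    return params.ec50_t1 * (100.0 / target_t1_pct - 1.0) ** (1.0 / gamma)
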