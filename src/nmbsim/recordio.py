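"""Device-dialect dosing-record I/O.

The automated delivery system records drug doses at a fixed 12-s cadence
as comma-separated files.  The dialect used here is declared, not
claimed device-compatible: one row per interval with columns

    time_s, rb_ug_per_min, rb_bolus_ug, sgx_bolus_ug, tofc, tofr

``rb_bolus_ug`` (an extension so induction boluses round-trip exactly)
and the two TOF columns are optional on input.  Reading reconstructs a
canonical dose-event list: a rate event wherever the recorded rate
changes (including the first row), and a bolus event for every non-zero
bolus cell.
"""

from __future__ import annotations

import math
import pathlib

import numpy as np
import pandas as pd

from .engine import BOLUS, INFUSION_RATE, RB, SGX, DoseEvent
from .errors import ParseError

RECORD_CADENCE_S = 12.0
REQUIRED_COLUMNS = ("time_s", "rb_ug_per_min")
OPTIONAL_COLUMNS = ("rb_bolus_ug", "sgx_bolus_ug", "tofc", "tofr")


def write_dosing_record(record: pd.DataFrame, path) -> None:
    """Write a dosing-record table (e.g. ``ControllerLog.to_record()``)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in record.columns]
    if missing:
        raise ParseError(f"dosing record is missing columns: {missing}")
    record.to_csv(path, index=False)


def events_from_record(record: pd.DataFrame) -> list[DoseEvent]:
    """Canonical dose-event list from a validated record table."""
    events: list[DoseEvent] = []
    previous_rate = 0.0  # no infusion before the record starts
    for row in record.itertuples(index=False):
        t = float(row.time_s)
        rate = float(row.rb_ug_per_min)
        if rate != previous_rate:
            events.append(DoseEvent(t, RB, INFUSION_RATE, rate))
            previous_rate = rate
        rb_bolus = float(getattr(row, "rb_bolus_ug", 0.0) or 0.0)
        if rb_bolus > 0.0:
            events.append(DoseEvent(t, RB, BOLUS, rb_bolus))
        sgx_bolus = float(getattr(row, "sgx_bolus_ug", 0.0) or 0.0)
        if sgx_bolus > 0.0:
            events.append(DoseEvent(t, SGX, BOLUS, sgx_bolus))
    return events


def read_dosing_record(
    path, cadence_s: float = RECORD_CADENCE_S
) -> list[DoseEvent]:
    """Read and validate a dosing-record CSV; return its dose events.

    Validation: header with the required columns, strictly increasing
    time at the fixed cadence, no negative doses.  Errors name the
    offending row (1-based, excluding the header).
    """
    path = pathlib.Path(path)
    try:
        record = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"cannot parse dosing record {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in record.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in ("rb_ug_per_min", "rb_bolus_ug", "sgx_bolus_ug"):
        if col in record.columns:
            values = pd.to_numeric(record[col], errors="coerce")
            bad = values.isna() & record[col].notna()
            if bad.any():
                raise ParseError(f"{path}: non-numeric {col} at row {bad.idxmax() + 1}")
            negative = values.fillna(0.0) < 0.0
            if negative.any():
                raise ParseError(
                    f"{path}: negative dose in {col} at row {int(np.argmax(negative.values)) + 1}"
                )
    times = record["time_s"].to_numpy(dtype=float)
    for i in range(1, len(times)):
        gap = times[i] - times[i - 1]
        if gap <= 0.0:
            raise ParseError(f"{path}: time not strictly increasing at row {i + 1}")
        if not math.isclose(gap, cadence_s, abs_tol=1e-6):
            raise ParseError(
                f"{path}: cadence broken at row {i + 1} "
                f"(gap {gap:g} s, expected {cadence_s:g} s)"
            )
    return events_from_record(record)
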