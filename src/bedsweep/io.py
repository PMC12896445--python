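"""Cohort CSV reading/writing with full-file schema validation.

The cohort schema is one UTF-8 CSV row per tumor with exactly the columns
in :data:`bedsweep.cohort.COHORT_COLUMNS`.  Validation collects *all*
offending cells (with 1-based data-row numbers) before raising, so a bad
file is reported once, completely.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .cohort import COHORT_COLUMNS, LOCATIONS, SEXES, CohortRecord, frame_to_records, records_to_frame
from .errors import SchemaError

__all__ = ["read_cohort", "write_cohort"]


def _check_numeric(df, col, errors, *, positive=False, integer=False, binary=False):
    vals = pd.to_numeric(df[col], errors="coerce")
    for i, (raw, v) in enumerate(zip(df[col], vals), start=1):
        if pd.isna(v):
            errors.append(f"row {i}: {col}={raw!r} is not numeric")
        elif binary and v not in (0, 1):
            errors.append(f"row {i}: {col}={raw!r} must be 0 or 1")
        elif integer and v != int(v):
            errors.append(f"row {i}: {col}={raw!r} must be an integer")
        elif positive and not v > 0:
            errors.append(f"row {i}: {col}={raw!r} must be > 0")
    return vals


def read_cohort(path) -> list[CohortRecord]:
    """Read and validate a cohort CSV; returns one record per tumor.

    Raises :class:`~bedsweep.errors.SchemaError` listing every offending
    cell by data-row number (the first row after the header is row 1).
    """
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing required column(s): {', '.join(missing)}"])
    errors: list[str] = []
    _check_numeric(df, "age_years", errors, positive=True)
    _check_numeric(df, "gtv_cc", errors, positive=True)
    _check_numeric(df, "ptv_cc", errors, positive=True)
    _check_numeric(df, "bmi", errors, positive=True)
    _check_numeric(df, "n_fractions", errors, positive=True, integer=True)
    _check_numeric(df, "dose_per_fraction_gy", errors, positive=True)
    _check_numeric(df, "ptbe_event", errors, binary=True)
    _check_numeric(df, "time_to_event_days", errors, positive=True)
    _check_numeric(df, "hypertension", errors, binary=True)
    _check_numeric(df, "diabetes", errors, binary=True)
    for i, v in enumerate(df["sex"], start=1):
        if v not in SEXES:
            errors.append(f"row {i}: sex={v!r} must be one of {SEXES}")
    for i, v in enumerate(df["location"], start=1):
        if v not in LOCATIONS:
            errors.append(f"row {i}: location={v!r} must be one of {LOCATIONS}")
    if not errors:
        gtv = pd.to_numeric(df["gtv_cc"])
        ptv = pd.to_numeric(df["ptv_cc"])
        for i, (g, p) in enumerate(zip(gtv, ptv), start=1):
            if p < g:
                errors.append(f"row {i}: ptv_cc={p} must be >= gtv_cc={g}")
    if errors:
        raise SchemaError(errors)
    typed = df[COHORT_COLUMNS].copy()
    for col in typed.columns:
        if col not in ("patient_id", "tumor_id", "sex", "location"):
            # numpy's parser is correctly rounded, so write->read round-trips
            typed[col] = typed[col].to_numpy().astype(float)
    return frame_to_records(typed)


def write_cohort(records: Iterable[CohortRecord], path) -> None:
    """Write a cohort to CSV in the canonical column order."""
    records_to_frame(records).to_csv(Path(path), index=False)
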