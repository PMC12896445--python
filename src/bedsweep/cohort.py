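"""Cohort record container and tabular conversion.

One :class:`CohortRecord` describes one treated tumor: its fractionation
scheme, the binary/time-to-event outcome (post-radiotherapy peritumoral
brain edema, PTBE), and the clinical covariates used by the analyses.
Patients with more than one treated tumor contribute one record per tumor.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidParameterError
from .radiobiology import TreatmentScheme, compute_bed

__all__ = ["CohortRecord", "COHORT_COLUMNS", "records_to_frame", "frame_to_records"]

SEXES = ("female", "male")
LOCATIONS = ("convexity", "parasagittal_falcine")

#: Canonical CSV column order of the cohort schema.
COHORT_COLUMNS = [
    "patient_id",
    "tumor_id",
    "age_years",
    "sex",
    "location",
    "gtv_cc",
    "ptv_cc",
    "bmi",
    "n_fractions",
    "dose_per_fraction_gy",
    "ptbe_event",
    "time_to_event_days",
    "hypertension",
    "diabetes",
]


@dataclass(frozen=True)
class CohortRecord:
    """One tumor treated with LINAC-based radiotherapy.

    ``time_to_event_days`` counts from radiotherapy completion to PTBE
    (``ptbe_event = 1``) or to the last imaging follow-up (``0``, censored).
    """

    patient_id: str
    tumor_id: str
    age_years: float
    sex: str
    location: str
    gtv_cc: float
    ptv_cc: float
    bmi: float
    n_fractions: int
    dose_per_fraction_gy: float
    ptbe_event: int
    time_to_event_days: float
    hypertension: int
    diabetes: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InvalidParameterError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.location not in LOCATIONS:
            raise InvalidParameterError(
                f"location must be one of {LOCATIONS}, got {self.location!r}"
            )
        if not (self.time_to_event_days > 0):
            raise InvalidParameterError("time_to_event_days must be positive")
        if self.ptbe_event not in (0, 1):
            raise InvalidParameterError("ptbe_event must be 0 or 1")
        if self.hypertension not in (0, 1) or self.diabetes not in (0, 1):
            raise InvalidParameterError("hypertension and diabetes must be 0 or 1")
        if not (self.gtv_cc > 0 and self.ptv_cc > 0):
            raise InvalidParameterError("tumor volumes must be positive")
        if self.ptv_cc < self.gtv_cc:
            raise InvalidParameterError("ptv_cc must be >= gtv_cc (PTV is an expansion of GTV)")
        # delegates dose/fraction validation
        TreatmentScheme(self.n_fractions, self.dose_per_fraction_gy)

    @property
    def scheme(self) -> TreatmentScheme:
        return TreatmentScheme(self.n_fractions, self.dose_per_fraction_gy)

    def bed(self, alpha_beta: float) -> float:
        """Biologically effective dose of this tumor's scheme (Gy)."""
        return compute_bed(self.scheme, alpha_beta)


def records_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical column order."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df[COHORT_COLUMNS] if len(df) else pd.DataFrame(columns=COHORT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CohortRecord]:
    """Inverse of :func:`records_to_frame`; assumes an already-valid frame."""
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            CohortRecord(
                patient_id=str(d["patient_id"]),
                tumor_id=str(d["tumor_id"]),
                age_years=float(d["age_years"]),
                sex=str(d["sex"]),
                location=str(d["location"]),
                gtv_cc=float(d["gtv_cc"]),
                ptv_cc=float(d["ptv_cc"]),
                bmi=float(d["bmi"]),
                n_fractions=int(d["n_fractions"]),
                dose_per_fraction_gy=float(d["dose_per_fraction_gy"]),
                ptbe_event=int(d["ptbe_event"]),
                time_to_event_days=float(d["time_to_event_days"]),
                hypertension=int(d["hypertension"]),
                diabetes=int(d["diabetes"]),
            )
        )
    return records
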