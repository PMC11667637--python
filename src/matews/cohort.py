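"""Patient data model, infection-severity classification, and cohort CSV I/O.

A cohort is a list of :class:`PatientRecord`, one per woman, each carrying up
to three :class:`DayObservation` slots (the day before enrolment, the day of
enrolment, and the day after — day indices −1, 0, +1) together with outcome
and intervention flags observed over the hospital stay.

Severity classification follows the WHO near-miss framework: a woman with any
near-miss criterion or who died has a severe maternal outcome (SMO, the proxy
for maternal sepsis); otherwise, an invasive procedure to treat the infection
source, ICU/high-dependency admission, or transfer marks a complicated
infection; the remainder are less severe infections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "AVPU_LEVELS",
    "DayObservation",
    "PatientRecord",
    "Severity",
    "OutcomeFlags",
    "classify_severity",
    "outcome_flags",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
]

AVPU_LEVELS = ("alert", "voice", "pain", "unresponsive")
PREGNANCY_STATUSES = ("pregnant", "postpartum", "postabortion")

#: Broad physiological plausibility bounds (exclusive) used for validation.
PLAUSIBILITY = {
    "systolic_bp": (20.0, 300.0),
    "diastolic_bp": (10.0, 250.0),
    "heart_rate": (0.0, 300.0),
    "respiratory_rate": (0.0, 90.0),
    "temperature": (25.0, 45.0),
    "spo2": (0.0, 100.0001),
    "wbc": (0.0, 200.0),
    "lactate": (0.0, 40.0),
    "paco2": (1.0, 200.0),
    "urine_output": (0.0, 2000.0),
}


@dataclass
class DayObservation:
    """Vital signs, labs and mental status captured on one study day.

    Every clinical field is individually optional; ``None`` means the value
    was not recorded that day.
    """

    day_index: int
    systolic_bp: Optional[float] = None
    diastolic_bp: Optional[float] = None
    heart_rate: Optional[float] = None
    respiratory_rate: Optional[float] = None
    temperature: Optional[float] = None
    spo2: Optional[float] = None
    gcs: Optional[int] = None
    avpu: Optional[str] = None
    wbc: Optional[float] = None
    lactate: Optional[float] = None
    paco2: Optional[float] = None
    urine_output: Optional[float] = None
    mental_state_altered: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.day_index not in (-1, 0, 1):
            raise ValueError(f"day_index must be -1, 0 or +1, got {self.day_index}")
        for name, (lo, hi) in PLAUSIBILITY.items():
            v = getattr(self, name)
            if v is not None and not (lo < float(v) < hi):
                raise ValueError(f"{name}={v} outside plausible range ({lo}, {hi})")
        if self.gcs is not None:
            g = int(self.gcs)
            if not 3 <= g <= 15:
                raise ValueError(f"gcs={self.gcs} outside [3, 15]")
            self.gcs = g
        if self.avpu is not None and self.avpu not in AVPU_LEVELS:
            raise ValueError(f"avpu={self.avpu!r} not one of {AVPU_LEVELS}")


class Severity(str, Enum):
    """Infection severity group of one woman (a strict partition)."""

    SMO = "smo"
    COMPLICATED = "complicated"
    LESS_SEVERE = "less_severe"


@dataclass
class PatientRecord:
    """One woman: day observations plus outcome/intervention flags."""

    id: str
    pregnancy_status: str
    days: dict[int, DayObservation] = field(default_factory=dict)
    near_miss: Optional[bool] = None
    died: Optional[bool] = None
    invasive_procedure: Optional[bool] = None
    icu_or_hdu_admission: Optional[bool] = None
    transferred: Optional[bool] = None
    hospital_stay_days: Optional[int] = None
    icu_days: Optional[int] = None
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pregnancy_status not in PREGNANCY_STATUSES:
            raise ValueError(
                f"pregnancy_status={self.pregnancy_status!r} not one of {PREGNANCY_STATUSES}"
            )
        for d, obs in self.days.items():
            if d != obs.day_index:
                raise ValueError(f"days key {d} does not match observation day {obs.day_index}")
        if (
            self.icu_days is not None
            and self.hospital_stay_days is not None
            and self.icu_days > self.hospital_stay_days
        ):
            raise ValueError(
                f"icu_days={self.icu_days} exceeds hospital_stay_days={self.hospital_stay_days}"
            )
        for name in ("hospital_stay_days", "icu_days"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def observation(self, day_index: int) -> Optional[DayObservation]:
        return self.days.get(day_index)

    def add_observation(self, obs: DayObservation) -> None:
        if obs.day_index in self.days:
            raise ValueError(f"duplicate observation for day {obs.day_index} (woman {self.id})")
        self.days[obs.day_index] = obs


def classify_severity(record: PatientRecord) -> Severity:
    """Assign the woman to exactly one severity group.

    SMO (near miss or death) strictly dominates; then any of invasive
    procedure / ICU or HDU admission / transfer makes the infection
    complicated; otherwise less severe. Missing flags count as False.
    """
    if bool(record.near_miss) or bool(record.died):
        return Severity.SMO
    if (
        bool(record.invasive_procedure)
        or bool(record.icu_or_hdu_admission)
        or bool(record.transferred)
    ):
        return Severity.COMPLICATED
    return Severity.LESS_SEVERE


@dataclass(frozen=True)
class OutcomeFlags:
    """Outcome strata used for the triggered-proportion subgroups.

    ``long_stay`` / ``icu_3plus`` are ``None`` (undefined, excluded from the
    relevant denominator) when the underlying duration is missing.
    """

    is_smo: bool
    is_complicated_or_worse: bool
    long_stay: Optional[bool]
    icu_3plus: Optional[bool]


def outcome_flags(record: PatientRecord) -> OutcomeFlags:
    sev = classify_severity(record)
    long_stay = None if record.hospital_stay_days is None else record.hospital_stay_days > 7
    icu_3plus = None if record.icu_days is None else record.icu_days >= 3
    return OutcomeFlags(
        is_smo=sev is Severity.SMO,
        is_complicated_or_worse=sev in (Severity.SMO, Severity.COMPLICATED),
        long_stay=long_stay,
        icu_3plus=icu_3plus,
    )


# ---------------------------------------------------------------------------
# CSV dialect: one row per woman-day; per-woman fields repeated on each row.

CSV_COLUMNS = [
    "id", "day", "sbp", "dbp", "hr", "rr", "temp", "spo2", "gcs", "avpu",
    "wbc", "lactate", "paco2", "urine_output", "altered_mentation",
    "pregnancy_status", "near_miss", "died", "invasive_procedure",
    "icu_admission", "transferred", "hospital_stay_days", "icu_days", "stratum",
]

_OBS_FROM_CSV = {
    "sbp": "systolic_bp",
    "dbp": "diastolic_bp",
    "hr": "heart_rate",
    "rr": "respiratory_rate",
    "temp": "temperature",
    "spo2": "spo2",
    "gcs": "gcs",
    "avpu": "avpu",
    "wbc": "wbc",
    "lactate": "lactate",
    "paco2": "paco2",
    "urine_output": "urine_output",
    "altered_mentation": "mental_state_altered",
}

_BOOL_COLUMNS = ("near_miss", "died", "invasive_procedure", "icu_admission", "transferred")


def _opt_float(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def _opt_bool(v) -> Optional[bool]:
    if pd.isna(v):
        return None
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("1", "true", "t", "yes"):
            return True
        if s in ("0", "false", "f", "no"):
            return False
        raise ValueError(f"cannot parse boolean value {v!r}")
    return bool(int(v))


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV (one row per woman-day) into PatientRecord objects.

    Unknown columns are ignored with a warning; empty fields are missing
    values. Outcome flags left empty are treated as False downstream, with a
    warning here.
    """
    df = pd.read_csv(path, dtype={"id": str, "avpu": str, "pregnancy_status": str, "stratum": str})
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    missing = [c for c in ("id", "day", "pregnancy_status") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required columns: {missing}")

    records: list[PatientRecord] = []
    n_missing_outcomes = 0
    for woman_id, rows in df.groupby("id", sort=False):
        first = rows.iloc[0]
        kwargs = {}
        for col in _BOOL_COLUMNS:
            v = _opt_bool(first[col]) if col in rows.columns else None
            if v is None:
                n_missing_outcomes += 1
            kwargs["icu_or_hdu_admission" if col == "icu_admission" else col] = v
        rec = PatientRecord(
            id=str(woman_id),
            pregnancy_status=str(first["pregnancy_status"]),
            hospital_stay_days=(
                None if "hospital_stay_days" not in rows.columns
                or pd.isna(first["hospital_stay_days"])
                else int(first["hospital_stay_days"])
            ),
            icu_days=(
                None if "icu_days" not in rows.columns or pd.isna(first["icu_days"])
                else int(first["icu_days"])
            ),
            stratum=(
                None if "stratum" not in rows.columns or pd.isna(first["stratum"])
                else str(first["stratum"])
            ),
            **kwargs,
        )
        for _, row in rows.iterrows():
            obs_kwargs = {}
            for csv_name, field_name in _OBS_FROM_CSV.items():
                if csv_name not in rows.columns:
                    continue
                v = row[csv_name]
                if field_name == "avpu":
                    obs_kwargs[field_name] = None if pd.isna(v) else str(v)
                elif field_name == "mental_state_altered":
                    obs_kwargs[field_name] = _opt_bool(v)
                elif field_name == "gcs":
                    obs_kwargs[field_name] = None if pd.isna(v) else int(v)
                else:
                    obs_kwargs[field_name] = _opt_float(v)
            rec.add_observation(DayObservation(day_index=int(row["day"]), **obs_kwargs))
        records.append(rec)

    if n_missing_outcomes:
        warnings.warn(
            f"{n_missing_outcomes} empty outcome flags treated as False", stacklevel=2
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate woman ids in cohort CSV")
    return records


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Serialise a cohort to the one-row-per-woman-day CSV dialect."""
    rows = []
    for rec in cohort:
        days = sorted(rec.days) or [0]
        for d in days:
            obs = rec.days.get(d)
            row = {
                "id": rec.id,
                "day": d,
                "pregnancy_status": rec.pregnancy_status,
                "near_miss": _b(rec.near_miss),
                "died": _b(rec.died),
                "invasive_procedure": _b(rec.invasive_procedure),
                "icu_admission": _b(rec.icu_or_hdu_admission),
                "transferred": _b(rec.transferred),
                "hospital_stay_days": rec.hospital_stay_days,
                "icu_days": rec.icu_days,
                "stratum": rec.stratum,
            }
            for csv_name, field_name in _OBS_FROM_CSV.items():
                v = getattr(obs, field_name) if obs is not None else None
                if field_name == "mental_state_altered":
                    v = _b(v)
                row[csv_name] = v
            rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _b(v: Optional[bool]):
    return None if v is None else int(bool(v))


def write_cohort(cohort: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)
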