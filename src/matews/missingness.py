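"""Missing-data profiling and per-score computability accounting.

"Overall" missingness for a woman means the variable was recorded on none of
her captured days — the relevant notion for score computability, since a
score needs only one complete day. Per-day rates are reported alongside.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohort import PatientRecord
from .scores import Registry, _resolve

__all__ = ["missing_rates", "computability_matrix"]

#: Clinical variables profiled, in the cohort-CSV naming.
PROFILE_VARIABLES = {
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

DAYS = (-1, 0, 1)


def missing_rates(cohort: Sequence[PatientRecord], by_day: bool = True) -> pd.DataFrame:
    """Percentage of women missing each variable, overall and (optionally) per day.

    Overall: missing on every captured day (an absent day observation counts
    as missing). Per-day: missing on that specific day. Returns a tidy frame
    with columns ``variable, day, pct_missing`` where ``day`` is −1/0/1 or
    ``"overall"``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n = len(cohort)
    rows = []
    for csv_name, field_name in PROFILE_VARIABLES.items():
        per_day_missing = {d: 0 for d in DAYS}
        overall_missing = 0
        for rec in cohort:
            present_any = False
            for d in DAYS:
                obs = rec.days.get(d)
                v = None if obs is None else getattr(obs, field_name)
                if v is None:
                    per_day_missing[d] += 1
                else:
                    present_any = True
            if not present_any:
                overall_missing += 1
        if by_day:
            for d in DAYS:
                rows.append(
                    {"variable": csv_name, "day": str(d),
                     "pct_missing": 100.0 * per_day_missing[d] / n}
                )
        rows.append(
            {"variable": csv_name, "day": "overall",
             "pct_missing": 100.0 * overall_missing / n}
        )
    return pd.DataFrame(rows)


def computability_matrix(registry: Registry, cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-score count of women for whom the score is computable.

    Determined directly from day-level variable availability plus score
    applicability; by construction this equals the complete-case denominators
    used by the scoring and diagnostics modules.
    """
    rows = []
    for definition in registry.values():
        count = 0
        for rec in cohort:
            if not definition.applies_to(rec):
                continue
            for obs in rec.days.values():
                if all(_resolve(obs, v) is not None for v in definition.required_variables):
                    count += 1
                    break
        rows.append({"score": definition.name, "n_computable": count, "n_cohort": len(cohort)})
    return pd.DataFrame(rows)
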