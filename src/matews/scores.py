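"""Declarative rule engine for early warning systems (EWS).

An EWS is described entirely as data: a set of threshold bands over the
day-observation variables plus an aggregation rule. The engine evaluates a
score on each observed day; a day is usable only when every required variable
is present that day (complete-data rule, no cross-day imputation), and a
woman's score is triggered when it is triggered on any usable day.

Aggregation rules
-----------------
``count_ge_k``        count distinct satisfied criteria; trigger at ``k``.
``points_ge_k``       sum band weights; trigger at ``k`` points.
``any_red``           trigger on a single red-zone abnormality.
``red1_or_yellow2``   trigger on one red or two yellow abnormalities
                      (track-and-trigger chart convention).
``ratio_ge``          numerator/denominator ratio at or above a cutoff
                      (shock-index family).

Derived variables
-----------------
``map``                     mean arterial pressure, (SBP + 2·DBP)/3.
``gcs_effective``           GCS, or an AVPU→GCS mapping when GCS is absent.
``consciousness_abnormal``  0/1; altered-mentation flag, else AVPU≠alert,
                            else GCS<15.
``avpu_level``              0 alert, 1 voice, 2 pain, 3 unresponsive, with a
                            GCS fallback for charts that grade consciousness.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .cohort import AVPU_LEVELS, DayObservation, PatientRecord

__all__ = [
    "ScoreConfigError",
    "ThresholdBand",
    "ScoreDefinition",
    "ScoreResult",
    "Registry",
    "load_score_definitions",
    "compute_map",
    "evaluate_score_on_day",
    "evaluate_score",
    "score_cohort",
]

SCORE_NAMES_21 = (
    "FAST-M", "FAST-M red flag", "IMEWS", "MEOWS A", "MEOWS B", "MEOWS C",
    "MEOWS D", "MEOWS E", "MEOWS F", "MEWT", "SOS", "NICE-RST-PP/PA",
    "NICE-RST-P", "mSIRS", "OmqSOFA", "qSOFA-P", "EMIP", "qSOFA", "SIRS",
    "SI", "MSI",
)

COMPARATORS = ("lt", "le", "gt", "ge", "inside", "outside")
ZONES = ("yellow", "red", "flag")
CATEGORIES = ("obstetric_nonsepsis", "obstetric_sepsis", "generic")
APPLICABILITIES = ("pregnant", "postpartum_postabortion", "any")

OBSERVATION_VARIABLES = (
    "systolic_bp", "diastolic_bp", "heart_rate", "respiratory_rate",
    "temperature", "spo2", "gcs", "wbc", "lactate", "paco2", "urine_output",
)
DERIVED_VARIABLES = ("map", "gcs_effective", "consciousness_abnormal", "avpu_level")
KNOWN_VARIABLES = OBSERVATION_VARIABLES + DERIVED_VARIABLES

#: AVPU → GCS mapping used when a chart needs GCS but only AVPU was charted.
AVPU_TO_GCS = {"alert": 15, "voice": 12, "pain": 9, "unresponsive": 3}


class ScoreConfigError(ValueError):
    """Raised for malformed or inconsistent score-definition config."""


def compute_map(systolic: float, diastolic: float) -> float:
    """Mean arterial pressure in mmHg: one third systolic, two thirds diastolic."""
    if systolic is None or diastolic is None:
        raise ValueError("both pressures are required to compute MAP")
    if not systolic >= diastolic > 0:
        raise ValueError(f"need systolic >= diastolic > 0, got ({systolic}, {diastolic})")
    return (float(systolic) + 2.0 * float(diastolic)) / 3.0


@dataclass(frozen=True)
class ThresholdBand:
    variable: str
    comparator: str
    bound: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    weight: int = 1
    zone: Optional[str] = None
    criterion: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variable not in KNOWN_VARIABLES:
            raise ScoreConfigError(f"band references unknown variable {self.variable!r}")
        if self.comparator not in COMPARATORS:
            raise ScoreConfigError(
                f"band on {self.variable!r}: unknown comparator {self.comparator!r}"
            )
        if self.comparator in ("inside", "outside"):
            if self.low is None or self.high is None or not self.low <= self.high:
                raise ScoreConfigError(
                    f"range band on {self.variable!r} needs low <= high, "
                    f"got ({self.low}, {self.high})"
                )
        elif self.bound is None:
            raise ScoreConfigError(f"band on {self.variable!r} lacks a bound")
        if self.weight < 0:
            raise ScoreConfigError(f"band on {self.variable!r}: negative weight")
        if self.zone is not None and self.zone not in ZONES:
            raise ScoreConfigError(f"band on {self.variable!r}: unknown zone {self.zone!r}")

    def satisfied(self, value: float) -> bool:
        v = float(value)
        if self.comparator == "lt":
            return v < self.bound
        if self.comparator == "le":
            return v <= self.bound
        if self.comparator == "gt":
            return v > self.bound
        if self.comparator == "ge":
            return v >= self.bound
        if self.comparator == "inside":
            return self.low <= v <= self.high
        return v < self.low or v > self.high  # outside

    @property
    def criterion_key(self) -> str:
        return self.criterion if self.criterion is not None else f"{self.variable}/{id(self)}"


@dataclass(frozen=True)
class Aggregation:
    type: str
    k: Optional[int] = None
    cutoff: Optional[float] = None
    numerator: Optional[str] = None
    denominator: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type in ("count_ge_k", "points_ge_k"):
            if self.k is None or self.k < 1:
                raise ScoreConfigError(f"aggregation {self.type} needs k >= 1")
        elif self.type == "ratio_ge":
            if not (self.numerator and self.denominator and self.cutoff is not None):
                raise ScoreConfigError("ratio_ge needs numerator, denominator and cutoff")
            for v in (self.numerator, self.denominator):
                if v not in KNOWN_VARIABLES:
                    raise ScoreConfigError(f"ratio operand {v!r} unknown")
        elif self.type not in ("any_red", "red1_or_yellow2"):
            raise ScoreConfigError(f"unknown aggregation type {self.type!r}")


@dataclass(frozen=True)
class ScoreDefinition:
    name: str
    category: str
    applicability: str
    aggregation: Aggregation
    bands: tuple[ThresholdBand, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ScoreConfigError(f"{self.name}: unknown category {self.category!r}")
        if self.applicability not in APPLICABILITIES:
            raise ScoreConfigError(f"{self.name}: unknown applicability {self.applicability!r}")
        if self.aggregation.type in ("any_red", "red1_or_yellow2"):
            for b in self.bands:
                if b.zone is None:
                    raise ScoreConfigError(
                        f"{self.name}: zone aggregation requires zone labels on every band"
                    )
        if not self.bands and self.aggregation.type != "ratio_ge":
            raise ScoreConfigError(f"{self.name}: no bands")

    @property
    def required_variables(self) -> tuple[str, ...]:
        vars_ = {b.variable for b in self.bands}
        if self.aggregation.type == "ratio_ge":
            vars_ |= {self.aggregation.numerator, self.aggregation.denominator}
        return tuple(sorted(vars_))

    def applies_to(self, record: PatientRecord) -> bool:
        if self.applicability == "any":
            return True
        if self.applicability == "pregnant":
            return record.pregnancy_status == "pregnant"
        return record.pregnancy_status in ("postpartum", "postabortion")


@dataclass
class ScoreResult:
    score_name: str
    computable: bool
    woman_id: Optional[str] = None
    triggered: Optional[bool] = None
    numeric_value: Optional[float] = None
    missing_variables: list[str] = field(default_factory=list)
    triggering_day: Optional[int] = None
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.computable and self.triggered is not None:
            raise ValueError("triggered is undefined for a non-computable result")


# ---------------------------------------------------------------------------
# Derived-variable resolution

def _resolve(obs: DayObservation, var: str) -> Optional[float]:
    """Value of ``var`` on ``obs``, resolving derived variables; None if missing."""
    if var == "map":
        if obs.systolic_bp is None or obs.diastolic_bp is None:
            return None
        try:
            return compute_map(obs.systolic_bp, obs.diastolic_bp)
        except ValueError:
            return None  # internally inconsistent pressures: not computable
    if var == "gcs_effective":
        if obs.gcs is not None:
            return float(obs.gcs)
        if obs.avpu is not None:
            return float(AVPU_TO_GCS[obs.avpu])
        return None
    if var == "consciousness_abnormal":
        if obs.mental_state_altered is not None:
            return 1.0 if obs.mental_state_altered else 0.0
        if obs.avpu is not None:
            return 0.0 if obs.avpu == "alert" else 1.0
        if obs.gcs is not None:
            return 0.0 if obs.gcs >= 15 else 1.0
        return None
    if var == "avpu_level":
        if obs.avpu is not None:
            return float(AVPU_LEVELS.index(obs.avpu))
        if obs.gcs is not None:
            g = obs.gcs
            return 0.0 if g >= 15 else 1.0 if g >= 13 else 2.0 if g >= 9 else 3.0
        if obs.mental_state_altered is not None:
            return 1.0 if obs.mental_state_altered else 0.0
        return None
    return getattr(obs, var)


#: Reported name for a derived variable that could not be resolved.
_MISSING_LABEL = {
    "gcs_effective": "gcs",
    "consciousness_abnormal": "mental_status",
    "avpu_level": "avpu",
}


def _missing_for(obs: DayObservation, var: str) -> list[str]:
    if var == "map":
        missing = [
            v for v, val in (
                ("systolic_bp", obs.systolic_bp), ("diastolic_bp", obs.diastolic_bp)
            ) if val is None
        ]
        return missing or ["map"]
    return [_MISSING_LABEL.get(var, var)]


def evaluate_score_on_day(definition: ScoreDefinition, obs: DayObservation) -> ScoreResult:
    """Evaluate one score on a single day (complete-data rule applies)."""
    values: dict[str, float] = {}
    missing: list[str] = []
    for var in definition.required_variables:
        v = _resolve(obs, var)
        if v is None:
            missing.extend(_missing_for(obs, var))
        else:
            values[var] = v
    if missing:
        return ScoreResult(
            score_name=definition.name,
            computable=False,
            missing_variables=sorted(set(missing)),
        )

    agg = definition.aggregation
    if agg.type == "ratio_ge":
        denom = values[agg.denominator]
        if denom == 0:
            return ScoreResult(
                score_name=definition.name, computable=False,
                missing_variables=[], reason="zero denominator",
            )
        ratio = values[agg.numerator] / denom
        return ScoreResult(
            score_name=definition.name, computable=True,
            triggered=ratio >= agg.cutoff, numeric_value=ratio,
        )

    satisfied = [b for b in definition.bands if b.satisfied(values[b.variable])]
    if agg.type == "count_ge_k":
        value = float(len({b.criterion_key for b in satisfied}))
        triggered = value >= agg.k
    elif agg.type == "points_ge_k":
        value = float(sum(b.weight for b in satisfied))
        triggered = value >= agg.k
    elif agg.type == "any_red":
        value = float(sum(b.zone == "red" for b in satisfied))
        triggered = value >= 1
    else:  # red1_or_yellow2
        reds = sum(b.zone == "red" for b in satisfied)
        yellows = sum(b.zone == "yellow" for b in satisfied)
        value = float(2 * reds + yellows)
        triggered = reds >= 1 or yellows >= 2
    return ScoreResult(
        score_name=definition.name, computable=True,
        triggered=triggered, numeric_value=value,
    )


def evaluate_score(definition: ScoreDefinition, record: PatientRecord) -> ScoreResult:
    """Evaluate one score on a woman across her observed days.

    Computable when at least one day is computable; triggered when triggered
    on any computable day (earliest such day recorded); the numeric value is
    the maximum daily value.
    """
    if not definition.applies_to(record):
        return ScoreResult(
            score_name=definition.name, woman_id=record.id, computable=False,
            reason=f"inapplicable to pregnancy status {record.pregnancy_status!r}",
        )
    day_results = [
        (d, evaluate_score_on_day(definition, record.days[d])) for d in sorted(record.days)
    ]
    computable = [(d, r) for d, r in day_results if r.computable]
    if not computable:
        missing = sorted({m for _, r in day_results for m in r.missing_variables})
        return ScoreResult(
            score_name=definition.name, woman_id=record.id, computable=False,
            missing_variables=missing,
            reason="no computable day" if day_results else "no observations",
        )
    triggering = [(d, r) for d, r in computable if r.triggered]
    return ScoreResult(
        score_name=definition.name,
        woman_id=record.id,
        computable=True,
        triggered=bool(triggering),
        numeric_value=max(r.numeric_value for _, r in computable),
        triggering_day=triggering[0][0] if triggering else None,
    )


# ---------------------------------------------------------------------------
# Registry loading

class Registry(dict):
    """Mapping score name → ScoreDefinition, with config provenance."""

    sha256: Optional[str] = None
    source: Optional[str] = None

    def definitions(self) -> list[ScoreDefinition]:
        return list(self.values())


def _parse_band(raw: dict, score_name: str) -> ThresholdBand:
    if not isinstance(raw, dict) or "variable" not in raw or "comparator" not in raw:
        raise ScoreConfigError(f"{score_name}: malformed band entry {raw!r}")
    allowed = {"variable", "comparator", "bound", "low", "high", "weight", "zone", "criterion"}
    extra = set(raw) - allowed
    if extra:
        raise ScoreConfigError(f"{score_name}: unknown band keys {sorted(extra)}")
    try:
        return ThresholdBand(**raw)
    except ScoreConfigError as e:
        raise ScoreConfigError(f"{score_name}: {e}") from None


def load_score_definitions(config_source=None) -> Registry:
    """Load score definitions from YAML/JSON text, a path, or the bundled default.

    Returns a :class:`Registry`; its ``sha256`` attribute fingerprints the
    exact rule set so reports can cite it.
    """
    if config_source is None:
        text = resources.files("matews.data").joinpath("ews_definitions.yaml").read_text()
        source = "bundled:ews_definitions.yaml"
    elif hasattr(config_source, "read"):
        text = config_source.read()
        source = getattr(config_source, "name", "<stream>")
    else:
        s = str(config_source)
        if "\n" in s or s.lstrip().startswith(("{", "version:", "scores:", "- ", "#")):
            text, source = s, "<inline>"
        else:
            with open(s) as fh:
                text = fh.read()
            source = s

    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "scores" not in doc:
        raise ScoreConfigError("config must be a mapping with a 'scores' list")
    registry = Registry()
    for entry in doc["scores"]:
        name = entry.get("name")
        if not name:
            raise ScoreConfigError(f"score entry without a name: {entry!r}")
        if name in registry:
            raise ScoreConfigError(f"duplicate score name {name!r}")
        try:
            agg = Aggregation(**entry.get("aggregation", {}))
        except (TypeError, ScoreConfigError) as e:
            raise ScoreConfigError(f"{name}: bad aggregation ({e})") from None
        bands = tuple(_parse_band(b, name) for b in entry.get("bands", []))
        registry[name] = ScoreDefinition(
            name=name,
            category=entry.get("category", "generic"),
            applicability=entry.get("applicability", "any"),
            aggregation=agg,
            bands=bands,
        )
    registry.sha256 = hashlib.sha256(text.encode()).hexdigest()
    registry.source = source
    return registry


def score_cohort(registry: Registry, cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Evaluate every score on every woman.

    Returns a long-form trigger matrix with one row per (woman, score):
    columns ``woman_id, score, computable, triggered, value, triggering_day,
    reason``. ``triggered`` is NA for non-computable results. Inapplicable
    (score, woman) pairs are included as non-computable with a reason, so
    per-score denominators are simply the count of computable rows.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for rec in cohort:
        for definition in registry.values():
            r = evaluate_score(definition, rec)
            rows.append(
                {
                    "woman_id": rec.id,
                    "score": definition.name,
                    "computable": r.computable,
                    "triggered": r.triggered,
                    "value": r.numeric_value,
                    "triggering_day": r.triggering_day,
                    "reason": r.reason,
                }
            )
    df = pd.DataFrame(rows)
    df["triggered"] = df["triggered"].astype("boolean")
    return df
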