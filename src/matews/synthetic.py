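"""Seeded generator of synthetic maternal-infection cohorts.

Emulates the structure of the multi-country maternal sepsis analysis set the
package targets: a three-group severity mix (61.7% less severe, 23.4%
complicated, 14.9% severe maternal outcome), three observation days per woman
(day −1, day 0, day +1), group-shifted vital signs and labs, outcome flags
consistent with each group, and heavy per-variable missingness (worst for
blood-gas and lactate measurements, mildest for blood pressure and pulse).

Group sizes are allocated by deterministic largest-remainder rounding, so the
default configuration at n = 2560 reproduces the published 1580/599/381
split exactly; everything else is drawn from the seeded generator. Vitals are
truncated normals, conditionally independent given severity group — the
generator makes no attempt to copy real inter-variable correlation.

Missingness is MCAR. The default mode masks each (woman, variable) across all
days at the configured rate — matching the published per-variable accounting,
in which a variable counts as missing when it was never recorded for the
woman — plus additive per-day masking that makes the enrolment day (day 0)
the most complete. An independent per-(woman, day) mode is available via
``missingness_mode="day"``. A severity-dependent (MNAR) stress mode inflates
masking for the most severe group.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .cohort import DayObservation, PatientRecord

__all__ = ["GeneratorConfig", "generate_cohort", "apply_missingness"]

SEVERITIES = ("less_severe", "complicated", "smo")
DAYS = (-1, 0, 1)

#: Healthy-baseline distributions: mean, sd, truncation low/high.
BASELINES = {
    "heart_rate": (84.0, 11.0, 40.0, 220.0),
    "respiratory_rate": (17.0, 2.5, 8.0, 60.0),
    "temperature": (37.0, 0.45, 34.0, 42.0),
    "systolic_bp": (115.0, 12.0, 60.0, 230.0),
    "spo2": (97.5, 1.4, 70.0, 100.0),
    "wbc": (9.5, 2.5, 1.0, 60.0),
    "lactate": (1.3, 0.5, 0.2, 18.0),
    "paco2": (34.0, 4.0, 15.0, 90.0),
    "urine_output": (60.0, 20.0, 5.0, 400.0),
}

#: Location shifts per severity group, natural units.
DEFAULT_SHIFTS = {
    "less_severe": {
        "heart_rate": 8.0, "respiratory_rate": 2.0, "temperature": 0.5,
        "systolic_bp": -2.0, "spo2": -0.5, "wbc": 2.0, "lactate": 0.2,
        "paco2": 0.0, "urine_output": 0.0,
    },
    "complicated": {
        "heart_rate": 18.0, "respiratory_rate": 5.0, "temperature": 0.9,
        "systolic_bp": -10.0, "spo2": -1.5, "wbc": 4.0, "lactate": 0.8,
        "paco2": -2.0, "urine_output": -10.0,
    },
    "smo": {
        "heart_rate": 32.0, "respiratory_rate": 9.0, "temperature": 1.2,
        "systolic_bp": -22.0, "spo2": -4.0, "wbc": 7.0, "lactate": 2.2,
        "paco2": -5.0, "urine_output": -25.0,
    },
}

#: Probability of depressed consciousness per group.
ALTERED_MENTATION_PROB = {"less_severe": 0.02, "complicated": 0.08, "smo": 0.35}

#: Per-(woman, variable) base missingness rates (cohort-CSV variable names).
DEFAULT_MISSINGNESS = {
    "paco2": 0.927,
    "lactate": 0.934,
    "urine_output": 0.678,
    "spo2": 0.668,
    "gcs": 0.504,
    "temperature": 0.504,
    "avpu": 0.504,
    "mental_state_altered": 0.55,
    "wbc": 0.30,
    "respiratory_rate": 0.08,
    "heart_rate": 0.03,
    "systolic_bp": 0.03,
    "diastolic_bp": 0.05,
}

#: Additional independent per-day masking; enrolment day is most complete.
DEFAULT_DAY_EXTRA = {-1: 0.30, 0: 0.0, 1: 0.20}

#: Within-woman day profile: shifts peak on the enrolment day.
DAY_MULTIPLIER = {-1: 0.7, 0: 1.0, 1: 0.85}

MASKABLE_FIELDS = tuple(DEFAULT_MISSINGNESS)


@dataclass
class GeneratorConfig:
    n_women: int = 2560
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {"less_severe": 0.617, "complicated": 0.234, "smo": 0.149}
    )
    severity_effect_scale: float = 1.0
    shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_SHIFTS)
    )
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    day_extra_missingness: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DAY_EXTRA)
    )
    missingness_mode: str = "woman"
    mnar_smo_extra: float = 0.0
    apply_missingness: bool = True
    pregnant_fraction: float = 0.468
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        if set(self.group_proportions) != set(SEVERITIES):
            raise ValueError(f"group_proportions must have keys {SEVERITIES}")
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {total}, not 1")
        if any(p < 0 for p in self.group_proportions.values()):
            raise ValueError("group proportions must be non-negative")
        bad = {k: v for k, v in self.missingness.items() if not 0.0 <= v <= 1.0}
        bad.update({k: v for k, v in self.day_extra_missingness.items() if not 0.0 <= v <= 1.0})
        if bad:
            raise ValueError(f"missingness rates outside [0, 1]: {bad}")
        if self.missingness_mode not in ("woman", "day"):
            raise ValueError(f"unknown missingness_mode {self.missingness_mode!r}")
        if self.severity_effect_scale < 0:
            raise ValueError("severity_effect_scale must be non-negative")
        if not 0.0 <= self.pregnant_fraction <= 1.0:
            raise ValueError("pregnant_fraction outside [0, 1]")


def largest_remainder_allocation(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Deterministic integer allocation: floors, then distribute the remainder
    to the largest fractional parts (ties broken by key order)."""
    keys = [k for k in SEVERITIES if k in proportions]
    quotas = {k: n * proportions[k] for k in keys}
    sizes = {k: int(np.floor(quotas[k])) for k in keys}
    short = n - sum(sizes.values())
    order = sorted(keys, key=lambda k: quotas[k] - sizes[k], reverse=True)
    for k in order[:short]:
        sizes[k] += 1
    return sizes


def _trunc_draw(rng, mean, sd, low, high, size):
    mean = np.asarray(mean, dtype=float)
    a = (low - mean) / sd
    b = (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _avpu_from_gcs(g: int) -> str:
    if g >= 15:
        return "alert"
    if g >= 13:
        return "voice"
    if g >= 9:
        return "pain"
    return "unresponsive"


def generate_cohort(cfg: Optional[GeneratorConfig] = None, **overrides) -> list[PatientRecord]:
    """Generate a seeded synthetic cohort of PatientRecord objects.

    Identical (config, seed) yields an identical cohort. Keyword overrides
    are applied to a default config for convenience
    (``generate_cohort(n_women=500, seed=3)``).
    """
    if cfg is None:
        cfg = GeneratorConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_women

    sizes = largest_remainder_allocation(n, cfg.group_proportions)
    groups = np.repeat(
        np.arange(len(SEVERITIES)), [sizes[k] for k in SEVERITIES]
    )
    groups = groups[rng.permutation(n)]

    scale = cfg.severity_effect_scale
    n_days = len(DAYS)
    day_mult = np.array([DAY_MULTIPLIER[d] for d in DAYS])

    values: dict[str, np.ndarray] = {}
    for var, (mu, sd, lo, hi) in BASELINES.items():
        shift = np.array([cfg.shifts[k].get(var, 0.0) for k in SEVERITIES])
        mean = mu + scale * shift[groups][:, None] * day_mult[None, :]
        values[var] = _trunc_draw(rng, mean, sd, lo, hi, (n, n_days))
    pulse_pressure = _trunc_draw(rng, 43.0, 8.0, 15.0, 90.0, (n, n_days))
    values["diastolic_bp"] = np.maximum(values["systolic_bp"] - pulse_pressure, 25.0)

    altered_prob = np.array([ALTERED_MENTATION_PROB[k] for k in SEVERITIES])
    altered = rng.random(n) < np.minimum(1.0, scale * altered_prob[groups])
    gcs_when_altered = rng.integers(6, 15, size=(n, n_days))

    pregnant = rng.random(n) < cfg.pregnant_fraction
    postabortion = rng.random(n) < 0.15

    # Outcome flags and stays, consistent with each group by construction.
    died = (groups == 2) & (rng.random(n) < 0.12)
    icu = np.where(
        groups == 2, rng.random(n) < 0.50,
        np.where(groups == 1, rng.random(n) < 0.30, False),
    ).astype(bool)
    invasive = np.where(
        groups == 2, rng.random(n) < 0.40,
        np.where(groups == 1, rng.random(n) < 0.55, False),
    ).astype(bool)
    transferred = np.where(
        groups == 2, rng.random(n) < 0.15,
        np.where(groups == 1, rng.random(n) < 0.18, False),
    ).astype(bool)
    none_set = (groups == 1) & ~(icu | invasive | transferred)
    invasive = invasive | none_set
    stay = np.where(
        groups == 2, 3 + rng.poisson(9, n),
        np.where(groups == 1, 2 + rng.poisson(6, n), 1 + rng.poisson(4, n)),
    )
    icu_days = np.where(icu, np.minimum(stay, 1 + rng.poisson(3, n)), 0)

    cohort: list[PatientRecord] = []
    for i in range(n):
        group = SEVERITIES[groups[i]]
        status = (
            "pregnant" if pregnant[i]
            else ("postabortion" if postabortion[i] else "postpartum")
        )
        rec = PatientRecord(
            id=f"W{i:05d}",
            pregnancy_status=status,
            near_miss=bool(groups[i] == 2),
            died=bool(died[i]),
            invasive_procedure=bool(invasive[i]),
            icu_or_hdu_admission=bool(icu[i]),
            transferred=bool(transferred[i]),
            hospital_stay_days=int(stay[i]),
            icu_days=int(icu_days[i]),
        )
        for j, d in enumerate(DAYS):
            if altered[i]:
                gcs = int(gcs_when_altered[i, j])
            else:
                gcs = 15
            rec.add_observation(
                DayObservation(
                    day_index=d,
                    systolic_bp=round(float(values["systolic_bp"][i, j]), 1),
                    diastolic_bp=round(float(values["diastolic_bp"][i, j]), 1),
                    heart_rate=round(float(values["heart_rate"][i, j]), 1),
                    respiratory_rate=round(float(values["respiratory_rate"][i, j]), 1),
                    temperature=round(float(values["temperature"][i, j]), 1),
                    spo2=round(float(values["spo2"][i, j]), 1),
                    gcs=gcs,
                    avpu=_avpu_from_gcs(gcs),
                    wbc=round(float(values["wbc"][i, j]), 1),
                    lactate=round(float(values["lactate"][i, j]), 2),
                    paco2=round(float(values["paco2"][i, j]), 1),
                    urine_output=round(float(values["urine_output"][i, j]), 1),
                    mental_state_altered=bool(altered[i]),
                )
            )
        cohort.append(rec)

    if cfg.apply_missingness:
        cohort = _mask(cohort, cfg, rng)
    return cohort


def apply_missingness(
    cohort: Sequence[PatientRecord],
    rates: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
    day_extra: Optional[dict[int, float]] = None,
    mode: str = "woman",
    mnar_smo_extra: float = 0.0,
) -> list[PatientRecord]:
    """Return a copy of the cohort with values masked at the given rates.

    ``mode="woman"`` (default) masks a variable for a woman on all days at
    once; ``mode="day"`` masks each (woman, day, variable) independently.
    ``day_extra`` adds independent per-day masking on top of either mode.
    ``mnar_smo_extra`` adds masking probability for near-miss/death records
    (stress-test mode, off by default).
    """
    cfg = GeneratorConfig(
        missingness=dict(DEFAULT_MISSINGNESS if rates is None else rates),
        day_extra_missingness={} if day_extra is None else dict(day_extra),
        missingness_mode=mode,
        mnar_smo_extra=mnar_smo_extra,
        seed=0 if seed is None else seed,
    )
    return _mask(cohort, cfg, np.random.default_rng(cfg.seed))


def _mask(cohort: Sequence[PatientRecord], cfg: GeneratorConfig, rng) -> list[PatientRecord]:
    out = copy.deepcopy(list(cohort))
    n = len(out)
    days_present = DAYS
    for var in MASKABLE_FIELDS:
        rate = cfg.missingness.get(var, 0.0)
        if cfg.missingness_mode == "woman":
            woman_mask = rng.random(n) < rate
            mask = np.repeat(woman_mask[:, None], len(days_present), axis=1)
        else:
            mask = rng.random((n, len(days_present))) < rate
        for j, d in enumerate(days_present):
            extra = cfg.day_extra_missingness.get(d, 0.0)
            if extra > 0:
                mask[:, j] |= rng.random(n) < extra
        if cfg.mnar_smo_extra > 0:
            smo_rows = np.array([bool(r.near_miss) or bool(r.died) for r in out])
            mask |= (rng.random((n, len(days_present))) < cfg.mnar_smo_extra) & smo_rows[:, None]
        for i, rec in enumerate(out):
            for j, d in enumerate(days_present):
                if mask[i, j] and d in rec.days:
                    setattr(rec.days[d], var, None)
    return out
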