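"""Diagnostic-accuracy battery for trigger/outcome cross-tabulations.

Per-score 2×2 tables are built complete-case: women for whom a score could
not be computed are excluded from all four cells of that score's table.
Metrics follow the usual definitions — sensitivity TP/(TP+FN), specificity
TN/(TN+FP), LR+ = sens/(1−spec), LR− = (1−sens)/spec, DOR = (TP·TN)/(FP·FN),
Youden's J = sens + spec − 1 — with infinite values flagged and rendered as
the literal string ``INF`` in reports (a likelihood or odds ratio is
impossible to calculate when the relevant error cell is empty).

The DOR confidence interval defaults to the Woolf log-normal method; an
exact conditional-MLE interval is available via ``method="exact"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord, Severity, classify_severity, outcome_flags

__all__ = [
    "ConfusionTable",
    "DiagnosticSummary",
    "build_confusion",
    "confusion_for_score",
    "diagnostic_metrics",
    "dor_confidence_interval",
    "triggered_proportions",
    "performance_report",
    "fmt_pct",
]

INF = float("inf")

#: Subgroup columns of the triggered-proportion report, in presentation order.
SUBGROUPS = ("all", "complicated_or_worse", "smo", "long_stay", "icu_3plus")


def fmt_pct(fraction: float, decimals: int = 1) -> str:
    """Format a proportion as a percentage, half-away-from-zero rounding."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(fraction) * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def _round2(x: float) -> float:
    if math.isinf(x):
        return x
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass
class DiagnosticSummary:
    sensitivity: Optional[float]
    specificity: Optional[float]
    lr_pos: Optional[float]
    lr_neg: Optional[float]
    dor: Optional[float]
    youden_j: Optional[float]
    dor_ci: Optional[tuple[float, float]] = None
    undefined: tuple[str, ...] = ()

    def is_infinite(self, metric: str) -> bool:
        v = getattr(self, metric)
        return v is not None and math.isinf(v)


def build_confusion(
    triggered: Iterable[bool], smo: Iterable[bool]
) -> ConfusionTable:
    """Cross-tabulate aligned trigger results and SMO labels.

    Inputs must already be restricted to women for whom the score was
    computable; every element is a definite boolean.
    """
    trig = list(triggered)
    lab = list(smo)
    if len(trig) != len(lab):
        raise ValueError("triggered and smo sequences differ in length")
    if not trig:
        raise ValueError("empty denominator: no computable women")
    tp = sum(1 for t, s in zip(trig, lab) if t and s)
    fp = sum(1 for t, s in zip(trig, lab) if t and not s)
    fn = sum(1 for t, s in zip(trig, lab) if not t and s)
    tn = sum(1 for t, s in zip(trig, lab) if not t and not s)
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_for_score(
    matrix: pd.DataFrame, labels: dict[str, bool], score: str
) -> ConfusionTable:
    """2×2 table for one score from a long-form trigger matrix."""
    sub = matrix[(matrix["score"] == score) & matrix["computable"]]
    if sub.empty:
        raise ValueError(f"empty denominator: no computable women for {score!r}")
    trig = sub["triggered"].astype(bool).tolist()
    lab = [labels[w] for w in sub["woman_id"]]
    return build_confusion(trig, lab)


def diagnostic_metrics(ct: ConfusionTable) -> DiagnosticSummary:
    """Full metric set for one 2×2 table, with INF/undefined conventions."""
    undefined: list[str] = []
    pos = ct.tp + ct.fn
    neg = ct.tn + ct.fp

    sens = ct.tp / pos if pos else None
    spec = ct.tn / neg if neg else None
    if pos == 0:
        undefined += ["sensitivity", "lr_pos", "lr_neg", "dor", "youden_j"]
    if neg == 0:
        undefined += ["specificity", "lr_pos", "lr_neg", "dor", "youden_j"]

    lr_pos = lr_neg = dor = youden = None
    if sens is not None and spec is not None:
        lr_pos = INF if spec == 1.0 else sens / (1.0 - spec)
        lr_neg = INF if spec == 0.0 else (1.0 - sens) / spec
        dor = INF if ct.fp * ct.fn == 0 else (ct.tp * ct.tn) / (ct.fp * ct.fn)
        youden = sens + spec - 1.0
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        dor=dor,
        youden_j=youden,
        undefined=tuple(dict.fromkeys(undefined)),
    )


def dor_confidence_interval(
    ct: ConfusionTable,
    level: float = 0.95,
    method: str = "woolf",
    continuity: bool = False,
) -> Optional[tuple[float, float]]:
    """Confidence interval for the diagnostic odds ratio.

    ``woolf`` is the log-normal interval exp(ln DOR ± z·√(Σ 1/cell));
    ``exact`` is the conditional-MLE interval of the noncentral
    hypergeometric model. Returns None (undefined) when a cell is zero and
    no continuity correction is requested.
    """
    cells = (ct.tp, ct.fp, ct.fn, ct.tn)
    if method == "exact":
        res = stats.contingency.odds_ratio(
            [[ct.tp, ct.fp], [ct.fn, ct.tn]], kind="conditional"
        )
        ci = res.confidence_interval(confidence_level=level)
        return (float(ci.low), float(ci.high))
    if method != "woolf":
        raise ValueError(f"unknown CI method {method!r}")
    if 0 in cells:
        if not continuity:
            return None
        cells = tuple(c + 0.5 for c in cells)
    tp, fp, fn, tn = cells
    log_dor = math.log((tp * tn) / (fp * fn))
    se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (math.exp(log_dor - z * se), math.exp(log_dor + z * se))


# ---------------------------------------------------------------------------
# Report tables

def _subgroup_membership(cohort: Sequence[PatientRecord]) -> dict[str, dict[str, Optional[bool]]]:
    """Per woman: membership (True/False/None=undefined) in each subgroup."""
    member: dict[str, dict[str, Optional[bool]]] = {}
    for rec in cohort:
        f = outcome_flags(rec)
        member[rec.id] = {
            "all": True,
            "complicated_or_worse": f.is_complicated_or_worse,
            "smo": f.is_smo,
            "long_stay": f.long_stay,
            "icu_3plus": f.icu_3plus,
        }
    return member


def triggered_proportions(
    matrix: pd.DataFrame, cohort: Sequence[PatientRecord]
) -> pd.DataFrame:
    """Triggered/computable proportions per score and outcome subgroup.

    One row per score; cells are ``"n_triggered/n_computable (pct%)"`` with
    subgroup-specific complete-case denominators, or ``"undefined"`` for an
    empty denominator. Numeric companion columns carry the raw counts.
    """
    member = _subgroup_membership(cohort)
    rows = []
    for score, sub in matrix.groupby("score", sort=False):
        comp = sub[sub["computable"]]
        row: dict[str, object] = {"score": score}
        for g in SUBGROUPS:
            in_g = comp[[member[w][g] is True for w in comp["woman_id"]]]
            d = len(in_g)
            n = int(in_g["triggered"].astype(bool).sum()) if d else 0
            row[f"{g}_triggered"] = n
            row[f"{g}_computable"] = d
            row[g] = f"{n}/{d} ({fmt_pct(n / d)}%)" if d else "undefined"
        rows.append(row)
    return pd.DataFrame(rows)


def performance_report(
    matrix: pd.DataFrame,
    cohort: Sequence[PatientRecord],
    stratify_by: Optional[str] = None,
    ci_method: str = "woolf",
) -> pd.DataFrame:
    """Diagnostic-accuracy table: one row per score (× stratum if stratified).

    Outcome is SMO (near miss or death) vs non-SMO among women with a
    computable score. Strata with no SMO (or no non-SMO) women have the
    affected metrics left undefined (NaN) and flagged.
    """
    smo = {r.id: classify_severity(r) is Severity.SMO for r in cohort}
    strata: dict[str, Optional[str]]
    if stratify_by is None:
        strata = {r.id: None for r in cohort}
        levels = [None]
    else:
        if stratify_by != "stratum":
            raise ValueError("only the record's stratum label is available for stratification")
        strata = {r.id: r.stratum for r in cohort}
        levels = sorted({s for s in strata.values() if s is not None})

    rows = []
    for score, sub in matrix.groupby("score", sort=False):
        comp = sub[sub["computable"]]
        for level in levels:
            part = comp if level is None else comp[[strata[w] == level for w in comp["woman_id"]]]
            row: dict[str, object] = {"score": score}
            if level is not None:
                row["stratum"] = level
            if part.empty:
                row.update(
                    dict.fromkeys(
                        ["tp", "fp", "fn", "tn", "sensitivity", "specificity",
                         "lr_pos", "lr_neg", "dor", "youden_j"], np.nan
                    )
                )
                row["undefined"] = "empty denominator"
                rows.append(row)
                continue
            ct = build_confusion(
                part["triggered"].astype(bool).tolist(),
                [smo[w] for w in part["woman_id"]],
            )
            summ = diagnostic_metrics(ct)
            ci = (
                dor_confidence_interval(ct, method=ci_method)
                if "dor" not in summ.undefined
                else None
            )
            row.update(
                tp=ct.tp, fp=ct.fp, fn=ct.fn, tn=ct.tn,
                sensitivity=summ.sensitivity, specificity=summ.specificity,
                lr_pos=summ.lr_pos, lr_neg=summ.lr_neg, dor=summ.dor,
                youden_j=summ.youden_j,
                dor_ci_low=ci[0] if ci else np.nan,
                dor_ci_high=ci[1] if ci else np.nan,
                undefined=";".join(summ.undefined),
            )
            rows.append(row)
    return pd.DataFrame(rows)


def format_performance_report(report: pd.DataFrame) -> pd.DataFrame:
    """Printed-style rendering: percentages to one decimal, ratios to two,
    infinities as the literal string ``INF``."""
    out = report.copy()

    def _ratio(x):
        if pd.isna(x):
            return ""
        if math.isinf(x):
            return "INF"
        return f"{_round2(x):.2f}"

    for col in ("sensitivity", "specificity"):
        out[col] = [("" if pd.isna(v) else fmt_pct(v)) for v in out[col]]
    for col in ("lr_pos", "lr_neg", "dor", "youden_j"):
        if col == "youden_j":
            out[col] = [("" if pd.isna(v) else f"{_round2(v):.2f}") for v in out[col]]
        else:
            out[col] = [_ratio(v) for v in out[col]]
    return out
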