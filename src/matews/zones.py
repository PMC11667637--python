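"""ROC-plane efficacy zones ("zombie plot") for screening scores.

The ROC plane is divided into a boomerang-shaped acceptable region in the
upper-left corner and a mediocre remainder. A score is acceptable for
*ruling out* disease when it is sensitive enough that a negative result is
reassuring (high sensitivity and small negative likelihood ratio), and
acceptable for *ruling in* disease when it is specific enough that a
positive result is convincing (high specificity, optionally a large positive
likelihood ratio). A score satisfying both arms is in the optimal zone;
one satisfying neither is mediocre.

Zone geometry is configuration: the defaults (sens ≥ 0.95 with LR− ≤ 0.25
for the rule-out arm; spec ≥ 0.90 for the rule-in arm) describe a
conventional slender boomerang and can be replaced wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

__all__ = ["ZoneConfig", "DEFAULT_ZONES", "classify_zone", "zone_table", "plot_zones"]

ZONE_LABELS = ("optimal", "rule_in_acceptable", "rule_out_acceptable", "mediocre")


@dataclass(frozen=True)
class ZoneConfig:
    rule_out_min_sens: float = 0.95
    rule_out_max_lr_neg: float = 0.25
    rule_in_min_spec: float = 0.90
    rule_in_min_lr_pos: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("rule_out_min_sens", "rule_in_min_spec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rule_out_max_lr_neg < 0:
            raise ValueError("rule_out_max_lr_neg must be non-negative")


DEFAULT_ZONES = ZoneConfig()


def classify_zone(sens: float, spec: float, cfg: ZoneConfig = DEFAULT_ZONES) -> str:
    """Map a (sensitivity, specificity) point to exactly one efficacy zone."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError(f"sensitivity/specificity outside [0, 1]: ({sens}, {spec})")
    lr_neg = (1.0 - sens) / spec if spec > 0 else float("inf")
    lr_pos = sens / (1.0 - spec) if spec < 1 else float("inf")
    rule_out = sens >= cfg.rule_out_min_sens and lr_neg <= cfg.rule_out_max_lr_neg
    rule_in = spec >= cfg.rule_in_min_spec and (
        cfg.rule_in_min_lr_pos is None or lr_pos >= cfg.rule_in_min_lr_pos
    )
    if rule_in and rule_out:
        return "optimal"
    if rule_out:
        return "rule_out_acceptable"
    if rule_in:
        return "rule_in_acceptable"
    return "mediocre"


def zone_table(report: pd.DataFrame, cfg: ZoneConfig = DEFAULT_ZONES) -> pd.DataFrame:
    """ROC coordinates and zone per score, from a performance report."""
    rows = []
    for _, r in report.iterrows():
        sens, spec = r["sensitivity"], r["specificity"]
        if pd.isna(sens) or pd.isna(spec):
            zone = "undefined"
        else:
            zone = classify_zone(float(sens), float(spec), cfg)
        rows.append(
            {"score": r["score"], "sensitivity": sens, "specificity": spec, "zone": zone}
        )
    return pd.DataFrame(rows)


def plot_zones(table: pd.DataFrame, cfg: ZoneConfig = DEFAULT_ZONES, path=None):
    """Optional thin plotting layer: scores on the ROC plane with the zone
    boundaries sketched. Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.axvspan(1.0 - cfg.rule_in_min_spec, 0.0, color="tab:green", alpha=0.15,
               label="rule-in arm")
    ax.axhspan(cfg.rule_out_min_sens, 1.0, color="tab:blue", alpha=0.15,
               label="rule-out arm")
    for _, r in table.iterrows():
        if pd.isna(r["sensitivity"]) or pd.isna(r["specificity"]):
            continue
        x = 1.0 - float(r["specificity"])
        y = float(r["sensitivity"])
        ax.plot(x, y, "o", color="tab:red", ms=4)
        ax.annotate(str(r["score"]), (x, y), fontsize=6, xytext=(3, 3),
                    textcoords="offset points")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right", fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
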