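#!/usr/bin/env python
"""Triggered-proportion and diagnostic-accuracy tables for a cohort CSV.

Writes ``table1.csv`` — trigger proportions per score within each outcome
subgroup (all women, complicated or worse, severe maternal outcome, stays
over a week, ICU ≥ 3 days) — and ``table2.csv`` — sensitivity, specificity,
likelihood ratios, diagnostic odds ratio (Woolf 95% CI) and Youden's J per
score for discriminating SMO, complete-case per score. Prints the most
sensitive and most specific systems.
"""

import argparse
from pathlib import Path

import pandas as pd

from matews.cohort import read_cohort
from matews.diagnostics import (
    format_performance_report,
    performance_report,
    triggered_proportions,
)
from matews.scores import load_score_definitions, score_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    registry = load_score_definitions()
    matrix = score_cohort(registry, cohort)

    t1 = triggered_proportions(matrix, cohort)
    report = performance_report(matrix, cohort)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    t1.to_csv(args.out_dir / "table1.csv", index=False)
    format_performance_report(report).to_csv(args.out_dir / "table2.csv", index=False)

    ok = report.dropna(subset=["sensitivity", "specificity"])
    best_sens = ok.sort_values("sensitivity", ascending=False).head(3)
    best_spec = ok.sort_values("specificity", ascending=False).head(3)
    print("most sensitive for SMO:")
    for _, r in best_sens.iterrows():
        print(f"  {r.score:16s} sens {100 * r.sensitivity:5.1f}%  spec {100 * r.specificity:5.1f}%")
    print("most specific for SMO:")
    for _, r in best_spec.iterrows():
        print(f"  {r.score:16s} sens {100 * r.sensitivity:5.1f}%  spec {100 * r.specificity:5.1f}%")


if __name__ == "__main__":
    main()
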