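#!/usr/bin/env python
"""Profile missing data and per-score computability for a cohort CSV.

Writes ``missingness.csv`` (variable × day percentages) and
``computability.csv`` (evaluable women per score). The headline finding on
the default cohort mirrors the study setting: blood-gas and lactate values
are almost never recorded (>90% missing), temperature and coma score are
absent for about half the women, so most scores are computable only for a
fraction of the cohort.
"""

import argparse
from pathlib import Path

from matews.cohort import read_cohort
from matews.missingness import computability_matrix, missing_rates
from matews.scores import load_score_definitions


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    registry = load_score_definitions()

    rates = missing_rates(cohort)
    rates["pct_missing"] = rates["pct_missing"].round(1)
    comp = computability_matrix(registry, cohort)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    rates.to_csv(args.out_dir / "missingness.csv", index=False)
    comp.to_csv(args.out_dir / "computability.csv", index=False)

    overall = rates[rates.day == "overall"].sort_values("pct_missing", ascending=False)
    print("most-missing variables (never recorded for the woman):")
    for _, row in overall.head(6).iterrows():
        print(f"  {row.variable:16s} {row.pct_missing:5.1f}%")
    worst = comp.sort_values("n_computable").head(3)
    print("least computable scores:")
    for _, row in worst.iterrows():
        print(f"  {row.score:16s} {row.n_computable}/{row.n_cohort}")


if __name__ == "__main__":
    main()
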