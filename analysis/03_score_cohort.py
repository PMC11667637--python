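#!/usr/bin/env python
"""Evaluate the 21 early warning systems on a cohort CSV.

Writes the long-form trigger matrix (``trigger_matrix.csv``: one row per
woman × score with computability, trigger status, value and triggering day)
and prints the most- and least-triggered systems among evaluable women.
"""

import argparse
from pathlib import Path

from matews.cohort import read_cohort
from matews.scores import load_score_definitions, score_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    registry = load_score_definitions()
    matrix = score_cohort(registry, cohort)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(args.out_dir / "trigger_matrix.csv", index=False)

    comp = matrix[matrix.computable]
    summary = comp.groupby("score").agg(
        n=("triggered", "size"), triggered=("triggered", "sum")
    )
    summary["pct"] = 100 * summary.triggered / summary.n
    summary = summary.sort_values("pct", ascending=False)
    print(f"scored {len(cohort)} women with rule set {registry.sha256[:12]}")
    print("trigger rates among evaluable women (top/bottom 3):")
    shown = list(summary.head(3).itertuples()) + list(summary.tail(3).itertuples())
    for row in shown:
        print(f"  {row.Index:16s} {int(row.triggered):4d}/{int(row.n):4d}  ({row.pct:.1f}%)")


if __name__ == "__main__":
    main()
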