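#!/usr/bin/env python
"""Generate the default synthetic cohort and report its structure.

Writes ``cohort.csv`` (one row per woman-day) to the output directory and
prints the severity-group sizes, which at the default n = 2560 and mix
(61.7 / 23.4 / 14.9%) come out to exactly 1580 / 599 / 381 by deterministic
largest-remainder allocation.
"""

import argparse
from collections import Counter
from pathlib import Path

from matews.cohort import classify_severity, write_cohort
from matews.synthetic import GeneratorConfig, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=2560)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = generate_cohort(GeneratorConfig(n_women=args.n, seed=args.seed))
    counts = Counter(classify_severity(r).value for r in cohort)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    out = args.out_dir / "cohort.csv"
    write_cohort(cohort, out)

    print(f"cohort of {len(cohort)} women written to {out}")
    for group in ("less_severe", "complicated", "smo"):
        n = counts[group]
        print(f"  {group:12s} {n:5d}  ({100 * n / len(cohort):.1f}%)")


if __name__ == "__main__":
    main()
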