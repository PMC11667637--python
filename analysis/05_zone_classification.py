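#!/usr/bin/env python
"""Place each score on the ROC plane and classify its efficacy zone.

Writes ``zones.csv`` (score, sensitivity, specificity, zone) and an optional
zone-overlay figure. With the default boundaries a score is acceptable for
ruling out SMO when sens ≥ 0.95 with LR− ≤ 0.25, acceptable for ruling in
when spec ≥ 0.90, optimal when both, mediocre otherwise.
"""

import argparse
from pathlib import Path

from matews.cohort import read_cohort
from matews.diagnostics import performance_report
from matews.scores import load_score_definitions, score_cohort
from matews.zones import plot_zones, zone_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--plot", type=Path, default=None,
                    help="optional PNG path for the zone overlay")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    registry = load_score_definitions()
    matrix = score_cohort(registry, cohort)
    report = performance_report(matrix, cohort)
    zones = zone_table(report)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    zones.to_csv(args.out_dir / "zones.csv", index=False)
    if args.plot is not None:
        plot_zones(zones, path=args.plot)

    for zone in ("optimal", "rule_out_acceptable", "rule_in_acceptable", "mediocre"):
        members = zones[zones.zone == zone].score.tolist()
        print(f"{zone:20s} {len(members):2d}  {', '.join(members[:6])}"
              + (" ..." if len(members) > 6 else ""))


if __name__ == "__main__":
    main()
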