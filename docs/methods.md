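# Methods

This note documents the models and procedures implemented in `matews`, the
parameters that matter, and the design decisions taken where the underlying
study description left the design open.

## Severity classification

Women with suspected or confirmed infection are partitioned by worst status
during the hospital stay:

1. **SMO** — any WHO maternal near-miss criterion, or death. The near-miss
   determination is carried as a single pre-computed boolean on the record,
   because analysis datasets in this field ship the flag rather than the raw
   organ-dysfunction panel; the classifier does not re-derive it from labs.
2. **Complicated** — no SMO, but an invasive procedure to treat the
   infection source (aspiration, curettage, debridement, drainage,
   laparotomy…), ICU/high-dependency admission, or transfer to another
   facility.
3. **Less severe** — the remainder.

Precedence is strict (SMO dominates), so the three groups partition any
cohort and flipping `near_miss` on can never demote a woman. Missing outcome
flags are treated as `False` — absence of evidence of a complication — with
a warning at CSV-read time; the alternative (dropping such women) would
silently change denominators.

Outcome strata for the trigger-proportion table: *complicated-or-worse*
(groups 1+2), *long stay* (> 7 days), *ICU ≥ 3 days*. The ICU stratum uses
≥ 3 (the tabulated convention) rather than the looser prose reading
"over three days"; a record with a missing duration is excluded from that
stratum's denominator rather than counted as a zero.

## The rule engine

A score definition is pure data: threshold bands (`variable`, comparator
among `<, ≤, >, ≥, inside, outside`, bounds, and a weight or a yellow/red
zone label) plus one aggregation rule:

- `count_ge_k` — count distinct satisfied criteria (bands may share a
  `criterion` key so "temperature high *or* low" counts once), trigger at k;
- `points_ge_k` — sum band weights, trigger at k points;
- `any_red` / `red1_or_yellow2` — chart logic (value = 2·reds + yellows);
- `ratio_ge` — shock-index family, trigger when the ratio reaches the
  cut-off (whether the boundary itself triggers is config, not code).

Derived variables: `map` = (SBP + 2·DBP)/3; `gcs_effective` (GCS, else an
AVPU→GCS mapping alert/voice/pain/unresponsive → 15/12/9/3);
`consciousness_abnormal` (altered-mentation flag, else AVPU ≠ alert, else
GCS < 15 — the obstetric qSOFA variants chart "altered mentation" directly);
`avpu_level` for charts that grade consciousness in zones.

**Complete-data rule.** A day is usable only if every variable the score
needs is present that day; there is no cross-day imputation. A woman is
evaluable if at least one day is usable, and she is *triggered* if any
usable day triggers (earliest triggering day recorded; the reported numeric
value is the maximum across usable days). OR-aggregation over days matches
screening intent — a woman flagged on any assessed day was flagged.
Pregnancy-specific tools (MEWT, OmqSOFA, qSOFA-P, EMIP, the pregnancy NICE
tool) and the postpartum/post-abortion NICE tool return
"inapplicable" (non-evaluable) outside their population.

**Cut-offs are configuration.** The 21 tools' variable compositions follow
the published score families, but many of the original charts exist in
several published versions. The bundled defaults transcribe the public
originals where unambiguous (qSOFA: RR ≥ 22, SBP ≤ 100, GCS < 15, trigger
≥ 2; SIRS: temp > 38/< 36 °C, HR > 90, RR > 20 or PaCO₂ < 32 mmHg, WBC
> 12/< 4 ×10⁹/L, trigger ≥ 2; SI = HR/SBP; MSI = HR/MAP) and otherwise use
clinically conventional bounds for each family, chosen once under two
constraints: a textbook-normal adult record must trigger nothing, and
monotone worsening of any vital must never lower a score. The six MEOWS
variants are distinct published chart versions and differ in variable sets
and bounds. The MSI default trigger is the upper abnormal bound of its
original publication (ratio ≥ 1.3). Every number lives in
`src/matews/data/ews_definitions.yaml`; the loader's SHA-256 fingerprint is
written into every report manifest so a result always cites its exact rule
set. Correctness of the *engine* is established independently of these
choices: a test drives it against 21 hand-coded reference implementations on
grids straddling every cut-off.

## Diagnostic accuracy

Per score, trigger status is cross-tabulated against SMO among evaluable
women (complete-case per score — mirroring per-score denominators in this
literature). Metrics: sensitivity, specificity, LR± , DOR, Youden's J.
Conventions:

- `INF` when specificity is 1 (LR+, and DOR when FP·FN = 0) — rendered as
  the literal string in CSV reports;
- percentages formatted to one decimal, round-half-away-from-zero; ratios
  to two decimals;
- DOR CI: Woolf log-normal `exp(ln DOR ± z·√(1/TP+1/FP+1/FN+1/TN))` by
  default, undefined on a zero cell unless the 0.5 continuity correction is
  requested; a conditional-MLE exact interval
  (`scipy.stats.contingency.odds_ratio`) is selectable. Published tables in
  this area do not always state their CI method, and at least one printed
  interval is consistent with neither — CIs are therefore reported but not
  treated as anchor values anywhere in the tests.
- Stratified analysis partitions by the record's free-form `stratum` label
  (e.g. an income grouping); a stratum with no SMO women has the affected
  metrics flagged undefined rather than zeroed.

Note for users comparing against published two-table layouts: trigger-count
tables and accuracy tables in the source literature are not always mutually
consistent (different analysis subsets); the test-suite anchors use only the
self-consistent rows.

## ROC efficacy zones

The plane is split by two arms into four zones: rule-out-acceptable
(sens ≥ 0.95 **and** LR− ≤ 0.25), rule-in-acceptable (spec ≥ 0.90,
optionally also a minimum LR+), optimal (both), mediocre (neither).
The boundaries are configuration; the defaults are calibrated to the
conventional "slender boomerang in the upper-left corner" reading and make
the expected qualitative placements hold (a highly sensitive tool with
adequate LR− rules out; a maximally specific tool rules in; a tool with
95%+ sensitivity but LR− ≈ 0.7 is mediocre). Zone membership is total and
exclusive, and monotone: raising sensitivity at fixed specificity can only
promote a point along the rule-out arm, never demote it.

## Synthetic cohort generator

The generator's defaults *are* the study conditions the package targets:

- **n = 2560**, severity mix 0.617/0.234/0.149, allocated by deterministic
  largest-remainder rounding (so the default size yields exactly
  1580/599/381 — multinomial sampling would only approximate the published
  structure), then shuffled by seed.
- **Three days per woman** (−1, 0, +1). Vitals are truncated normals around
  healthy baselines (HR 84±11, RR 17±2.5, T 37±0.45 °C, SBP 115±12 with
  pulse pressure 43±8 giving DBP, SpO₂ 97.5±1.4, WBC 9.5±2.5, lactate
  1.3±0.5, PaCO₂ 34±4, urine 60±20) with additive group shifts (e.g. SMO:
  HR +32, RR +9, T +1.2 °C, SBP −22, lactate +2.2) scaled by a day profile
  peaking at enrolment (×0.7/×1.0/×0.85). Depressed consciousness occurs
  with group-dependent probability (2%/8%/35%), drawing GCS 6–14 and the
  matching AVPU level. A single `severity_effect_scale` knob multiplies all
  shifts; empirical score sensitivity is non-decreasing in it (verified at
  n = 5000 over 3 seeds).
- **Outcome flags** are drawn consistently with the group (SMO ⇒ near miss,
  12% death; complicated ⇒ at least one of procedure 55%/ICU 30%/transfer
  18%; less severe ⇒ none), so the severity classifier recovers the
  configured group sizes exactly. Stays are Poisson with group-dependent
  means; ICU days never exceed the stay.
- **Missingness** is MCAR. The default mode masks per (woman, variable)
  across all three days at the published per-variable rates (PaCO₂ 0.927,
  lactate 0.934, urine output 0.678, SpO₂ 0.668, GCS and temperature 0.504;
  the unlisted variables use the package's own choices — pulse/pressure
  nearly complete, WBC 0.30), because the published accounting counts a
  variable missing when it was never recorded for the woman, and because
  per-score evaluable fractions then follow the simple product of
  per-variable completeness. Additive per-day masking (30% day −1, 20%
  day +1) makes the enrolment day the most complete, as observed. An
  independent per-(woman, day) mode and a severity-dependent (MNAR) stress
  mode exist but are off by default.
- **Not emulated:** inter-variable correlation beyond the group conditioning,
  facility/country clustering, newborn outcomes, within-woman day-to-day
  autocorrelation. Passing tests on generated data therefore demonstrate
  correctness of the *pipeline under the published marginal structure*, not
  clinical performance of any score on real women — on real data the
  missingness is informative and vitals are correlated, which can move every
  denominator and accuracy figure.

Byte-identical reproducibility: all randomness flows from one
`numpy.random.Generator` seeded by the config, and serialising the same
(config, seed) twice yields identical CSV bytes.

## Marker-combination ML protocol

Features are routine day-0 markers; the outcome is SMO. The protocol: 80/20
split with outcome prevalence balanced (proportional per-class allocation
handles degenerate single-member classes), marker ranking by exact
information gain in bits (labels vs equal-frequency-binned features, 10
bins, complete-case per feature, alphabetical tie-break), nested prefix
subsets, stratified k-fold cross-validation (k = 10 by default; folds with
a single class are skipped with a warning and counted in the output), two
statistical classifiers — Gaussian naive Bayes and logistic regression —
and fold-averaged sensitivity, specificity, FPR = 1 − spec, FNR = 1 − sens
(identities exact by construction) and Mann–Whitney AUROC (ties = ½;
verified against brute-force pair counting and an independent library
implementation). Information gain is computed in-package because the
established libraries expose only kNN-estimated mutual information, which
is not the bits-valued quantity attribute-selection rankings use. The "best
classifier" nomination uses configurable cut-offs (defaults: spec ≥ 0.90
and AUROC ≥ 0.75). The protocol deliberately omits the larger classifier
zoo of some published workflows — the statistical pair is the part credited
with the best metrics, and further classifiers are pluggable.

## Problem sizes and tolerances

Default analyses run at the study size (n = 2560); the two Monte-Carlo
monotonicity properties (sensitivity and AUROC vs effect size) use n = 5000
with 3 seeds and a 0.05/0.02 Monte-Carlo allowance. Binomial checks on
recovered missingness rates use 3σ bands. Metric identities are asserted to
1e−9 relative (DOR = LR+/LR−) or 1e−12 absolute (J). Percent formatting is
decimal-based (half-away-from-zero) to avoid float round-half-even
surprises at printed precision.

## Known limitations

- Default cut-offs for chart-family scores are package transcriptions of
  published families, not a certified copy of any one hospital's chart;
  audits should review the YAML, not the code.
- Complete-case evaluation means per-score denominators differ — cross-score
  comparisons inherit that non-overlap, as in the source literature.
- The generator's conditional-independence assumption typically makes
  marker combinations *more* separable than real data; ML metrics on
  synthetic cohorts are upper bounds of a sort and are not anchored to any
  published range.
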