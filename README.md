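# matews — maternal early-warning-system evaluation

`matews` is an analysis toolkit for asking a practical obstetric question:
**how well do bedside early warning systems (EWS) identify women with
suspected or confirmed infection who go on to a sepsis-related severe
maternal outcome (SMO)?** An EWS is a track-and-trigger rule set over vital
signs and labs — it "triggers" when one or more criteria leave their normal
range. An SMO is a WHO maternal near miss (life-threatening organ
dysfunction) or a maternal death, the standard proxy for maternal sepsis in
cohorts of infected women.

The package targets the setting of the WHO Global Maternal Sepsis Study
(GLOSS, 2017): 2560 women from 46 countries with infection, observed on the
day before, the day of, and the day after enrolment, partitioned into three
severity groups (61.7% less severe infection, 23.4% infection with
complications, 14.9% infection-related SMO). Because the individual-level
data are available only under a data-sharing agreement, the package ships a
seeded synthetic-cohort generator that emulates the study's structure —
severity mix, three-day observations, and the heavy real-world missingness
(lactate ≈ 93% missing, blood gas ≈ 93%, urine output ≈ 68%, pulse oximetry
≈ 67%, temperature and coma score ≈ 50%) — so the entire battery runs
end-to-end without any download.

## What it computes

- **Rule engine** (`matews.scores`): 21 EWS encoded declaratively as
  threshold bands + aggregation rules (counting criteria, weighted points,
  one-red-or-two-yellow chart logic, and shock-index ratios), covering the
  obstetric non-sepsis tools (FAST-M and its red-flag variant, IMEWS, six
  MEOWS charts, MEWT, SOS), obstetric sepsis tools (NICE risk stratification
  for pregnancy and for postpartum/post-abortion, mSIRS, OmqSOFA, qSOFA-P,
  EMIP) and generic scores (qSOFA, SIRS, SI = HR/SBP, MSI = HR/MAP with
  MAP = (SBP + 2·DBP)/3). All cut-offs are editable YAML; the loader
  fingerprints the rule set (SHA-256) so results cite exact rules. Scores
  are computed complete-case per day and a woman is "triggered" if any
  observed day triggers.
- **Severity classification** (`matews.cohort`): near miss or death → SMO;
  otherwise invasive source-control procedure, ICU/high-dependency
  admission, or transfer → complicated; remainder → less severe.
- **Diagnostic accuracy** (`matews.diagnostics`): per score, the 2×2 table
  of trigger vs SMO among evaluable women, with sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP), LR+ = sens/(1−spec), LR− = (1−sens)/spec,
  DOR = (TP·TN)/(FP·FN) with a Woolf log-normal 95% CI (conditional-MLE
  exact interval optional), Youden's J = sens + spec − 1, and the table
  convention that a ratio whose error cell is empty prints as `INF`.
- **ROC efficacy zones** (`matews.zones`): the "zombie plot" partition of
  the ROC plane into rule-out-acceptable (sens ≥ 0.95 and LR− ≤ 0.25),
  rule-in-acceptable (spec ≥ 0.90), optimal (both) and mediocre zones.
- **Missingness accounting** (`matews.missingness`): per-variable, per-day
  and per-woman missing percentages, and per-score computable denominators.
- **Marker-combination ML** (`matews.ml`): 80/20 outcome-balanced split,
  information-gain marker ranking, nested feature subsets, cross-validated
  naive Bayes and logistic regression, with fold-averaged sensitivity,
  specificity, FPR, FNR and rank-based (Mann–Whitney) AUROC.

## Worked example

The published per-group counts for the Modified Shock Index are enough to
rebuild its full accuracy row: 2114 evaluable women of whom 1994 triggered,
and 327 women with SMO of whom 313 triggered, give TP = 313, FP = 1681,
FN = 14, TN = 106:

```python
>>> from matews import ConfusionTable, diagnostic_metrics, dor_confidence_interval
>>> ct = ConfusionTable(tp=313, fp=1681, fn=14, tn=106)
>>> s = diagnostic_metrics(ct)
>>> print(f"sens {s.sensitivity:.1%}  spec {s.specificity:.1%}  "
...       f"LR+ {s.lr_pos:.2f}  LR- {s.lr_neg:.2f}  DOR {s.dor:.2f}  J {s.youden_j:.2f}")
sens 95.7%  spec 5.9%  LR+ 1.02  LR- 0.72  DOR 1.41  J 0.02
>>> [round(x, 2) for x in dor_confidence_interval(ct)]
[0.8, 2.49]
```

A sensitivity of 95.7% with specificity of 5.9% is the signature of an
over-triggering score: it flags nearly every infected woman, so a trigger
carries almost no information (LR+ ≈ 1, J ≈ 0) — the MSI lands in the
*mediocre* ROC zone despite its sensitivity.

The full pipeline runs from the command line:

```
matews simulate --n 2560 --seed 17 --out cohort.csv
matews all --cohort cohort.csv --out-dir reports --seed 17
```

or as a sequence of narrative drivers:

```
python analysis/01_simulate_cohort.py      # cohort.csv; groups 1580/599/381
python analysis/02_profile_missingness.py  # missingness.csv, computability.csv
python analysis/03_score_cohort.py         # trigger_matrix.csv
python analysis/04_diagnostic_accuracy.py  # table1.csv, table2.csv
python analysis/05_zone_classification.py  # zones.csv
python analysis/06_ml_markers.py           # ml_metrics.csv
```

On the default synthetic cohort the first driver prints:

```
cohort of 2560 women written to results/cohort.csv
  less_severe   1580  (61.7%)
  complicated    599  (23.4%)
  smo            381  (14.9%)
```

## Layout

```
src/matews/         library: cohort model, rule engine + bundled YAML rules,
                    diagnostics, zones, missingness, ML, generator, pipeline, CLI
analysis/           numbered narrative drivers over the library
scripts/acceptance.py   headline-quantity reproduction
tests/              pytest suite (unit, property-based, end-to-end)
docs/methods.md     methods note: models, parameters, design choices, limits
```
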