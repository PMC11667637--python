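"""Diagnostic-accuracy metrics: worked examples from the published study's
self-consistent counts, infinite-value conventions, and brute-force
property checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matews.cohort import classify_severity, Severity
from matews.diagnostics import (
    ConfusionTable,
    build_confusion,
    confusion_for_score,
    diagnostic_metrics,
    dor_confidence_interval,
    fmt_pct,
    format_performance_report,
    performance_report,
    triggered_proportions,
)
from matews.scores import load_score_definitions, score_cohort

from conftest import make_record

#: The modified shock index 2×2 reconstructed from the published per-group
#: counts: 2114 evaluable women, 1994 triggered overall; 327 SMO, 313 triggered.
MSI_CT = ConfusionTable(tp=313, fp=1681, fn=14, tn=106)


class TestBuildConfusion:
    def test_enumeration(self):
        ct = build_confusion([True, True, False], [True, False, False])
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (1, 1, 0, 1)

    def test_study_shaped_msi_counts(self):
        """2114 computable of whom 1994 triggered; 313 of 327 SMO triggered."""
        triggered = [True] * 313 + [False] * 14 + [True] * 1681 + [False] * 106
        smo = [True] * 327 + [False] * 1787
        ct = build_confusion(triggered, smo)
        assert ct == MSI_CT
        assert ct.total == 2114

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError, match="empty denominator"):
            build_confusion([], [])


class TestDiagnosticMetrics:
    def test_msi_row_at_printed_rounding(self):
        s = diagnostic_metrics(MSI_CT)
        assert fmt_pct(s.sensitivity) == "95.7"
        assert fmt_pct(s.specificity) == "5.9"
        assert round(s.lr_pos, 2) == 1.02
        assert round(s.lr_neg, 2) == 0.72
        assert round(s.dor, 2) == 1.41
        assert round(s.youden_j, 2) == 0.02

    def test_perfect_test_gives_infinite_dor(self):
        s = diagnostic_metrics(ConfusionTable(10, 0, 0, 10))
        assert s.sensitivity == 1.0 and s.specificity == 1.0
        assert math.isinf(s.dor) and math.isinf(s.lr_pos)

    @pytest.mark.parametrize(
        "tp, pos_total, printed",
        [
            (161, 256, "62.9"),   # SIRS
            (116, 130, "89.2"),   # mSIRS
            (156, 177, "88.1"),   # EMIP
            (89, 165, "53.9"),    # FAST-M
            (249, 303, "82.2"),   # IMEWS
        ],
    )
    def test_published_smo_sensitivities(self, tp, pos_total, printed):
        s = diagnostic_metrics(ConfusionTable(tp=tp, fp=1, fn=pos_total - tp, tn=1))
        assert fmt_pct(s.sensitivity) == printed

    def test_undefined_when_no_positives(self):
        s = diagnostic_metrics(ConfusionTable(0, 5, 0, 5))
        assert s.sensitivity is None and "sensitivity" in s.undefined


class TestDorCI:
    def test_woolf_interval_on_msi_counts(self):
        low, high = dor_confidence_interval(MSI_CT)
        assert (round(low, 2), round(high, 2)) == (0.80, 2.49)

    def test_balanced_table_symmetric_on_log_scale(self):
        low, high = dor_confidence_interval(ConfusionTable(10, 10, 10, 10))
        assert math.log(low) == pytest.approx(-math.log(high), abs=1e-9)

    def test_zero_cell_undefined_without_correction(self):
        assert dor_confidence_interval(ConfusionTable(10, 0, 3, 7)) is None
        assert dor_confidence_interval(ConfusionTable(10, 0, 3, 7), continuity=True) is not None

    def test_exact_method_brackets_conditional_estimate(self):
        low, high = dor_confidence_interval(ConfusionTable(20, 10, 5, 30), method="exact")
        assert low < (20 * 30) / (10 * 5) < high


@given(
    triggers=st.lists(st.booleans(), min_size=2, max_size=50),
    labels_seed=st.integers(0, 2**16),
)
@settings(derandomize=True, max_examples=60)
def test_metric_identities_against_brute_force(triggers, labels_seed):
    """On random small cohorts: cells reproduce raw counting, J = sens+spec−1
    exactly, and DOR = LR+/LR− when everything is finite."""
    rng = np.random.default_rng(labels_seed)
    labels = list(rng.random(len(triggers)) < 0.5)
    if not (any(labels) and not all(labels)):
        labels[0], labels[-1] = True, False
    ct = build_confusion(triggers, labels)
    # brute-force recount
    assert ct.tp == sum(t and l for t, l in zip(triggers, labels))
    assert ct.tp + ct.fn == sum(labels)
    assert ct.total == len(triggers)
    s = diagnostic_metrics(ct)
    assert s.youden_j == pytest.approx(s.sensitivity + s.specificity - 1.0, abs=1e-12)
    if all(c > 0 for c in (ct.tp, ct.fp, ct.fn, ct.tn)):
        assert s.dor == pytest.approx(s.lr_pos / s.lr_neg, rel=1e-9)


def _toy_cohort_and_matrix():
    registry = load_score_definitions()
    cohort = [
        make_record("S1", "pregnant", near_miss=True, hospital_stay_days=12, icu_days=4,
                    obs_overrides=dict(heart_rate=150, systolic_bp=80, diastolic_bp=50)),
        make_record("S2", "pregnant", near_miss=True, hospital_stay_days=3, icu_days=0),
        make_record("N1", "pregnant", hospital_stay_days=9, icu_days=0),
        make_record("N2", "pregnant", invasive_procedure=True, hospital_stay_days=2,
                    icu_days=0,
                    obs_overrides=dict(heart_rate=140, systolic_bp=90, diastolic_bp=60)),
    ]
    return cohort, score_cohort(registry, cohort)


class TestReports:
    def test_triggered_proportions_formatting(self):
        cohort, matrix = _toy_cohort_and_matrix()
        t1 = triggered_proportions(matrix, cohort)
        msi = t1[t1.score == "MSI"].iloc[0]
        # S1 triggers (150/60 = 2.5), S2/N1 normal, N2 = 140/70 = 2.0
        assert msi["all"] == "2/4 (50.0%)"
        assert msi["smo"] == "1/2 (50.0%)"
        assert msi["icu_3plus"] == "1/1 (100.0%)"

    def test_row_order_invariance(self):
        cohort, _ = _toy_cohort_and_matrix()
        registry = load_score_definitions()
        fwd = performance_report(score_cohort(registry, cohort), cohort)
        rev = performance_report(score_cohort(registry, cohort[::-1]), cohort[::-1])
        f = fwd[fwd.score == "MSI"].iloc[0]
        r = rev[rev.score == "MSI"].iloc[0]
        assert (f.tp, f.fp, f.fn, f.tn) == (r.tp, r.fp, r.fn, r.tn)

    def test_single_stratum_equals_unstratified(self):
        cohort, matrix = _toy_cohort_and_matrix()
        for rec in cohort:
            rec.stratum = "only"
        plain = performance_report(matrix, cohort)
        strat = performance_report(matrix, cohort, stratify_by="stratum")
        for col in ("tp", "fp", "fn", "tn"):
            assert list(plain[col].fillna(-1)) == list(strat[col].fillna(-1))

    def test_pooled_cells_reproduce_overall_dor(self):
        cohort, matrix = _toy_cohort_and_matrix()
        for i, rec in enumerate(cohort):
            rec.stratum = "A" if i % 2 else "B"
        strat = performance_report(matrix, cohort, stratify_by="stratum")
        plain = performance_report(matrix, cohort)
        msi = strat[strat.score == "MSI"]
        pooled = ConfusionTable(
            int(msi.tp.sum()), int(msi.fp.sum()), int(msi.fn.sum()), int(msi.tn.sum())
        )
        overall = plain[plain.score == "MSI"].iloc[0]
        assert (pooled.tp, pooled.fp, pooled.fn, pooled.tn) == (
            overall.tp, overall.fp, overall.fn, overall.tn
        )

    def test_inf_rendered_literally(self):
        cohort, matrix = _toy_cohort_and_matrix()
        report = performance_report(matrix, cohort)
        # build a perfect-specificity row synthetically via formatting
        report.loc[report.index[0], "lr_pos"] = float("inf")
        rendered = format_performance_report(report)
        assert rendered.iloc[0]["lr_pos"] == "INF"

    def test_smo_positives_conserved(self, default_cohort, default_matrix):
        labels = {r.id: classify_severity(r) is Severity.SMO for r in default_cohort}
        ct = confusion_for_score(default_matrix, labels, "qSOFA")
        comp = default_matrix[(default_matrix.score == "qSOFA") & default_matrix.computable]
        n_smo = sum(labels[w] for w in comp["woman_id"])
        assert ct.tp + ct.fn == n_smo
        assert ct.total == len(comp)
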