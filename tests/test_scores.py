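"""Rule-engine behaviour: config loading, day aggregation, and equivalence
with independently hand-coded per-score references on cut-off-straddling
grids."""

import itertools
import random

import pytest

from matews.cohort import DayObservation
from matews.scores import (
    SCORE_NAMES_21,
    ScoreConfigError,
    compute_map,
    evaluate_score,
    evaluate_score_on_day,
    load_score_definitions,
    score_cohort,
)

from conftest import NORMAL_VALUES, make_obs, make_record
from score_oracles import ORACLES


class TestRegistry:
    def test_default_registry_has_the_21_systems(self, registry):
        assert set(registry) == set(SCORE_NAMES_21)
        assert len(registry.sha256) == 64

    def test_subset_config_allowed(self, registry):
        import yaml

        from importlib import resources

        doc = yaml.safe_load(
            resources.files("matews.data").joinpath("ews_definitions.yaml").read_text()
        )
        doc["scores"] = [s for s in doc["scores"] if s["name"] != "MSI"]
        sub = load_score_definitions(yaml.safe_dump(doc))
        assert len(sub) == 20 and "MSI" not in sub

    def test_unknown_variable_rejected(self):
        cfg = """
scores:
- name: bogus
  aggregation: {type: count_ge_k, k: 1}
  bands:
  - {variable: foo, comparator: ge, bound: 1}
"""
        with pytest.raises(ScoreConfigError, match="foo"):
            load_score_definitions(cfg)

    def test_duplicate_name_rejected(self):
        cfg = """
scores:
- name: twin
  aggregation: {type: count_ge_k, k: 1}
  bands: [{variable: heart_rate, comparator: ge, bound: 100}]
- name: twin
  aggregation: {type: count_ge_k, k: 1}
  bands: [{variable: heart_rate, comparator: ge, bound: 100}]
"""
        with pytest.raises(ScoreConfigError, match="duplicate"):
            load_score_definitions(cfg)

    def test_malformed_band_rejected(self):
        cfg = """
scores:
- name: broken
  aggregation: {type: count_ge_k, k: 1}
  bands: [{variable: heart_rate, comparator: between, bound: 100}]
"""
        with pytest.raises(ScoreConfigError, match="comparator"):
            load_score_definitions(cfg)


class TestMap:
    @pytest.mark.parametrize(
        "sbp, dbp, expected",
        [(80, 50, 60.0), (100, 100, 100.0), (120, 80, pytest.approx(93.3333, abs=1e-3))],
    )
    def test_mean_arterial_pressure(self, sbp, dbp, expected):
        assert compute_map(sbp, dbp) == expected

    def test_inverted_pressures_rejected(self):
        with pytest.raises(ValueError):
            compute_map(80, 90)


class TestSingleDayEvaluation:
    def test_qsofa_two_points_triggers(self, registry):
        obs = make_obs(respiratory_rate=24, systolic_bp=95, gcs=15)
        r = evaluate_score_on_day(registry["qSOFA"], obs)
        assert r.computable and r.numeric_value == 2 and r.triggered

    def test_sirs_all_normal_scores_zero(self, registry):
        obs = make_obs(temperature=36.8, heart_rate=80, respiratory_rate=14,
                       wbc=8, paco2=40)
        r = evaluate_score_on_day(registry["SIRS"], obs)
        assert r.computable and r.numeric_value == 0 and not r.triggered

    def test_missing_required_variable_blocks_computation(self, registry):
        obs = make_obs(gcs=None, avpu=None)
        r = evaluate_score_on_day(registry["qSOFA"], obs)
        assert not r.computable
        assert r.missing_variables == ["gcs"]
        assert r.triggered is None

    def test_avpu_substitutes_for_gcs(self, registry):
        obs = make_obs(gcs=None, avpu="voice", respiratory_rate=24)
        r = evaluate_score_on_day(registry["qSOFA"], obs)
        assert r.computable and r.triggered  # voice maps below GCS 15


class TestRecordEvaluation:
    def test_msi_ratio_and_trigger(self, registry):
        rec = make_record(obs_overrides=dict(heart_rate=120, systolic_bp=80, diastolic_bp=50))
        r = evaluate_score(registry["MSI"], rec)
        assert r.computable and r.numeric_value == pytest.approx(2.0) and r.triggered

    def test_any_day_triggering_uses_earliest_day(self, registry):
        rec = make_record(days=())
        rec.add_observation(make_obs(day_index=-1, gcs=None, avpu=None))  # not computable
        rec.add_observation(make_obs(day_index=0, respiratory_rate=26, systolic_bp=92))
        r = evaluate_score(registry["qSOFA"], rec)
        assert r.computable and r.triggered and r.triggering_day == 0

    def test_trigger_is_or_over_computable_days(self, registry):
        rec = make_record(days=())
        rec.add_observation(make_obs(day_index=-1))  # normal day
        rec.add_observation(make_obs(day_index=1, respiratory_rate=26, systolic_bp=92))
        day_triggers = [
            evaluate_score_on_day(registry["qSOFA"], rec.days[d]).triggered
            for d in sorted(rec.days)
        ]
        r = evaluate_score(registry["qSOFA"], rec)
        assert r.triggered == any(day_triggers)
        assert r.triggering_day == 1

    def test_pregnancy_applicability(self, registry):
        postpartum = make_record(pregnancy_status="postpartum")
        r = evaluate_score(registry["NICE-RST-P"], postpartum)
        assert not r.computable and "inapplicable" in r.reason
        pregnant = make_record(pregnancy_status="pregnant")
        assert not evaluate_score(registry["NICE-RST-PP/PA"], pregnant).computable

    @pytest.mark.parametrize("status", ["pregnant", "postpartum"])
    def test_all_normal_record_triggers_nothing(self, registry, status):
        """A fully observed textbook-normal record trips none of the 21 scores."""
        rec = make_record(pregnancy_status=status, days=(-1, 0, 1))
        for definition in registry.values():
            r = evaluate_score(definition, rec)
            if r.computable:
                assert not r.triggered, f"{definition.name} triggered on a normal record"


def _grid_observations(candidates, field_map, rng):
    """Full product when small; otherwise one-at-a-time sweeps plus a seeded
    sample of the product."""
    keys = list(candidates)
    pools = [candidates[k] for k in keys]
    total = 1
    for p in pools:
        total *= len(p)
    combos = []
    if total <= 4000:
        combos = list(itertools.product(*pools))
    else:
        base = {k: candidates[k][0] for k in keys}
        for k in keys:
            for v in candidates[k]:
                combos.append(tuple(v if kk == k else base[kk] for kk in keys))
        combos.extend(
            tuple(rng.choice(candidates[k]) for k in keys) for _ in range(1500)
        )
    for combo in combos:
        yield dict(zip(keys, combo))


@pytest.mark.parametrize("score_name", sorted(ORACLES))
def test_engine_matches_hand_coded_reference(registry, score_name):
    """The generic engine reproduces an independent hand-coded implementation
    of each score on grids straddling every threshold."""
    oracle, candidates, field_map = ORACLES[score_name]
    definition = registry[score_name]
    rng = random.Random(20240 + len(score_name))
    n_checked = 0
    for values in _grid_observations(candidates, field_map, rng):
        obs_kwargs = {field_map[k]: v for k, v in values.items()}
        obs = DayObservation(day_index=0, **obs_kwargs)
        result = evaluate_score_on_day(definition, obs)
        expected_value, expected_triggered = oracle(values)
        assert result.computable, f"{score_name}: unexpectedly non-computable at {values}"
        assert result.numeric_value == pytest.approx(expected_value), (score_name, values)
        assert result.triggered == expected_triggered, (score_name, values)
        n_checked += 1
    assert n_checked >= 12  # smallest full product (ratio scores)


def _worse_value(band):
    """A value satisfying the band, and one pushed further past the boundary."""
    if band.comparator in ("lt", "le"):
        at = band.bound - (0.0 if band.comparator == "le" else 0.01)
        return at, at - 5.0
    if band.comparator in ("gt", "ge"):
        at = band.bound + (0.0 if band.comparator == "ge" else 0.01)
        return at, at + 5.0
    return None


def test_monotonic_worsening_never_untriggers(registry):
    """For count/points scores, pushing one variable further past a satisfied
    boundary never lowers the score value or clears a trigger."""
    continuous = {
        "heart_rate", "respiratory_rate", "temperature", "systolic_bp",
        "diastolic_bp", "spo2", "wbc", "lactate", "paco2", "urine_output",
    }
    checked = 0
    for definition in registry.values():
        if definition.aggregation.type not in ("count_ge_k", "points_ge_k"):
            continue
        for band in definition.bands:
            if band.variable not in continuous:
                continue
            pair = _worse_value(band)
            if pair is None:
                continue
            at, worse = pair
            lo, hi = {"spo2": (1, 100), "temperature": (26, 44)}.get(band.variable, (1, 250))
            at, worse = max(lo, min(hi, at)), max(lo, min(hi, worse))
            base = evaluate_score_on_day(registry[definition.name],
                                         make_obs(**{band.variable: at}))
            pushed = evaluate_score_on_day(registry[definition.name],
                                           make_obs(**{band.variable: worse}))
            assert pushed.numeric_value >= base.numeric_value, (definition.name, band)
            if base.triggered:
                assert pushed.triggered, (definition.name, band)
            checked += 1
    assert checked > 20


class TestCohortScoring:
    def test_denominator_counts_computable_women(self, registry):
        cohort = [make_record(f"W{i}", "pregnant") for i in range(4)]
        cohort[3].days[0].gcs = None
        cohort[3].days[0].avpu = None
        matrix = score_cohort(registry, cohort)
        q = matrix[matrix.score == "qSOFA"]
        assert len(q) == 4
        assert int(q.computable.sum()) == 3

    def test_empty_cohort_rejected(self, registry):
        with pytest.raises(ValueError, match="empty"):
            score_cohort(registry, [])

    def test_msi_denominator_near_cohort_size(self, registry, default_cohort,
                                              default_matrix):
        """MSI needs only pulse and blood pressure, the best-recorded vitals,
        so nearly the whole cohort is evaluable."""
        msi = default_matrix[(default_matrix.score == "MSI") & default_matrix.computable]
        assert len(msi) > 0.8 * len(default_cohort)
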