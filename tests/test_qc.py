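"""Inclusion-rule tests: hand-counted coverage fractions, the boundary
fixture suite (one constructed participant per rule edge), monotonicity
under added data, and analysis-set containment."""
import numpy as np
import pytest

from conftest import SLOTS_PER_DAY, make_meal, make_record, make_trace
from glucolab.qc import (
    QcThresholds,
    daily_cgm_coverage,
    good_logging_day,
    passes_cgm_requirement,
    passes_hr_capture,
    passes_meal_logging,
    passes_weight_tracking,
    resting_hr,
    select_analysis_sets,
)
from glucolab.types import DayRange, ValidationError

THR = QcThresholds()


def trace_with_missing(missing_per_day: dict[int, int], days: int = 28):
    """Full 100 mg/dL trace with the first k slots of selected days blanked."""
    v = np.full(days * SLOTS_PER_DAY, 100.0)
    for day, k in missing_per_day.items():
        v[(day - 1) * SLOTS_PER_DAY : (day - 1) * SLOTS_PER_DAY + k] = np.nan
    return v


class TestDailyCoverage:
    def test_full_day_is_one(self):
        assert daily_cgm_coverage(make_trace(), 1) == 1.0

    def test_72_of_96_slots_is_three_quarters(self):
        trace = make_record(glucose=trace_with_missing({3: 24})).glucose
        assert daily_cgm_coverage(trace, 3) == pytest.approx(0.75)

    def test_empty_day_is_zero(self):
        trace = make_record(glucose=trace_with_missing({5: 96})).glucose
        assert daily_cgm_coverage(trace, 5) == 0.0

    def test_day_outside_span_rejected(self):
        with pytest.raises(ValidationError):
            daily_cgm_coverage(make_trace(days=28), 29)


class TestCgmRequirement:
    def test_full_capture_passes(self):
        assert passes_cgm_requirement(make_record(), THR)

    def test_failing_end_window_fails(self):
        # all end-window days below 70% coverage
        missing = {d: 30 for d in range(15, 29)}  # 66/96 = 68.75%
        rec = make_record(glucose=trace_with_missing(missing))
        assert not passes_cgm_requirement(rec, THR)

    def test_boundary_half_of_days_at_exactly_70pct_passes(self):
        # 7 of 14 end-window days at exactly 70% coverage (the other 7 at 0):
        # inclusive thresholds on both the coverage and the day fraction.
        missing = {d: 96 - 68 for d in range(15, 22)}  # hold 68/96 > 0.70
        missing.update({d: 96 for d in range(22, 29)})
        rec = make_record(glucose=trace_with_missing(missing))
        assert daily_cgm_coverage(rec.glucose, 15) >= 0.70
        assert passes_cgm_requirement(rec, THR)
        # push one held day below threshold -> only 6/14 days pass -> fail
        missing[21] = 96 - 66  # 66/96 = 68.75% < 70%
        rec2 = make_record(glucose=trace_with_missing(missing))
        assert not passes_cgm_requirement(rec2, THR)


class TestGoodLoggingDay:
    def test_two_spread_meals_totalling_1700_pass(self):
        meals = [make_meal(1, 7.0, kcal=900), make_meal(1, 22.0, kcal=800)]
        assert good_logging_day(meals, THR)

    def test_single_large_log_fails(self):
        assert not good_logging_day([make_meal(1, 12.0, kcal=1600)], THR)

    def test_kcal_floor(self):
        meals = [make_meal(1, 8.0, kcal=700), make_meal(1, 19.0, kcal=800)]
        assert not good_logging_day(meals, THR)  # 1500 < 1600
        meals = [make_meal(1, 8.0, kcal=800), make_meal(1, 19.0, kcal=800)]
        assert good_logging_day(meals, THR)  # boundary inclusive

    def test_span_rules(self):
        # > 16 h apart: fails the waking-window rule
        meals = [make_meal(1, 5.0, kcal=900), make_meal(1, 22.0, kcal=900)]
        assert not good_logging_day(meals, THR)
        # < 4 h spread: not "spread throughout waking hours"
        meals = [make_meal(1, 12.0, kcal=900), make_meal(1, 13.0, kcal=900)]
        assert not good_logging_day(meals, THR)


class TestStreamRules:
    def test_weight_in_both_windows_passes(self):
        assert passes_weight_tracking(make_record(weights=[(2, 200), (20, 195)]), THR)

    def test_weight_single_window_fails(self):
        assert not passes_weight_tracking(make_record(weights=[(2, 200)]), THR)

    def test_hr_short_day_fails(self):
        hr = np.full(28 * 1440, 70.0)
        day = 10
        hr[(day - 1) * 1440 : (day - 1) * 1440 + 1440 - 19 * 60] = np.nan  # 19 h left
        assert not passes_hr_capture(make_record(hr=hr), THR)

    def test_hr_exactly_20h_passes(self):
        hr = np.full(28 * 1440, 70.0)
        for day in range(1, 29):
            hr[(day - 1) * 1440 : (day - 1) * 1440 + 4 * 60] = np.nan  # 20 h capture
        assert passes_hr_capture(make_record(hr=hr), THR)

    def test_meal_logging_requires_both_windows(self):
        # meals only in the first week -> end window fails
        meals = [make_meal(d, h) for d in range(1, 8) for h in (8.0, 19.0)]
        rec = make_record(meals=meals, weights=[])
        assert not passes_meal_logging(rec, THR)


class TestAnalysisSets:
    def test_weight_only_failure_keeps_glucose_set(self):
        rec = make_record(weights=[(2, 200.0)])  # fails weight rule only
        report = select_analysis_sets([rec])
        assert rec.id in report.glucose_set
        assert rec.id not in report.weight_set

    def test_high_resting_hr_flagged_but_glucose_eligible(self):
        rec = make_record(hr=np.full(28 * 1440, 115.0))
        report = select_analysis_sets([rec])
        row = report.row(rec.id)
        assert row["resting_hr_excluded"]
        assert rec.id in report.glucose_set

    def test_empty_log_participant_in_no_set(self):
        rec = make_record(
            glucose=np.full(28 * SLOTS_PER_DAY, np.nan),
            hr=np.full(28 * 1440, np.nan),
            meals=[],
            weights=[],
        )
        report = select_analysis_sets([rec])
        row = report.row(rec.id)
        assert not any(
            row[k] for k in ("cgm_ok", "meals_ok", "weight_ok", "hr_ok",
                             "glucose_set", "weight_set", "diet_set")
        )

    def test_set_containment(self, small_cohort):
        report = select_analysis_sets(small_cohort)
        assert report.weight_set <= report.glucose_set
        assert report.diet_set <= report.glucose_set

    def test_monotonicity_adding_data_never_breaks_a_pass(self, small_cohort):
        """Filling CGM gaps and adding log events can only help."""
        report = select_analysis_sets(small_cohort)
        enriched = []
        for rec in small_cohort:
            v = rec.glucose.values.copy()
            v[~np.isfinite(v)] = 100.0
            meals = list(rec.meals) + [
                make_meal(d, 12.0) for d in range(1, rec.program_days + 1)
            ]
            enriched.append(
                make_record(
                    pid=rec.id, category=rec.category, glucose=v,
                    hr=np.where(np.isfinite(rec.heart_rate), rec.heart_rate, 70.0),
                    meals=sorted(meals, key=lambda m: m.t_min),
                    weights=rec.weights or [(2, 200.0), (20, 199.0)],
                )
            )
        report2 = select_analysis_sets(enriched)
        for key in ("glucose_set", "weight_set"):
            assert getattr(report, key) <= getattr(report2, key)


def boundary_fixtures():
    """20 constructed participants, one per inclusion-rule boundary, each
    with the designed classification."""
    full_hr = np.full(28 * 1440, 70.0)
    cases = []

    def add(name, rec, **expected):
        cases.append((name, rec, expected))

    # CGM coverage boundaries
    v = trace_with_missing({d: 96 - 68 for d in range(2, 8)})  # 70.8% baseline days
    add("cgm_exactly_70pct_passes", make_record(glucose=v), cgm_ok=True)
    v = trace_with_missing({d: 30 for d in range(2, 8)})  # 68.75% all baseline days
    add("cgm_below_70pct_fails", make_record(glucose=v), cgm_ok=False)
    v = trace_with_missing({d: 96 for d in (2, 3, 4)})  # 3/6 baseline days empty
    add("cgm_half_days_passes", make_record(glucose=v), cgm_ok=True)
    v = trace_with_missing({d: 96 for d in (2, 3, 4, 5)})  # 4/6 empty
    add("cgm_under_half_days_fails", make_record(glucose=v), cgm_ok=False)

    # meal logging boundaries (>=2 events/day on >= half the window days)
    meals2 = [make_meal(d, h) for d in range(1, 29) for h in (8.0, 19.0)]
    add("meals_two_per_day_passes", make_record(meals=meals2, weights=[]),
        meals_ok=True)
    meals1 = [make_meal(d, 12.0) for d in range(1, 29)]
    add("meals_one_per_day_fails", make_record(meals=meals1, weights=[]),
        meals_ok=False)
    half = [make_meal(d, h) for d in (1, 2, 3, 4, 15, 16, 17, 18, 19, 20, 21)
            for h in (8.0, 19.0)]
    add("meals_half_of_days_passes", make_record(meals=half, weights=[]),
        meals_ok=True)
    under = [make_meal(d, h) for d in (1, 2, 3, 15, 16, 17, 18, 19, 20)
             for h in (8.0, 19.0)]
    add("meals_under_half_fails", make_record(meals=under, weights=[]),
        meals_ok=False)

    # good-day kcal boundary feeds diet_set
    good = [make_meal(d, h, kcal=800.0) for d in range(1, 29) for h in (8.0, 19.0)]
    add("good_day_1600_kcal_passes", make_record(meals=good), diet_set=True)
    low = [make_meal(d, h, kcal=799.0) for d in range(1, 29) for h in (8.0, 19.0)]
    add("good_day_1599_kcal_fails", make_record(meals=low), diet_set=False)

    # 16-h span boundary
    span16 = [make_meal(d, h, kcal=900.0) for d in range(1, 29) for h in (6.0, 22.0)]
    add("good_day_16h_span_passes", make_record(meals=span16), diet_set=True)
    span17 = [make_meal(d, h, kcal=900.0) for d in range(1, 29) for h in (5.0, 22.0)]
    add("good_day_17h_span_fails", make_record(meals=span17), diet_set=False)
    tight = [make_meal(d, h, kcal=900.0) for d in range(1, 29) for h in (12.0, 13.0)]
    add("good_day_narrow_spread_fails", make_record(meals=tight), diet_set=False)

    # HR capture boundaries
    hr20 = np.full(28 * 1440, 70.0)
    for day in range(1, 29):
        hr20[(day - 1) * 1440 : (day - 1) * 1440 + 4 * 60] = np.nan
    add("hr_exactly_20h_passes", make_record(hr=hr20), hr_ok=True)
    hr199 = np.full(28 * 1440, 70.0)
    hr199[: 1440 - (19 * 60 + 54)] = np.nan  # 19.9 h on day 1
    add("hr_19p9h_fails", make_record(hr=hr199), hr_ok=False)

    # weight-window boundaries
    add("weight_day7_and_day15_passes",
        make_record(weights=[(7, 200.0), (15, 198.0)]), weight_ok=True)
    add("weight_day8_first_fails",
        make_record(weights=[(8, 200.0), (20, 198.0)]), weight_ok=False)
    add("weight_day14_last_fails",
        make_record(weights=[(2, 200.0), (14, 198.0)]), weight_ok=False)

    # resting-HR boundary (5th percentile at / above 110)
    add("resting_hr_110_not_excluded", make_record(hr=np.full(28 * 1440, 110.0)),
        resting_hr_excluded=False)
    add("resting_hr_111_excluded", make_record(hr=np.full(28 * 1440, 111.0)),
        resting_hr_excluded=True)
    return cases


BOUNDARY_CASES = boundary_fixtures()


def test_boundary_suite_has_twenty_fixtures():
    assert len(BOUNDARY_CASES) == 20


@pytest.mark.parametrize(
    "name,rec,expected", BOUNDARY_CASES, ids=[c[0] for c in BOUNDARY_CASES]
)
def test_inclusion_rule_boundaries(name, rec, expected):
    report = select_analysis_sets([rec])
    row = report.row(rec.id)
    for key, want in expected.items():
        assert row[key] == want, f"{name}: {key} expected {want}"
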