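"""Cohort inclusion criteria and logging-quality rules.

Selects the analysis subsets: sufficient CGM capture, consistent meal
logging, weight tracking in both program windows, and heart-rate capture.
All threshold comparisons are inclusive (the rules are stated as "at
least").
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import (
    DayRange,
    MINUTES_PER_DAY,
    MealLog,
    ParticipantRecord,
    ValidationError,
)


@dataclass(frozen=True)
class QcThresholds:
    """Inclusion-rule thresholds.

    The source protocol states the baseline CGM-QC window inconsistently
    (days 3-7 in one place, days 1-5 excluding day 1 in another); the
    default here is days 2-7, aligned with the glycemic baseline window.
    Both alternatives are expressible through ``cgm_baseline_window``.
    """

    cgm_daily_coverage_min: float = 0.70
    cgm_days_fraction_min: float = 0.5
    cgm_baseline_window: DayRange = DayRange(2, 7)
    cgm_end_window: DayRange = DayRange(15, 28)
    meal_baseline_window: DayRange = DayRange(1, 7)
    meal_end_window: DayRange = DayRange(15, 28)
    meal_days_fraction_min: float = 0.5
    min_meal_logs_per_day: int = 2
    good_day_kcal_min: float = 1600.0
    good_day_span_hours: float = 16.0
    good_day_min_spread_hours: float = 4.0
    hr_hours_min: float = 20.0
    weight_first_window: DayRange = DayRange(1, 7)
    weight_last_window: DayRange = DayRange(15, 28)
    resting_hr_max: float = 110.0

    def __post_init__(self):
        for name in ("cgm_daily_coverage_min", "cgm_days_fraction_min",
                     "meal_days_fraction_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")


def daily_cgm_coverage(trace, day: int) -> float:
    """Fraction of the day's CGM slots that carry a reading."""
    vals = trace.values[trace.day_slice(day)]
    return float(np.isfinite(vals).sum()) / trace.slots_per_day


def passes_cgm_requirement(record: ParticipantRecord, thr: QcThresholds) -> bool:
    """>= coverage_min on >= days_fraction_min of the days in EACH of the
    baseline and end QC windows."""
    trace = record.glucose
    if trace.n_slots == 0:
        return False
    for window in (thr.cgm_baseline_window, thr.cgm_end_window):
        days = [d for d in window.days() if d <= trace.n_days]
        if not days:
            return False
        ok = sum(
            daily_cgm_coverage(trace, d) >= thr.cgm_daily_coverage_min for d in days
        )
        if ok / len(days) < thr.cgm_days_fraction_min:
            return False
    return True


def good_logging_day(day_meals: Sequence[MealLog], thr: QcThresholds) -> bool:
    """A day of food logs usable for nutrient analysis: at least two logging
    events, spread through waking hours (all logs inside a 16-h window with a
    first-to-last spread of at least 4 h), totalling >= 1600 kcal."""
    if len(day_meals) < thr.min_meal_logs_per_day:
        return False
    days = {m.day for m in day_meals}
    if len(days) > 1:
        raise ValidationError("good_logging_day expects meals from one calendar day")
    times = sorted(m.t_min for m in day_meals)
    span_h = (times[-1] - times[0]) / 60.0
    if span_h > thr.good_day_span_hours:
        return False
    if span_h < thr.good_day_min_spread_hours:
        return False
    total_kcal = sum(m.nutrients.kcal for m in day_meals)
    return total_kcal >= thr.good_day_kcal_min


def _active_days_fraction(
    record: ParticipantRecord, window: DayRange, thr: QcThresholds
) -> float:
    """Fraction of window days with >= min_meal_logs_per_day log events of
    any type (meal, activity, weigh-in)."""
    events = record.log_events()
    days = [d for d in window.days() if d <= record.program_days]
    if not days:
        return 0.0
    counts = {d: 0 for d in days}
    for t in events:
        d = int(t // MINUTES_PER_DAY) + 1
        if d in counts:
            counts[d] += 1
    active = sum(c >= thr.min_meal_logs_per_day for c in counts.values())
    return active / len(days)


def passes_meal_logging(record: ParticipantRecord, thr: QcThresholds) -> bool:
    """Active logging (>= 2 events/day) on at least half the days of both the
    first-week and last-two-week windows."""
    return (
        _active_days_fraction(record, thr.meal_baseline_window, thr)
        >= thr.meal_days_fraction_min
        and _active_days_fraction(record, thr.meal_end_window, thr)
        >= thr.meal_days_fraction_min
    )


def passes_weight_tracking(record: ParticipantRecord, thr: QcThresholds) -> bool:
    days = [d for d, _ in record.weights]
    first = any(thr.weight_first_window.start <= d <= thr.weight_first_window.end
                for d in days)
    last = any(thr.weight_last_window.start <= d <= thr.weight_last_window.end
               for d in days)
    return first and last


def hr_capture_hours(record: ParticipantRecord, day: int) -> float:
    lo = (day - 1) * MINUTES_PER_DAY
    hi = min(day * MINUTES_PER_DAY, record.heart_rate.size)
    if hi <= lo:
        return 0.0
    return float(np.isfinite(record.heart_rate[lo:hi]).sum()) / 60.0


def passes_hr_capture(record: ParticipantRecord, thr: QcThresholds) -> bool:
    """HR capture >= hr_hours_min on every program day."""
    n_days = record.program_days
    if record.heart_rate.size == 0:
        return False
    return all(
        hr_capture_hours(record, d) >= thr.hr_hours_min for d in range(1, n_days + 1)
    )


def resting_hr(record: ParticipantRecord) -> float:
    """Resting HR proxy: 5th percentile of per-minute HR over the program."""
    finite = record.heart_rate[np.isfinite(record.heart_rate)]
    if finite.size == 0:
        return float("nan")
    return float(np.percentile(finite, 5))


def has_good_days_in_window(
    record: ParticipantRecord, window: DayRange, thr: QcThresholds
) -> bool:
    for day in window.days():
        if day > record.program_days:
            break
        if good_logging_day(record.meals_on_day(day), thr):
            return True
    return False


@dataclass
class QcReport:
    """Per-participant inclusion booleans and derived analysis sets."""

    rows: list[dict] = field(default_factory=list)

    def ids(self, key: str) -> set[str]:
        return {r["id"] for r in self.rows if r[key]}

    @property
    def glucose_set(self) -> set[str]:
        return self.ids("glucose_set")

    @property
    def weight_set(self) -> set[str]:
        return self.ids("weight_set")

    @property
    def diet_set(self) -> set[str]:
        return self.ids("diet_set")

    def row(self, pid: str) -> dict:
        for r in self.rows:
            if r["id"] == pid:
                return r
        raise KeyError(pid)


def select_analysis_sets(
    cohort: Sequence[ParticipantRecord], thr: QcThresholds | None = None
) -> QcReport:
    """Classify every participant against the inclusion rules.

    glucose_set: CGM + meal-logging + HR-capture rules all pass.
    weight_set:  glucose_set plus a weigh-in in both weight windows.
    diet_set:    glucose_set plus at least one good logging day in both the
                 baseline and end meal windows.
    Participants whose resting HR exceeds 110 bpm stay eligible for glucose
    analyses but are flagged for exclusion from HR-based measures.
    """
    thr = thr or QcThresholds()
    if not cohort:
        raise ValidationError("cohort is empty")
    report = QcReport()
    for rec in cohort:
        cgm_ok = passes_cgm_requirement(rec, thr)
        meals_ok = passes_meal_logging(rec, thr)
        weight_ok = passes_weight_tracking(rec, thr)
        hr_ok = passes_hr_capture(rec, thr)
        rhr = resting_hr(rec)
        rhr_excluded = bool(np.isfinite(rhr) and rhr > thr.resting_hr_max)
        glucose_set = cgm_ok and meals_ok and hr_ok
        diet_ok = (
            has_good_days_in_window(rec, thr.meal_baseline_window, thr)
            and has_good_days_in_window(rec, thr.meal_end_window, thr)
        )
        report.rows.append(
            {
                "id": rec.id,
                "category": rec.category,
                "cgm_ok": cgm_ok,
                "meals_ok": meals_ok,
                "weight_ok": weight_ok,
                "hr_ok": hr_ok,
                "resting_hr": rhr,
                "resting_hr_excluded": rhr_excluded,
                "glucose_set": glucose_set,
                "weight_set": glucose_set and weight_ok,
                "diet_set": glucose_set and diet_ok,
            }
        )
    return report
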