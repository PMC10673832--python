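"""Dietary, activity, heart-rate and body-weight outcomes.

The dietary summaries use only "good" logging days and express macronutrients
as a proportion of logged total calories (grams x4 for carbohydrate, sugar
and protein; x9 for fat and saturated fat; fiber as grams per kcal), which
makes the ratios insensitive to how often a participant logged.  Activity
minutes are normalized by the participant's app-interaction rate relative to
baseline for the same reason.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .qc import QcThresholds, good_logging_day, hr_capture_hours, resting_hr
from .types import (
    DayRange,
    MINUTES_PER_DAY,
    ActivityLog,
    MealLog,
    NoDataError,
    ParticipantRecord,
)

# Windows for activity / food logging comparisons (the glycemic baseline
# window, days 2-7, is configured separately in glycemic.AnalysisWindows).
ACTIVITY_BASELINE = DayRange(1, 5)
DIET_BASELINE = DayRange(1, 7)
END_WINDOW = DayRange(14, 28)

MACRO_RATIOS = ("carb", "sugar", "protein", "fat", "satfat")


class HrExcludedError(ValueError):
    """Participant excluded from HR analyses (resting HR above threshold)."""


@dataclass
class NutrientSummary:
    mean_daily_kcal: float
    ratios: dict[str, float]  # macronutrient kcal / logged total kcal
    fiber_per_kcal: float  # grams of fiber per logged kcal
    n_good_days: int


@dataclass
class BehaviorSummary:
    adjusted_activity_min_per_day: float
    hr110_min_per_day: float
    weight_first: float
    weight_last: float
    weight_delta_lbs: float
    weight_delta_pct: float


def nutrient_summary(
    meals: Sequence[MealLog],
    window: DayRange,
    thr: QcThresholds | None = None,
) -> NutrientSummary:
    """Pool nutrients over the window's good logging days.

    Ratios are macro-kcal over logged total kcal summed across good days, so
    duplicating a day's logs leaves every ratio unchanged.
    """
    thr = thr or QcThresholds()
    by_day: dict[int, list[MealLog]] = {}
    for m in meals:
        if window.start <= m.day <= window.end:
            by_day.setdefault(m.day, []).append(m)
    good_days = {d: ms for d, ms in by_day.items() if good_logging_day(ms, thr)}
    if not good_days:
        raise NoDataError("no good logging days in window")

    total_kcal = 0.0
    macro_kcal = {k: 0.0 for k in MACRO_RATIOS}
    fiber_g = 0.0
    for ms in good_days.values():
        for m in ms:
            total_kcal += m.nutrients.kcal
            for k, v in m.nutrients.macro_kcal().items():
                macro_kcal[k] += v
            fiber_g += m.nutrients.fiber_g
    n = len(good_days)
    return NutrientSummary(
        mean_daily_kcal=total_kcal / n,
        ratios={k: (macro_kcal[k] / total_kcal if total_kcal > 0 else 0.0)
                for k in MACRO_RATIOS},
        fiber_per_kcal=fiber_g / total_kcal if total_kcal > 0 else 0.0,
        n_good_days=n,
    )


def _events_per_day(events: Sequence[float], window: DayRange) -> float:
    lo, hi = window.minute_bounds()
    return sum(lo <= t < hi for t in events) / window.n_days


def adjusted_activity_minutes(
    activities: Sequence[ActivityLog],
    app_interactions: Sequence[float],
    window: DayRange,
    reference_window: DayRange = ACTIVITY_BASELINE,
) -> float:
    """Logged activity min/day, corrected for changing logging frequency.

    Raw minutes/day are divided by the ratio of the window's app-interaction
    rate to the reference (baseline) window's rate; when logging behavior is
    unchanged the adjustment is the identity.
    """
    rate = _events_per_day(app_interactions, window)
    ref_rate = _events_per_day(app_interactions, reference_window)
    if rate <= 0:
        raise NoDataError("no app interactions in window")
    lo, hi = window.minute_bounds()
    raw = sum(a.duration_min for a in activities if lo <= a.t_min < hi) / window.n_days
    if ref_rate <= 0:
        return raw
    return raw / (rate / ref_rate)


def hr_above_threshold_minutes(
    record: ParticipantRecord,
    window: DayRange,
    threshold: float = 110.0,
    thr: QcThresholds | None = None,
) -> float:
    """Minutes/day with HR strictly above threshold, over window days with
    >= 20 h of HR capture.  Raises for resting-HR-excluded participants."""
    thr = thr or QcThresholds()
    rhr = resting_hr(record)
    if np.isfinite(rhr) and rhr > thr.resting_hr_max:
        raise HrExcludedError(
            f"resting HR {rhr:.0f} bpm exceeds {thr.resting_hr_max:.0f}"
        )
    minutes = 0.0
    capture_days = 0
    for day in window.days():
        if day > record.program_days:
            break
        if hr_capture_hours(record, day) < thr.hr_hours_min:
            continue
        capture_days += 1
        lo = (day - 1) * MINUTES_PER_DAY
        hi = min(day * MINUTES_PER_DAY, record.heart_rate.size)
        seg = record.heart_rate[lo:hi]
        minutes += float((seg[np.isfinite(seg)] > threshold).sum())
    if capture_days == 0:
        raise NoDataError("no days with sufficient HR capture in window")
    return minutes / capture_days


def weight_change(
    weights: Sequence[tuple[int, float]],
    program_days: int = 28,
    first_window: DayRange = DayRange(1, 7),
    last_window: DayRange = DayRange(15, 28),
) -> tuple[float, float, float, float]:
    """(first, last, delta_lbs, delta_pct): first weigh-in of the first week
    vs last weigh-in of the final two weeks."""
    firsts = sorted(
        (d, w) for d, w in weights if first_window.start <= d <= first_window.end
    )
    lasts = sorted(
        (d, w) for d, w in weights if last_window.start <= d <= last_window.end
    )
    if not firsts or not lasts:
        raise NoDataError("weight measurement missing in first or last window")
    first = firsts[0][1]
    last = lasts[-1][1]
    delta = last - first
    return first, last, delta, 100.0 * delta / first


WEIGHT_STRATA = (
    ("<150", 0.0, 150.0),
    ("150-199", 150.0, 200.0),
    ("200-249", 200.0, 250.0),
    ("250-300", 250.0, 300.0),
)


def weight_stratum(baseline_lbs: float) -> str:
    """Stratum label; boundaries are lower-inclusive (250.0 -> '250-300')."""
    for label, lo, hi in WEIGHT_STRATA:
        if lo <= baseline_lbs < hi:
            return label
    return ">300"


def weight_strata_report(
    cohort: Sequence[ParticipantRecord],
    include_ids: set[str] | None = None,
    horizons: dict[str, DayRange] | None = None,
) -> dict:
    """Mean weight loss per baseline-weight stratum and horizon.

    Default horizon is the 4-week program window; a 12-week horizon (days
    70-84) is reported only when weigh-ins exist there.  Empty strata are
    absent from the result.
    """
    horizons = horizons or {
        "4wk": DayRange(15, 28),
        "12wk": DayRange(70, 84),
    }
    out: dict = {}
    for name, last_window in horizons.items():
        rows: dict[str, list[tuple[float, float]]] = {}
        for rec in cohort:
            if include_ids is not None and rec.id not in include_ids:
                continue
            try:
                first, last, delta, pct = weight_change(
                    rec.weights, last_window=last_window
                )
            except NoDataError:
                continue
            stratum = weight_stratum(first)
            rows.setdefault(stratum, []).append((delta, pct))
            rows.setdefault("overall", []).append((delta, pct))
        for stratum, pairs in rows.items():
            deltas = np.array([p[0] for p in pairs])
            pcts = np.array([p[1] for p in pairs])
            out[(stratum, name)] = {
                "n": len(pairs),
                "mean_loss_lbs": float(-deltas.mean()),
                "mean_loss_pct": float(-pcts.mean()),
            }
    return out


def behavior_summary(
    record: ParticipantRecord,
    baseline: DayRange = ACTIVITY_BASELINE,
    end: DayRange = END_WINDOW,
    thr: QcThresholds | None = None,
) -> dict:
    """Baseline and end activity/HR measures plus the weight change."""
    thr = thr or QcThresholds()
    interactions = record.log_events()
    out: dict = {}
    for name, window in (("baseline", baseline), ("end", end)):
        try:
            out[f"adjusted_activity_{name}"] = adjusted_activity_minutes(
                record.activities, interactions, window, reference_window=baseline
            )
        except NoDataError:
            out[f"adjusted_activity_{name}"] = np.nan
        try:
            out[f"hr110_{name}"] = hr_above_threshold_minutes(record, window, thr=thr)
        except (HrExcludedError, NoDataError):
            out[f"hr110_{name}"] = np.nan
    try:
        first, last, delta, pct = weight_change(record.weights)
        out.update(weight_first=first, weight_last=last,
                   weight_delta_lbs=delta, weight_delta_pct=pct)
    except NoDataError:
        out.update(weight_first=np.nan, weight_last=np.nan,
                   weight_delta_lbs=np.nan, weight_delta_pct=np.nan)
    return out
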