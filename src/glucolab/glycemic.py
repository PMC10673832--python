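"""CGM outcome metrics per analysis window and baseline-vs-end deltas.

Time in range (TIR) uses 70-180 mg/dL for T2D and 70-140 mg/dL otherwise.
The glucose management indicator (GMI) maps mean CGM glucose to an HbA1c
estimate with the standard consensus linear formula.  Excursion events are
maximal runs of >= 2 consecutive beyond-threshold samples, with nearby runs
merged; event *rates* (but not the averaged metrics) are corrected for CGM
signal loss by the window's lost-time fraction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import DayRange, GlucoseTrace, NoDataError, ParticipantRecord

GMI_INTERCEPT = 3.31
GMI_SLOPE = 0.02392

EVENT_THRESHOLDS = (
    (">140", 140.0, "above"),
    (">180", 180.0, "above"),
    (">250", 250.0, "above"),
    ("<70", 70.0, "below"),
)

TIR_RANGE_T2D = (70.0, 180.0)
TIR_RANGE_NON_T2D = (70.0, 140.0)


@dataclass(frozen=True)
class AnalysisWindows:
    """Baseline vs end-of-program comparison windows (day 1 excluded from
    baseline because first-day CGM readings are unreliable)."""

    baseline: DayRange = DayRange(2, 7)
    end: DayRange = DayRange(14, 28)


@dataclass
class GlycemicSummary:
    tir_pct: float
    gmi_pct: float
    events_per_day: dict[str, float]
    cv_pct: float
    mean_glucose: float
    lost_time_fraction: float
    tir_range: tuple[float, float] = TIR_RANGE_NON_T2D


def _window_samples(trace: GlucoseTrace, window: DayRange) -> np.ndarray:
    vals = trace.window_values(window)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise NoDataError(f"no CGM samples in days {window.start}-{window.end}")
    return finite


def time_in_range(
    trace: GlucoseTrace, window: DayRange, low: float, high: float
) -> float:
    """Percent of non-missing window samples with low <= v <= high."""
    v = _window_samples(trace, window)
    return 100.0 * float(((v >= low) & (v <= high)).sum()) / v.size


def mean_glucose(trace: GlucoseTrace, window: DayRange) -> float:
    return float(_window_samples(trace, window).mean())


def gmi(trace: GlucoseTrace, window: DayRange) -> float:
    """GMI(%) = 3.31 + 0.02392 * mean glucose (mg/dL)."""
    return GMI_INTERCEPT + GMI_SLOPE * mean_glucose(trace, window)


def lost_time_fraction(trace: GlucoseTrace, window: DayRange) -> float:
    vals = trace.window_values(window)
    if vals.size == 0:
        raise NoDataError("window does not overlap trace")
    return float((~np.isfinite(vals)).sum()) / vals.size


def count_events(
    trace: GlucoseTrace,
    window: DayRange,
    threshold: float,
    direction: str = "above",
    min_run: int = 2,
    merge_gap_min: float = 30.0,
) -> float:
    """Excursion events per day, lost-time adjusted.

    An event is a maximal run of >= min_run consecutive non-missing samples
    beyond the threshold (strictly above for "above", strictly below for
    "below"); runs separated by < merge_gap_min minutes are merged into one
    event.  The per-day rate divides by window days scaled by the fraction
    of slots actually recorded.
    """
    sl = trace.window_slice(window)
    vals = trace.values[sl]
    if vals.size == 0:
        raise NoDataError("window does not overlap trace")
    ltf = float((~np.isfinite(vals)).sum()) / vals.size
    if ltf >= 1.0:
        raise NoDataError("window has no recorded CGM time")

    finite = np.isfinite(vals)
    if direction == "above":
        beyond = finite & (vals > threshold)
    elif direction == "below":
        beyond = finite & (vals < threshold)
    else:
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")

    max_gap_slots = int(np.ceil(merge_gap_min / trace.step_min)) - 1  # gap < 30 min
    runs: list[tuple[int, int]] = []  # [start, end) slot index of qualifying runs
    i = 0
    n = beyond.size
    while i < n:
        if beyond[i]:
            j = i
            while j < n and beyond[j]:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    # merge runs separated by a gap shorter than merge_gap_min
    events = 0
    prev_end = None
    for start, end in runs:
        if prev_end is not None and start - prev_end <= max_gap_slots:
            pass  # continuation of the previous event
        else:
            events += 1
        prev_end = end

    window_days = vals.size / trace.slots_per_day
    return events / (window_days * (1.0 - ltf))


def coefficient_of_variation(trace: GlucoseTrace, window: DayRange) -> float:
    """100 * sample SD / mean over the window's non-missing samples."""
    v = _window_samples(trace, window)
    if v.size < 2:
        raise NoDataError("coefficient of variation requires >= 2 samples")
    return 100.0 * float(v.std(ddof=1)) / float(v.mean())


def tir_range_for(category: str) -> tuple[float, float]:
    return TIR_RANGE_T2D if category == "t2d" else TIR_RANGE_NON_T2D


def summarize(
    record: ParticipantRecord, window: DayRange, category: str | None = None
) -> GlycemicSummary:
    """All window metrics for one participant."""
    category = category or record.category
    low, high = tir_range_for(category)
    trace = record.glucose
    events = {
        name: count_events(trace, window, thr, direction)
        for name, thr, direction in EVENT_THRESHOLDS
    }
    return GlycemicSummary(
        tir_pct=time_in_range(trace, window, low, high),
        gmi_pct=gmi(trace, window),
        events_per_day=events,
        cv_pct=coefficient_of_variation(trace, window),
        mean_glucose=mean_glucose(trace, window),
        lost_time_fraction=lost_time_fraction(trace, window),
        tir_range=(low, high),
    )


# ---------------------------------------------------------------------------
# Baseline-vs-end subgrouping
# ---------------------------------------------------------------------------

SUBGROUPS = ("overall", "tir_lt_90", "tir_lt_70", "gmi_gt_6", "gmi_gt_7")


def subgroup_membership(baseline: GlycemicSummary) -> set[str]:
    groups = {"overall"}
    if baseline.tir_pct < 90.0:
        groups.add("tir_lt_90")
    if baseline.tir_pct < 70.0:
        groups.add("tir_lt_70")
    if baseline.gmi_pct > 6.0:
        groups.add("gmi_gt_6")
    if baseline.gmi_pct > 7.0:
        groups.add("gmi_gt_7")
    return groups


@dataclass
class ParticipantDelta:
    id: str
    category: str
    baseline: GlycemicSummary
    end: GlycemicSummary

    def delta(self, metric: str) -> float:
        if metric.startswith("events"):
            key = metric.split(":", 1)[1]
            return self.end.events_per_day[key] - self.baseline.events_per_day[key]
        return getattr(self.end, metric) - getattr(self.baseline, metric)


DELTA_METRICS = ("tir_pct", "gmi_pct", "cv_pct", "mean_glucose",
                 "events:>140", "events:>180", "events:>250", "events:<70")


def participant_deltas(
    cohort: Sequence[ParticipantRecord],
    windows: AnalysisWindows | None = None,
    include_ids: set[str] | None = None,
) -> list[ParticipantDelta]:
    """Baseline and end summaries per participant (skipping windows with no
    CGM data)."""
    windows = windows or AnalysisWindows()
    out = []
    for rec in cohort:
        if include_ids is not None and rec.id not in include_ids:
            continue
        try:
            base = summarize(rec, windows.baseline)
            end = summarize(rec, windows.end)
        except NoDataError:
            continue
        out.append(ParticipantDelta(rec.id, rec.category, base, end))
    return out


def subgroup_deltas(
    deltas: Sequence[ParticipantDelta],
    metrics: Sequence[str] = DELTA_METRICS,
) -> dict:
    """Mean end-minus-baseline change per baseline-defined subgroup, overall
    and per glycemic category.  Subgroups are formed on baseline values only;
    empty subgroups are reported as absent (no key), never as zero.
    """
    table: dict[tuple[str, str], list[ParticipantDelta]] = {}
    for d in deltas:
        for g in subgroup_membership(d.baseline):
            table.setdefault((g, "all"), []).append(d)
            table.setdefault((g, d.category), []).append(d)
    result = {}
    for (group, category), members in sorted(table.items()):
        entry = {"n": len(members)}
        for metric in metrics:
            vals = np.array([m.delta(metric) for m in members])
            entry[metric] = {
                "mean_delta": float(vals.mean()),
                "mean_baseline": float(
                    np.mean([_metric_value(m.baseline, metric) for m in members])
                ),
                "mean_end": float(
                    np.mean([_metric_value(m.end, metric) for m in members])
                ),
            }
        result[(group, category)] = entry
    return result


def _metric_value(summary: GlycemicSummary, metric: str) -> float:
    if metric.startswith("events"):
        return summary.events_per_day[metric.split(":", 1)[1]]
    return getattr(summary, metric)
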