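"""Feature-frame construction for the glucose predictor.

One frame per 15-min CGM step: glucose (mg/dL), mean heart rate (bpm),
exercise minutes within the step, time of day as a (sin, cos) pair, and the
nutrient vector of any foods logged in the step.  Only "complete" days
contribute training frames: at least 12 h of both CGM and HR capture plus a
logged food day (so the nutrient channel is trustworthy); small CGM gaps
inside a complete day are linearly interpolated so frames are gapless.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import MINUTES_PER_DAY, ParticipantRecord

FEATURE_NAMES = (
    "glucose", "heart_rate", "exercise_min", "tod_sin", "tod_cos",
    "kcal", "carb_g", "sugar_g", "protein_g", "fat_g", "satfat_g", "fiber_g",
)
GLUCOSE_CHANNEL = 0
FEATURE_GROUPS = {
    "nutrients": (5, 6, 7, 8, 9, 10, 11),
    "time_of_day": (3, 4),
    "heart_rate": (1,),
    "activity": (2,),
}
N_FEATURES = len(FEATURE_NAMES)

MIN_COMPLETE_DAYS = 5
COMPLETE_HOURS_MIN = 12.0


class InsufficientDataError(ValueError):
    """Record has fewer complete days than the model requires."""


def _interp_nan(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    bad = ~np.isfinite(out)
    if bad.any():
        idx = np.arange(out.size)
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def complete_days(record: ParticipantRecord) -> list[int]:
    """Days meeting the 12-h CGM + 12-h HR + food-logged completeness rule."""
    trace = record.glucose
    logged = record.ground_truth.get("logged_days")
    days = []
    for day in range(1, record.program_days + 1):
        g = trace.values[trace.day_slice(day)]
        cgm_h = np.isfinite(g).sum() * trace.step_min / 60.0
        lo, hi = (day - 1) * MINUTES_PER_DAY, min(day * MINUTES_PER_DAY,
                                                  record.heart_rate.size)
        hr_h = np.isfinite(record.heart_rate[lo:hi]).sum() / 60.0
        food_ok = (day in logged) if logged is not None else bool(
            record.meals_on_day(day)
        )
        if cgm_h >= COMPLETE_HOURS_MIN and hr_h >= COMPLETE_HOURS_MIN and food_ok:
            days.append(day)
    return days


def day_frames(record: ParticipantRecord, day: int) -> np.ndarray:
    """Feature matrix (slots_per_day, N_FEATURES) for one day."""
    trace = record.glucose
    spd = trace.slots_per_day
    step = trace.step_min
    sl = trace.day_slice(day)
    glucose = _interp_nan(trace.values[sl].astype(float))
    n = glucose.size

    t0 = (day - 1) * MINUTES_PER_DAY
    slot_start = t0 + np.arange(n) * step
    hod = (slot_start / 60.0) % 24.0
    tod_sin = np.sin(2 * np.pi * hod / 24.0)
    tod_cos = np.cos(2 * np.pi * hod / 24.0)

    hr = np.full(n, np.nan)
    for k in range(n):
        lo = int(slot_start[k])
        hi = min(lo + step, record.heart_rate.size)
        seg = record.heart_rate[lo:hi]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            hr[k] = seg.mean()
    hr = _interp_nan(hr) if np.isfinite(hr).any() else np.full(n, 65.0)

    exercise = np.zeros(n)
    for a in record.activities:
        a0, a1 = a.t_min, a.t_min + a.duration_min
        for k in range(n):
            lo = slot_start[k]
            hi = lo + step
            overlap = min(hi, a1) - max(lo, a0)
            if overlap > 0:
                exercise[k] += overlap

    nutrients = np.zeros((n, 7))
    for m in record.meals:
        if m.day != day:
            continue
        k = int((m.t_min - t0) // step)
        if 0 <= k < n:
            nutrients[k] += m.nutrients.as_array()

    frames = np.column_stack([glucose, hr, exercise, tod_sin, tod_cos, nutrients])
    return frames


@dataclass
class SequenceSet:
    """Sliding-window training sequences.

    X: (N, L, F) input frames; Y: (N, L) next-step glucose (mg/dL) aligned so
    Y[:, t] is the glucose at frame t+1.
    """

    X: np.ndarray
    Y: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_sequences(
    record: ParticipantRecord,
    sequence_length: int,
    min_days: int = MIN_COMPLETE_DAYS,
    days: list[int] | None = None,
) -> SequenceSet:
    """Sliding windows over each complete day (windows never cross days).

    A day of S steps yields S - L windows; each window of L frames carries L
    next-step glucose targets.
    """
    usable = days if days is not None else complete_days(record)
    if days is None and len(usable) < min_days:
        raise InsufficientDataError(
            f"{len(usable)} complete days < required {min_days}"
        )
    L = sequence_length
    xs, ys = [], []
    for day in usable:
        frames = day_frames(record, day)
        S = frames.shape[0]
        glucose = frames[:, GLUCOSE_CHANNEL]
        for p in range(S - L):
            xs.append(frames[p : p + L])
            ys.append(glucose[p + 1 : p + L + 1])
    if not xs:
        raise InsufficientDataError("no usable sequences")
    return SequenceSet(X=np.stack(xs), Y=np.stack(ys))


def zero_feature_groups(X: np.ndarray, groups: tuple[str, ...]) -> np.ndarray:
    """Copy of X with the named feature groups zeroed (ablation)."""
    out = X.copy()
    for g in groups:
        out[..., list(FEATURE_GROUPS[g])] = 0.0
    return out
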