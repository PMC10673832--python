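"""Core containers shared across the pipeline.

Time is kept as naive minutes since program start (day 1, 00:00 local).
Day indices are 1-based and day boundaries fall at local midnight.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CATEGORIES = ("healthy", "prediabetes", "t2d")

MINUTES_PER_DAY = 1440


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class NoDataError(ValueError):
    """Raised when a metric is requested on a window with no usable samples."""


def day_of_minute(t_min: float) -> int:
    """1-based program day containing minute ``t_min``."""
    return int(t_min // MINUTES_PER_DAY) + 1


@dataclass(frozen=True)
class DayRange:
    """Inclusive 1-based day range, e.g. DayRange(2, 7) = days 2..7."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"invalid day range {self.start}-{self.end}")

    @property
    def n_days(self) -> int:
        return self.end - self.start + 1

    def days(self) -> range:
        return range(self.start, self.end + 1)

    def contains_minute(self, t_min: float) -> bool:
        return (self.start - 1) * MINUTES_PER_DAY <= t_min < self.end * MINUTES_PER_DAY

    def minute_bounds(self) -> tuple[float, float]:
        return (self.start - 1) * MINUTES_PER_DAY, self.end * MINUTES_PER_DAY


@dataclass(frozen=True)
class NutrientVector:
    """Per-meal (or per-serving) nutrient breakdown.

    kcal is the *logged* energy total; it need not equal the energy derived
    from the macronutrient grams (real food logs disagree routinely).
    """

    kcal: float
    carb_g: float
    sugar_g: float
    protein_g: float
    fat_g: float
    satfat_g: float
    fiber_g: float

    _FIELDS = ("kcal", "carb_g", "sugar_g", "protein_g", "fat_g", "satfat_g", "fiber_g")

    def __post_init__(self):
        for name in self._FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"nutrient field {name} must be >= 0, got {v}")
        if self.sugar_g > self.carb_g + 1e-9:
            raise ValidationError("sugar_g cannot exceed carb_g")
        if self.satfat_g > self.fat_g + 1e-9:
            raise ValidationError("satfat_g cannot exceed fat_g")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @staticmethod
    def zero() -> "NutrientVector":
        return NutrientVector(0, 0, 0, 0, 0, 0, 0)

    def macro_kcal(self) -> dict[str, float]:
        """Energy per macronutrient using the 4/9 kcal-per-gram convention
        (carbohydrate, sugar and protein x4; fat and saturated fat x9)."""
        return {
            "carb": 4.0 * self.carb_g,
            "sugar": 4.0 * self.sugar_g,
            "protein": 4.0 * self.protein_g,
            "fat": 9.0 * self.fat_g,
            "satfat": 9.0 * self.satfat_g,
        }


@dataclass(frozen=True)
class MealLog:
    t_min: float
    nutrients: NutrientVector
    name: str = ""

    @property
    def day(self) -> int:
        return day_of_minute(self.t_min)


@dataclass(frozen=True)
class ActivityLog:
    t_min: float
    duration_min: float

    @property
    def day(self) -> int:
        return day_of_minute(self.t_min)


@dataclass
class GlucoseTrace:
    """Uniformly sampled CGM series; NaN marks signal-loss slots.

    Slot i covers minutes [i*step_min, (i+1)*step_min).
    """

    values: np.ndarray
    step_min: int = 15

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.step_min <= 0:
            raise ValidationError("step_min must be positive")
        if MINUTES_PER_DAY % self.step_min:
            raise ValidationError("step_min must divide 1440")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() <= 20 or finite.max() >= 600):
            raise ValidationError("glucose values must lie in (20, 600) mg/dL")

    @property
    def slots_per_day(self) -> int:
        return MINUTES_PER_DAY // self.step_min

    @property
    def n_slots(self) -> int:
        return self.values.size

    @property
    def n_days(self) -> int:
        return int(np.ceil(self.n_slots / self.slots_per_day))

    def slot_times_min(self) -> np.ndarray:
        return np.arange(self.n_slots) * float(self.step_min)

    def day_slice(self, day: int) -> slice:
        if day < 1 or day > self.n_days:
            raise ValidationError(f"day {day} outside trace span 1-{self.n_days}")
        spd = self.slots_per_day
        return slice((day - 1) * spd, min(day * spd, self.n_slots))

    def window_slice(self, window: DayRange) -> slice:
        if window.start > self.n_days:
            raise NoDataError("window does not overlap trace")
        spd = self.slots_per_day
        return slice((window.start - 1) * spd, min(window.end * spd, self.n_slots))

    def window_values(self, window: DayRange) -> np.ndarray:
        return self.values[self.window_slice(window)]


@dataclass
class ParticipantRecord:
    """All streams for one program participant.

    ``heart_rate`` is a per-minute bpm array spanning the program (NaN where
    the monitor was off).  ``weights`` holds (day, lbs) self weigh-ins.
    ``ground_truth`` carries the generator parameters used to build a
    synthetic record so downstream metrics can be recomputed exactly.
    """

    id: str
    category: str
    age: float
    sex: str
    baseline_weight: float
    glucose: GlucoseTrace
    heart_rate: np.ndarray
    meals: list[MealLog] = field(default_factory=list)
    activities: list[ActivityLog] = field(default_factory=list)
    weights: list[tuple[int, float]] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown glycemic category {self.category!r}")
        self.heart_rate = np.asarray(self.heart_rate, dtype=float)
        for _, lbs in self.weights:
            if lbs <= 0:
                raise ValidationError("weights must be positive")

    @property
    def program_days(self) -> int:
        return self.glucose.n_days

    def meals_on_day(self, day: int) -> list[MealLog]:
        return [m for m in self.meals if m.day == day]

    def log_events(self) -> list[float]:
        """Timestamps (minutes) of every app interaction: meal logs,
        activity logs and weigh-ins."""
        events = [m.t_min for m in self.meals]
        events += [a.t_min for a in self.activities]
        events += [(d - 1) * MINUTES_PER_DAY + 8 * 60.0 for d, _ in self.weights]
        return sorted(events)


def meals_in_window(meals: Sequence[MealLog], window: DayRange) -> list[MealLog]:
    return [m for m in meals if window.start <= m.day <= window.end]
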