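"""Food recommendation pipeline and intervention levers.

Four stages: (1) nutrient-profile similarity matching against the queried
food, (2) removal of user-blacklisted items, (3) ranking by a healthiness
score built from carbohydrate and fiber density, (4) cleanup (drop items
with incomplete nutrients or not strictly healthier than the query), then
truncation to k results.

The lever planner covers the five intervention levers: spiking-food
identification from paired meal/CGM history, a personalized calorie target
(Mifflin-St Jeor, capped below maintenance), a sex-specific fiber goal,
post-meal activity, and a 16-h overnight-fast target.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import (
    DayRange,
    MINUTES_PER_DAY,
    GlucoseTrace,
    MealLog,
    NoDataError,
    NutrientVector,
    ValidationError,
)


@dataclass(frozen=True)
class FoodItem:
    id: str
    name: str
    nutrients: NutrientVector
    category: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValidationError("food name must be nonempty")


@dataclass
class RecommendationRequest:
    query: FoodItem
    blacklist: set[str] = field(default_factory=set)
    k: int = 5
    min_similarity: float = 0.5

    def __post_init__(self):
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValidationError("min_similarity must lie in [0, 1]")


def _density_vector(item: FoodItem) -> np.ndarray:
    """Nutrient grams per 100 kcal (serving-size independent)."""
    n = item.nutrients
    if n.kcal <= 0:
        raise ValidationError(f"item {item.id}: zero-kcal density undefined")
    grams = np.array(
        [n.carb_g, n.sugar_g, n.protein_g, n.fat_g, n.satfat_g, n.fiber_g]
    )
    return grams * (100.0 / n.kcal)


def similarity(
    query: FoodItem,
    candidate: FoodItem,
    w_nutrient: float = 0.5,
    w_category: float = 0.5,
) -> float:
    """Blend of nutrient-density cosine similarity and a category match.

    Both components lie in [0, 1] (nutrient vectors are non-negative), so
    with weights summing to 1 the score does too, and similarity(x, x) = 1.
    """
    a = _density_vector(query)
    b = _density_vector(candidate)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        cos = 1.0 if na == nb else 0.0
    else:
        cos = float(np.dot(a, b) / (na * nb))
    cat = 1.0 if (query.category and query.category == candidate.category) else 0.0
    return w_nutrient * cos + w_category * cat


def healthiness_score(item: FoodItem, w_fiber: float = 2.0, w_carb: float = 1.0) -> float:
    """w_f * fiber density - w_c * net-carb density (per 100 kcal); higher is
    healthier."""
    n = item.nutrients
    if n.kcal <= 0:
        raise ValidationError(f"item {item.id}: zero-kcal healthiness undefined")
    per100 = 100.0 / n.kcal
    fiber = n.fiber_g * per100
    net_carb = max(0.0, n.carb_g - n.fiber_g) * per100
    return w_fiber * fiber - w_carb * net_carb


def _has_complete_nutrients(item: FoodItem) -> bool:
    arr = item.nutrients.as_array()
    return bool(np.all(np.isfinite(arr))) and item.nutrients.kcal > 0


def recommend(
    request: RecommendationRequest, database: Sequence[FoodItem]
) -> list[FoodItem]:
    """Run the four stages in order and return at most k items, sorted by
    healthiness descending (ties broken by id for determinism)."""
    if not database:
        raise ValidationError("food database is empty")
    if not _has_complete_nutrients(request.query):
        raise ValidationError("query item has missing nutrients")
    q_health = healthiness_score(request.query)

    # stage 1: similarity matching
    candidates = [
        item
        for item in database
        if _has_complete_nutrients(item)
        and similarity(request.query, item) >= request.min_similarity
    ]
    # stage 2: blacklist removal
    candidates = [c for c in candidates if c.id not in request.blacklist]
    # stage 3: healthiness ranking
    candidates.sort(key=lambda c: (-healthiness_score(c), c.id))
    # stage 4: cleanup — only strictly healthier-than-query survive
    candidates = [c for c in candidates if healthiness_score(c) > q_health]
    return candidates[: request.k]


# ---------------------------------------------------------------------------
# Lever 1: spiking foods from paired meal / CGM history
# ---------------------------------------------------------------------------

@dataclass
class SpikingFood:
    name: str
    mean_iauc: float  # mg/dL * min over 2 h, baseline-subtracted
    mean_peak: float  # mg/dL above pre-meal baseline
    n_exposures: int

    @property
    def low_confidence(self) -> bool:
        return self.n_exposures < 2


def incremental_response(
    trace: GlucoseTrace, t_meal: float, horizon_min: float = 120.0
) -> tuple[float, float] | None:
    """(iAUC, peak) of the 2-h post-meal excursion above the pre-meal
    baseline (median of the 15 min before the log); None if the CGM gap
    leaves no pre- or post-meal samples."""
    step = trace.step_min
    times = trace.slot_times_min()
    pre = trace.values[(times >= t_meal - 15.0) & (times < t_meal)]
    pre = pre[np.isfinite(pre)]
    if pre.size == 0:
        return None
    baseline = float(np.median(pre))
    sel = (times >= t_meal) & (times <= t_meal + horizon_min)
    post = trace.values[sel]
    good = np.isfinite(post)
    if good.sum() < 2:
        return None
    rel_t = times[sel][good]
    excess = post[good] - baseline
    iauc = float(np.trapezoid(excess, rel_t))
    return iauc, float(excess.max())


def identify_spiking_foods(
    history: Sequence[MealLog], trace: GlucoseTrace
) -> list[SpikingFood]:
    """Rank logged foods by mean post-meal glucose impact, descending.

    Order-invariant in the history; meals falling inside CGM gaps contribute
    nothing.  Foods seen fewer than twice are flagged low-confidence.
    """
    by_food: dict[str, list[tuple[float, float]]] = {}
    for meal in history:
        key = meal.name or f"meal@{meal.t_min:.0f}"
        resp = incremental_response(trace, meal.t_min)
        if resp is None:
            continue
        by_food.setdefault(key, []).append(resp)
    if not by_food:
        raise NoDataError("no meals with paired CGM data")
    out = [
        SpikingFood(
            name=name,
            mean_iauc=float(np.mean([r[0] for r in resps])),
            mean_peak=float(np.mean([r[1] for r in resps])),
            n_exposures=len(resps),
        )
        for name, resps in by_food.items()
    ]
    out.sort(key=lambda s: (-s.mean_iauc, s.name))
    return out


# ---------------------------------------------------------------------------
# Levers 2-5
# ---------------------------------------------------------------------------

FIBER_GOAL_G = {"female": (21.0, 25.0), "male": (30.0, 35.0)}
FASTING_TARGET_H = 16.0
DEFAULT_DEFICIT_FACTOR = 0.85  # calorie target relative to maintenance


@dataclass
class UserProfile:
    age_years: float
    weight_kg: float
    height_cm: float
    sex: str  # "male" | "female"
    activity_factor: float = 1.2  # sedentary default

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError("sex must be 'male' or 'female'")
        for f in ("age_years", "weight_kg", "height_cm", "activity_factor"):
            if not math.isfinite(getattr(self, f)) or getattr(self, f) <= 0:
                raise ValidationError(f"profile field {f} must be positive")


@dataclass
class LeverPlan:
    spiking_foods: list[SpikingFood]
    maintenance_kcal: float
    calorie_target_kcal: float
    fiber_goal_g: tuple[float, float]
    activity_suggestion_min_per_day: float
    activity_note: str
    fasting_target_h: float
    achieved_fast_h: float


def mifflin_st_jeor(profile: UserProfile) -> float:
    """Resting energy expenditure, kcal/day."""
    base = 10.0 * profile.weight_kg + 6.25 * profile.height_cm - 5.0 * profile.age_years
    return base + (5.0 if profile.sex == "male" else -161.0)


def maintenance_kcal(profile: UserProfile) -> float:
    return mifflin_st_jeor(profile) * profile.activity_factor


def overnight_fasts(meals: Sequence[MealLog]) -> list[float]:
    """Hours between the last meal of each day and the first meal of the
    next logged day (the daily fasting interval)."""
    by_day: dict[int, list[float]] = {}
    for m in meals:
        by_day.setdefault(m.day, []).append(m.t_min)
    days = sorted(by_day)
    fasts = []
    for prev, nxt in zip(days, days[1:]):
        if nxt != prev + 1:
            continue  # unlogged day between: fast unknown
        fasts.append((min(by_day[nxt]) - max(by_day[prev])) / 60.0)
    return fasts


def lever_plan(
    profile: UserProfile,
    history: Sequence[MealLog],
    trace: GlucoseTrace,
    baseline_activity_min_per_day: float,
    deficit_factor: float = DEFAULT_DEFICIT_FACTOR,
) -> LeverPlan:
    """Assemble all five intervention levers for one user."""
    maint = maintenance_kcal(profile)
    fasts = overnight_fasts(history)
    achieved = float(np.mean(fasts)) if fasts else float("nan")
    try:
        spiking = identify_spiking_foods(history, trace)
    except NoDataError:
        spiking = []
    suggestion = max(30.0, baseline_activity_min_per_day)
    return LeverPlan(
        spiking_foods=spiking,
        maintenance_kcal=maint,
        calorie_target_kcal=maint * deficit_factor,
        fiber_goal_g=FIBER_GOAL_G[profile.sex],
        activity_suggestion_min_per_day=suggestion,
        activity_note="schedule activity after meals to blunt postprandial spikes",
        fasting_target_h=FASTING_TARGET_H,
        achieved_fast_h=achieved,
    )
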