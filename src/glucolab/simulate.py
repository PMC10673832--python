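"""Synthetic cohort generator.

Emulates a 28-day CGM + wearable lifestyle program across three glycemic
categories (healthy, prediabetes, non-insulin-treated T2D): meal-driven
glucose excursions on a 15-min CGM grid, per-minute diurnal heart rate with
exercise bouts, meal/activity/weight logging whose adherence decays over the
program, contiguous CGM signal-loss gaps, and a known injected behavior
change (end-window carbohydrate reduction + activity increase) so every
downstream metric has an exact oracle.

A day's meals exist iff the day is logged: logging adherence therefore
shapes the glucose stream itself, which mirrors how the analysed program can
only see what participants logged.  The *null* configuration used for
statistical calibration removes both the injected effect and the adherence
decay (see ``null_config``).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .types import (
    CATEGORIES,
    MINUTES_PER_DAY,
    ActivityLog,
    GlucoseTrace,
    MealLog,
    NutrientVector,
    ParticipantRecord,
    ValidationError,
)

# Cohort composition observed in the program being emulated:
# 746 normoglycemic / 206 prediabetes / 94 T2D.
DEFAULT_CATEGORY_MIX = (746 / 1046, 206 / 1046, 94 / 1046)

# Nominal per-meal composition (grams); three main meals per logged day.
MEAL_CARB_MEAN, MEAL_CARB_SD = 70.0, 15.0
MEAL_PROTEIN_MEAN, MEAL_PROTEIN_SD = 35.0, 8.0
MEAL_FAT_MEAN, MEAL_FAT_SD = 35.0, 8.0
MEAL_FIBER_MEAN, MEAL_FIBER_SD = 7.0, 3.0
SUGAR_FRAC_MEAN, SUGAR_FRAC_SD = 0.35, 0.08
SATFAT_FRAC_MEAN, SATFAT_FRAC_SD = 0.35, 0.08
MEAL_HOURS = (8.0, 13.0, 19.0)

# Energy-balance bookkeeping: reference intake at nominal meal composition.
REFERENCE_KCAL_PER_DAY = 3 * (
    4.0 * (MEAL_CARB_MEAN + MEAL_PROTEIN_MEAN) + 9.0 * MEAL_FAT_MEAN
)
KCAL_PER_LB = 3500.0

BASAL_BY_CATEGORY = {"healthy": 90.0, "prediabetes": 105.0, "t2d": 135.0}
WEIGHT_MEAN_BY_CATEGORY = {"healthy": 180.0, "prediabetes": 200.0, "t2d": 215.0}

ACTIVITY_BASE_PROB = 0.75  # chance of an exercise session on a given day
ACTIVITY_KCAL_PER_MIN = 4.0
WEIGH_IN_DAYS = (2, 7, 14, 21, 27)
WEIGH_IN_PROB = 0.6


@dataclass(frozen=True)
class MealResponseParams:
    """Gamma-like incremental glucose kernel for one meal.

    Peak height is ``amplitude * carb_g * max(0, 1 - fiber_atten * fiber_g)``
    mg/dL; the peak occurs ``rise_min`` minutes post-meal and the tail decays
    with time constant ``rise_min / alpha`` where ``alpha = rise_min /
    decay_min``, so ``decay_min`` is the late-tail e-folding time.
    """

    amplitude: float = 1.0  # mg/dL per gram of carbohydrate
    fiber_atten: float = 0.02  # fractional attenuation per gram of fiber
    rise_min: float = 40.0  # time to peak, minutes
    decay_min: float = 20.0  # tail time constant, minutes

    def __post_init__(self):
        if self.rise_min <= 0 or self.decay_min <= 0:
            raise ValidationError("kernel time constants must be positive")
        if self.amplitude < 0 or self.fiber_atten < 0:
            raise ValidationError("kernel amplitudes must be non-negative")


@dataclass(frozen=True)
class EffectConfig:
    """Injected end-of-program behavior change (days >= start_day)."""

    carb_reduction: float = 0.30  # fractional cut in per-meal carbohydrate
    activity_increase: float = 1.0  # fractional rise in session probability
    start_day: int = 15


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 100
    category_mix: tuple[float, float, float] = DEFAULT_CATEGORY_MIX
    program_days: int = 28
    cgm_step: int = 15
    basal_glucose_by_category: dict = field(
        default_factory=lambda: dict(BASAL_BY_CATEGORY)
    )
    meal_response: MealResponseParams = MealResponseParams()
    circadian_amp_range: tuple[float, float] = (3.0, 7.0)  # mg/dL, dawn peak
    noise_sd: float = 5.0  # mg/dL white CGM noise
    adherence_start: float = 0.81  # fraction of days logged, day 1
    adherence_end: float = 0.43  # fraction of days logged, final day
    signal_loss_fraction: float = 0.08
    effect: EffectConfig = EffectConfig()
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValidationError("n_participants must be positive")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValidationError("category_mix must sum to 1")
        if not (0 <= self.adherence_start <= 1 and 0 <= self.adherence_end <= 1):
            raise ValidationError("adherence must lie in [0, 1]")
        if not 0 <= self.signal_loss_fraction < 1:
            raise ValidationError("signal_loss_fraction must lie in [0, 1)")
        if self.program_days <= 0 or self.cgm_step <= 0:
            raise ValidationError("program_days and cgm_step must be positive")


def null_config(**overrides) -> GeneratorConfig:
    """Configuration with no systematic baseline-vs-end difference.

    Used for type-I-error calibration: both the injected effect and the
    adherence decay are behavior changes, so both are switched off.
    """
    base = dict(
        effect=EffectConfig(carb_reduction=0.0, activity_increase=0.0),
        adherence_start=0.81,
        adherence_end=0.81,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def cgp_training_config(**overrides) -> GeneratorConfig:
    """Model-development scenario: fully logged, gap-free days so every day
    satisfies the predictor's complete-day rule."""
    base = dict(
        adherence_start=1.0,
        adherence_end=1.0,
        signal_loss_fraction=0.0,
        effect=EffectConfig(carb_reduction=0.0, activity_increase=0.0),
    )
    base.update(overrides)
    return GeneratorConfig(**base)


# ---------------------------------------------------------------------------
# Meal kernel
# ---------------------------------------------------------------------------

def kernel_shape(t_min: np.ndarray, params: MealResponseParams) -> np.ndarray:
    """Unit-peak gamma-like shape (t/tp)^a * exp(a*(1 - t/tp)), zero for t<=0.

    Peaks at exactly t = rise_min with value 1.
    """
    t = np.asarray(t_min, dtype=float)
    a = params.rise_min / params.decay_min
    x = np.clip(t / params.rise_min, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x > 0, np.power(x, a) * np.exp(a * (1.0 - x)), 0.0)
    return out


def meal_peak_height(nutrients: NutrientVector, params: MealResponseParams) -> float:
    return (
        params.amplitude
        * nutrients.carb_g
        * max(0.0, 1.0 - params.fiber_atten * nutrients.fiber_g)
    )


def meal_response(
    nutrients: NutrientVector,
    params: MealResponseParams | None = None,
    step_min: int = 15,
    horizon_min: float = 240.0,
) -> np.ndarray:
    """Incremental glucose curve (mg/dL) on a post-meal grid.

    Grid point k is ``k * step_min`` minutes after the meal, k = 0..horizon.
    The curve starts at 0, is non-negative, and with the default time
    constants has decayed below 1 mg/dL by 4 h for realistic carb loads.
    """
    params = params or MealResponseParams()
    if min(nutrients.as_array()) < 0:  # NutrientVector already validates
        raise ValidationError("negative nutrient values")
    n = int(round(horizon_min / step_min)) + 1
    t = np.arange(n) * float(step_min)
    return meal_peak_height(nutrients, params) * kernel_shape(t, params)


# ---------------------------------------------------------------------------
# Participant generation
# ---------------------------------------------------------------------------

def _participant_rng(seed: int, pid: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(pid.encode())])
    )


def adherence_on_day(cfg: GeneratorConfig, day: int) -> float:
    """Linear interpolation of logging adherence over the program."""
    if cfg.program_days == 1:
        return cfg.adherence_start
    frac = (day - 1) / (cfg.program_days - 1)
    return cfg.adherence_start + frac * (cfg.adherence_end - cfg.adherence_start)


def _draw_meal(
    rng: np.random.Generator, day: int, hour: float, carb_scale: float
) -> MealLog:
    t = (day - 1) * MINUTES_PER_DAY + (hour + rng.uniform(-1.0, 1.0)) * 60.0
    t = float(np.clip(t, (day - 1) * MINUTES_PER_DAY, day * MINUTES_PER_DAY - 1))
    carb = max(10.0, rng.normal(MEAL_CARB_MEAN, MEAL_CARB_SD)) * carb_scale
    sugar = carb * float(np.clip(rng.normal(SUGAR_FRAC_MEAN, SUGAR_FRAC_SD), 0.05, 0.8))
    protein = max(5.0, rng.normal(MEAL_PROTEIN_MEAN, MEAL_PROTEIN_SD))
    fat = max(5.0, rng.normal(MEAL_FAT_MEAN, MEAL_FAT_SD))
    satfat = fat * float(np.clip(rng.normal(SATFAT_FRAC_MEAN, SATFAT_FRAC_SD), 0.05, 0.9))
    fiber = max(0.0, rng.normal(MEAL_FIBER_MEAN, MEAL_FIBER_SD))
    kcal = 4.0 * (carb + protein) + 9.0 * fat
    return MealLog(
        t_min=t,
        nutrients=NutrientVector(kcal, carb, sugar, protein, fat, satfat, fiber),
    )


def _place_signal_loss(
    rng: np.random.Generator, n_slots: int, fraction: float
) -> np.ndarray:
    """Boolean missing mask with contiguous 1-8 h gaps hitting the target
    missing count exactly (up to rounding)."""
    mask = np.zeros(n_slots, dtype=bool)
    target = int(round(fraction * n_slots))
    guard = 0
    while mask.sum() < target and guard < 10_000:
        guard += 1
        remaining = target - int(mask.sum())
        length = int(rng.integers(4, 33))  # 1-8 h in 15-min slots
        length = min(length, remaining, n_slots)
        pos = int(rng.integers(0, max(1, n_slots - length + 1)))
        seg = mask[pos : pos + length]
        new = int(length - seg.sum())
        if new > remaining:
            # trim the tail of this gap so the total lands exactly on target
            idx = np.flatnonzero(~seg)[:remaining]
            seg[idx] = True
        else:
            seg[:] = True
    return mask


def generate_participant(
    cfg: GeneratorConfig, category: str, pid: str, seed: int | None = None
) -> ParticipantRecord:
    """Build one synthetic participant; deterministic given (seed, pid)."""
    if category not in CATEGORIES:
        raise ValidationError(f"unknown glycemic category {category!r}")
    seed = cfg.seed if seed is None else seed
    rng = _participant_rng(seed, pid)

    days = cfg.program_days
    spd = MINUTES_PER_DAY // cfg.cgm_step
    n_slots = days * spd

    age = float(np.clip(rng.normal(49.0, 11.5), 18.0, 85.0))
    sex = "male" if rng.random() < 0.49 else "female"
    baseline_weight = float(
        np.clip(rng.normal(WEIGHT_MEAN_BY_CATEGORY[category], 35.0), 110.0, 330.0)
    )
    basal = cfg.basal_glucose_by_category[category] + rng.normal(0.0, 5.0)
    circ_amp = rng.uniform(*cfg.circadian_amp_range)

    # --- meals: a day is logged with probability adherence(day) ------------
    meals: list[MealLog] = []
    logged_days: list[int] = []
    for day in range(1, days + 1):
        if rng.random() >= adherence_on_day(cfg, day):
            continue
        logged_days.append(day)
        scale = (
            1.0 - cfg.effect.carb_reduction
            if day >= cfg.effect.start_day
            else 1.0
        )
        for hour in MEAL_HOURS:
            meals.append(_draw_meal(rng, day, hour, scale))
    meals.sort(key=lambda m: m.t_min)

    # --- glucose on the CGM grid -------------------------------------------
    t_slots = np.arange(n_slots) * float(cfg.cgm_step)
    hod = (t_slots / 60.0) % 24.0
    glucose = basal + circ_amp * np.cos(2.0 * np.pi * (hod - 7.0) / 24.0)
    for m in meals:
        dt = t_slots - m.t_min
        sel = (dt > 0) & (dt <= 300.0)
        glucose[sel] += meal_peak_height(m.nutrients, cfg.meal_response) * kernel_shape(
            dt[sel], cfg.meal_response
        )
    if cfg.noise_sd > 0:
        glucose += rng.normal(0.0, cfg.noise_sd, size=n_slots)
    glucose = np.clip(glucose, 45.0, 500.0)

    missing = _place_signal_loss(rng, n_slots, cfg.signal_loss_fraction)
    glucose = glucose.copy()
    glucose[missing] = np.nan
    trace = GlucoseTrace(values=glucose, step_min=cfg.cgm_step)

    # --- activity sessions --------------------------------------------------
    activities: list[ActivityLog] = []
    for day in range(1, days + 1):
        p = ACTIVITY_BASE_PROB
        if day >= cfg.effect.start_day:
            p = min(0.95, p * (1.0 + cfg.effect.activity_increase))
        if rng.random() < p:
            start_h = rng.uniform(6.0, 20.0)
            dur = rng.uniform(25.0, 50.0)
            activities.append(
                ActivityLog(
                    t_min=(day - 1) * MINUTES_PER_DAY + start_h * 60.0,
                    duration_min=float(dur),
                )
            )

    # --- per-minute heart rate ---------------------------------------------
    n_min = days * MINUTES_PER_DAY
    rest = rng.normal(62.0, 5.0)
    t_minute = np.arange(n_min, dtype=float)
    hod_m = (t_minute / 60.0) % 24.0
    hr = rest + 6.0 * np.sin(2.0 * np.pi * (hod_m - 9.0) / 24.0)
    hr += rng.normal(0.0, 3.0, size=n_min)
    for a in activities:
        i0 = int(a.t_min)
        i1 = min(n_min, i0 + int(a.duration_min))
        hr[i0:i1] = rng.uniform(115.0, 135.0) + rng.normal(0.0, 3.0, size=i1 - i0)
    hr = np.clip(hr, 40.0, 200.0)

    # --- body weight from energy balance ------------------------------------
    kcal_by_day = np.zeros(days + 1)
    for m in meals:
        kcal_by_day[m.day] += m.nutrients.kcal
    burn_by_day = np.zeros(days + 1)
    for a in activities:
        burn_by_day[a.day] += ACTIVITY_KCAL_PER_MIN * a.duration_min
    ref_burn = ACTIVITY_BASE_PROB * 37.5 * ACTIVITY_KCAL_PER_MIN
    deficit = np.zeros(days + 1)
    for day in range(1, days + 1):
        d = burn_by_day[day] - ref_burn
        if kcal_by_day[day] > 0:  # only logged days carry intake information
            d += REFERENCE_KCAL_PER_DAY - kcal_by_day[day]
        deficit[day] = d
    cum_deficit = np.cumsum(deficit)
    weights: list[tuple[int, float]] = []
    for day in WEIGH_IN_DAYS:
        if day <= days and rng.random() < WEIGH_IN_PROB:
            w = baseline_weight - cum_deficit[day] / KCAL_PER_LB + rng.normal(0.0, 0.6)
            weights.append((day, float(max(80.0, w))))

    ground_truth = {
        "basal": float(basal),
        "circadian_amp": float(circ_amp),
        "kernel": {
            "amplitude": cfg.meal_response.amplitude,
            "fiber_atten": cfg.meal_response.fiber_atten,
            "rise_min": cfg.meal_response.rise_min,
            "decay_min": cfg.meal_response.decay_min,
        },
        "logged_days": logged_days,
        "noise_sd": cfg.noise_sd,
        "effect": {
            "carb_reduction": cfg.effect.carb_reduction,
            "activity_increase": cfg.effect.activity_increase,
            "start_day": cfg.effect.start_day,
        },
        "reference_kcal_per_day": REFERENCE_KCAL_PER_DAY,
    }

    return ParticipantRecord(
        id=pid,
        category=category,
        age=age,
        sex=sex,
        baseline_weight=baseline_weight,
        glucose=trace,
        heart_rate=hr,
        meals=meals,
        activities=activities,
        weights=weights,
        ground_truth=ground_truth,
    )


def apportion_categories(n: int, mix: tuple[float, float, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n participants over categories."""
    raw = [n * p for p in mix]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in range(short):
        counts[order[i]] += 1
    return dict(zip(CATEGORIES, counts))


def generate_cohort(cfg: GeneratorConfig) -> list[ParticipantRecord]:
    """Generate n_participants records; reproducible from cfg.seed."""
    counts = apportion_categories(cfg.n_participants, cfg.category_mix)
    cohort: list[ParticipantRecord] = []
    idx = 0
    for category in CATEGORIES:
        for _ in range(counts[category]):
            idx += 1
            pid = f"P{idx:05d}"
            cohort.append(generate_participant(cfg, category, pid, cfg.seed))
    return cohort


# ---------------------------------------------------------------------------
# Analytic expectations for the injected effect (oracle for recovery tests)
# ---------------------------------------------------------------------------

def expected_carb_ratio(carb_scale: float = 1.0) -> float:
    """Expected carb-kcal : total-kcal ratio at nominal meal composition
    when per-meal carbohydrate is scaled by ``carb_scale``."""
    carb_kcal = 4.0 * MEAL_CARB_MEAN * carb_scale
    total = carb_kcal + 4.0 * MEAL_PROTEIN_MEAN + 9.0 * MEAL_FAT_MEAN
    return carb_kcal / total


def _count_distribution(probs: list[float]) -> np.ndarray:
    """Poisson-binomial pmf of how many of the given days get logged."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def _window_carb_ratio(cfg: GeneratorConfig, start_day: int, end_day: int) -> float:
    """Expected per-participant pooled carb:kcal ratio over a day window.

    The per-participant ratio is a ratio of sums over that participant's
    logged days, so when the window straddles the effect onset the expected
    ratio is an average over the joint distribution of (pre-effect,
    post-effect) logged-day counts, each day at the nominal meal
    composition; windows entirely on one side reduce to a constant ratio.
    Conditioned on at least one logged day (the analysis requires one).
    """
    def day_terms(day: int) -> tuple[float, float]:
        scale = 1.0 - cfg.effect.carb_reduction if day >= cfg.effect.start_day else 1.0
        carb_kcal = 4.0 * MEAL_CARB_MEAN * scale
        total = carb_kcal + 4.0 * MEAL_PROTEIN_MEAN + 9.0 * MEAL_FAT_MEAN
        return carb_kcal, total

    pre = [d for d in range(start_day, end_day + 1) if d < cfg.effect.start_day]
    post = [d for d in range(start_day, end_day + 1) if d >= cfg.effect.start_day]
    c_pre, k_pre = day_terms(pre[0]) if pre else (0.0, 0.0)
    c_post, k_post = day_terms(post[0]) if post else (0.0, 0.0)
    pmf_pre = _count_distribution([adherence_on_day(cfg, d) for d in pre])
    pmf_post = _count_distribution([adherence_on_day(cfg, d) for d in post])

    num = 0.0
    mass = 0.0
    for i, pi in enumerate(pmf_pre):
        for j, pj in enumerate(pmf_post):
            if i + j == 0:
                continue
            w = pi * pj
            num += w * (i * c_pre + j * c_post) / (i * k_pre + j * k_post)
            mass += w
    return num / mass


def expected_carb_ratio_delta(
    cfg: GeneratorConfig,
    baseline_days: tuple[int, int] = (1, 7),
    end_days: tuple[int, int] = (14, 28),
) -> float:
    """Analytic expectation of the end-minus-baseline carb:kcal ratio change
    induced by the generator's injected carbohydrate reduction, for the
    analysis windows actually used (the end window may include pre-effect
    days)."""
    return _window_carb_ratio(cfg, *end_days) - _window_carb_ratio(cfg, *baseline_days)
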