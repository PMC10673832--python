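"""Shared fixtures: hand-built participant records and small synthetic
cohorts (generated at test time, nothing on disk)."""
from __future__ import annotations

import numpy as np
import pytest

from glucolab.simulate import GeneratorConfig, generate_cohort
from glucolab.types import (
    GlucoseTrace,
    MealLog,
    NutrientVector,
    ParticipantRecord,
)

SLOTS_PER_DAY = 96


def make_trace(days: int = 28, value: float = 100.0, step: int = 15) -> GlucoseTrace:
    return GlucoseTrace(values=np.full(days * (1440 // step), value), step_min=step)


def make_meal(day: int, hour: float, kcal: float = 800.0, carb: float = 80.0,
              fiber: float = 5.0, name: str = "") -> MealLog:
    return MealLog(
        t_min=(day - 1) * 1440 + hour * 60.0,
        nutrients=NutrientVector(
            kcal=kcal, carb_g=carb, sugar_g=carb * 0.3, protein_g=30.0,
            fat_g=25.0, satfat_g=8.0, fiber_g=fiber,
        ),
        name=name,
    )


def make_record(
    pid: str = "X001",
    category: str = "healthy",
    days: int = 28,
    glucose: np.ndarray | None = None,
    hr: np.ndarray | None = None,
    meals=None,
    activities=None,
    weights=None,
) -> ParticipantRecord:
    """Fully-specified record; defaults give a clean full-capture subject
    with two good meals per day and weigh-ins in both windows."""
    if glucose is None:
        glucose = np.full(days * SLOTS_PER_DAY, 100.0)
    if hr is None:
        hr = np.full(days * 1440, 70.0)
    if meals is None:
        meals = [make_meal(d, h) for d in range(1, days + 1) for h in (8.0, 19.0)]
    if weights is None:
        weights = [(2, 200.0), (27, 195.0)]
    return ParticipantRecord(
        id=pid,
        category=category,
        age=49.0,
        sex="female",
        baseline_weight=200.0,
        glucose=GlucoseTrace(values=np.asarray(glucose, dtype=float)),
        heart_rate=np.asarray(hr, dtype=float),
        meals=list(meals),
        activities=list(activities or []),
        weights=list(weights),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """40-participant default-condition cohort, generated once per session."""
    return generate_cohort(GeneratorConfig(n_participants=40, seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    from glucolab.simulate import null_config

    return generate_cohort(null_config(n_participants=40, seed=17))
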