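"""Cohort serialization: one directory per cohort with long-format CSVs
(participants, glucose, hr, meals, activity, weights) plus ground_truth.json.

Timestamps are written as ISO-8601 from a nominal program start date; they
round-trip exactly through minutes-since-start.
"""
from __future__ import annotations

import json
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ActivityLog,
    GlucoseTrace,
    MealLog,
    NutrientVector,
    ParticipantRecord,
)

PROGRAM_EPOCH = datetime(2023, 1, 2, 0, 0, 0)

NUTRIENT_COLS = ["kcal", "carb_g", "sugar_g", "protein_g", "fat_g", "satfat_g",
                 "fiber_g"]


def _iso(t_min: float) -> str:
    return (PROGRAM_EPOCH + timedelta(minutes=float(t_min))).isoformat()


def _minutes(iso: str) -> float:
    return (datetime.fromisoformat(iso) - PROGRAM_EPOCH).total_seconds() / 60.0


def write_cohort(cohort: Sequence[ParticipantRecord], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "id": r.id, "category": r.category, "age": r.age, "sex": r.sex,
                "baseline_weight_lbs": r.baseline_weight,
                "program_days": r.program_days,
            }
            for r in cohort
        ]
    ).to_csv(out / "participants.csv", index=False)

    glu_rows = []
    for r in cohort:
        t = r.glucose.slot_times_min()
        ok = np.isfinite(r.glucose.values)
        for tm, v in zip(t[ok], r.glucose.values[ok]):
            glu_rows.append({"id": r.id, "timestamp": _iso(tm), "value": round(v, 3)})
    pd.DataFrame(glu_rows).to_csv(out / "glucose.csv", index=False)

    hr_rows = []
    for r in cohort:
        ok = np.isfinite(r.heart_rate)
        idx = np.flatnonzero(ok)
        for i in idx:
            hr_rows.append(
                {"id": r.id, "timestamp": _iso(float(i)),
                 "value": round(float(r.heart_rate[i]), 2)}
            )
    pd.DataFrame(hr_rows).to_csv(out / "hr.csv", index=False)

    meal_rows = []
    for r in cohort:
        for m in r.meals:
            row = {"id": r.id, "timestamp": _iso(m.t_min), "name": m.name}
            row.update(
                {c: round(getattr(m.nutrients, c), 3) for c in NUTRIENT_COLS}
            )
            meal_rows.append(row)
    pd.DataFrame(meal_rows).to_csv(out / "meals.csv", index=False)

    pd.DataFrame(
        [
            {"id": r.id, "timestamp": _iso(a.t_min),
             "duration_min": round(a.duration_min, 2)}
            for r in cohort
            for a in r.activities
        ]
    ).to_csv(out / "activity.csv", index=False)

    pd.DataFrame(
        [
            {"id": r.id, "day": d, "weight_lbs": round(w, 2)}
            for r in cohort
            for d, w in r.weights
        ]
    ).to_csv(out / "weights.csv", index=False)

    with open(out / "ground_truth.json", "w") as fh:
        json.dump({r.id: r.ground_truth for r in cohort}, fh, indent=1)
    return out


def read_cohort(in_dir: str | Path, cgm_step: int = 15) -> list[ParticipantRecord]:
    src = Path(in_dir)
    participants = pd.read_csv(src / "participants.csv")
    glucose = pd.read_csv(src / "glucose.csv")
    hr = pd.read_csv(src / "hr.csv")
    meals = pd.read_csv(src / "meals.csv") if (src / "meals.csv").stat().st_size else None
    activity = pd.read_csv(src / "activity.csv")
    weights = pd.read_csv(src / "weights.csv")
    with open(src / "ground_truth.json") as fh:
        gt = json.load(fh)

    out = []
    for _, row in participants.iterrows():
        pid = row["id"]
        days = int(row["program_days"])
        spd = 1440 // cgm_step

        values = np.full(days * spd, np.nan)
        sub = glucose[glucose["id"] == pid]
        for ts, v in zip(sub["timestamp"], sub["value"]):
            values[int(round(_minutes(ts))) // cgm_step] = v
        trace = GlucoseTrace(values=values, step_min=cgm_step)

        hr_arr = np.full(days * 1440, np.nan)
        sub = hr[hr["id"] == pid]
        for ts, v in zip(sub["timestamp"], sub["value"]):
            hr_arr[int(round(_minutes(ts)))] = v

        meal_list = []
        if meals is not None:
            for _, m in meals[meals["id"] == pid].iterrows():
                meal_list.append(
                    MealLog(
                        t_min=_minutes(m["timestamp"]),
                        nutrients=NutrientVector(
                            *[float(m[c]) for c in NUTRIENT_COLS]
                        ),
                        name=str(m.get("name", "") or ""),
                    )
                )
        act_list = [
            ActivityLog(t_min=_minutes(a["timestamp"]),
                        duration_min=float(a["duration_min"]))
            for _, a in activity[activity["id"] == pid].iterrows()
        ]
        weight_list = [
            (int(w["day"]), float(w["weight_lbs"]))
            for _, w in weights[weights["id"] == pid].iterrows()
        ]
        out.append(
            ParticipantRecord(
                id=pid,
                category=row["category"],
                age=float(row["age"]),
                sex=row["sex"],
                baseline_weight=float(row["baseline_weight_lbs"]),
                glucose=trace,
                heart_rate=hr_arr,
                meals=sorted(meal_list, key=lambda m: m.t_min),
                activities=sorted(act_list, key=lambda a: a.t_min),
                weights=sorted(weight_list),
                ground_truth=gt.get(pid, {}),
            )
        )
    return out
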