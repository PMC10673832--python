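"""Diet, activity, heart-rate and weight outcomes with logging-bias
adjustments; writes behavior.csv and nutrient_changes.csv (the percent
change in each macronutrient:kcal ratio, per glycemic category).
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from glucolab.behavior import (
    DIET_BASELINE,
    END_WINDOW,
    behavior_summary,
    nutrient_summary,
    weight_strata_report,
)
from glucolab.io import read_cohort
from glucolab.types import NoDataError

ROOT = Path(__file__).resolve().parents[1]

RATIOS = ("carb", "sugar", "protein", "fat", "satfat")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default=ROOT / "results" / "cohort")
    ap.add_argument("--qc", default=ROOT / "results" / "qc_report.csv")
    ap.add_argument("--out-dir", default=ROOT / "results")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    qc = pd.read_csv(args.qc)
    glucose_set = set(qc.loc[qc["glucose_set"], "id"])
    diet_set = set(qc.loc[qc["diet_set"], "id"])
    weight_set = set(qc.loc[qc["weight_set"], "id"])

    rows = []
    for rec in cohort:
        if rec.id not in glucose_set:
            continue
        row = {"id": rec.id, "category": rec.category}
        row.update(behavior_summary(rec))
        if rec.id in diet_set:
            for name, window in (("base", DIET_BASELINE), ("end", END_WINDOW)):
                try:
                    s = nutrient_summary(rec.meals, window)
                    row[f"kcal_{name}"] = s.mean_daily_kcal
                    row[f"fiber_per_kcal_{name}"] = s.fiber_per_kcal
                    for r in RATIOS:
                        row[f"{r}_ratio_{name}"] = s.ratios[r]
                except NoDataError:
                    pass
        rows.append(row)
    df = pd.DataFrame(rows)
    out_dir = Path(args.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "behavior.csv", index=False)

    # percent change in ratio metrics, per category and overall
    chg_rows = []
    for cat, sub in [("all", df)] + [(c, df[df.category == c]) for c in
                                     ("healthy", "prediabetes", "t2d")]:
        entry = {"category": cat, "n": int(sub["kcal_base"].notna().sum())
                 if "kcal_base" in sub else 0}
        if entry["n"] == 0:
            continue
        for col in ["kcal"] + [f"{r}_ratio" for r in RATIOS] + ["fiber_per_kcal"]:
            b = sub.get(f"{col}_base")
            e = sub.get(f"{col}_end")
            if b is None:
                continue
            ok = b.notna() & e.notna() & (b != 0)
            entry[f"{col}_pct_change"] = float(
                (100 * (e[ok] - b[ok]) / b[ok]).mean()
            )
        chg_rows.append(entry)
    pd.DataFrame(chg_rows).to_csv(out_dir / "nutrient_changes.csv", index=False)

    strata = weight_strata_report(cohort, include_ids=weight_set)
    pd.DataFrame(
        [{"stratum": k[0], "horizon": k[1], **v} for k, v in strata.items()]
    ).to_csv(out_dir / "weight_strata.csv", index=False)

    print(f"behavior metrics for {len(df)} participants -> behavior.csv")
    allrow = chg_rows[0] if chg_rows else {}
    if allrow:
        print(f"  kcal change: {allrow.get('kcal_pct_change', float('nan')):+.1f}%")
        print(f"  carb:kcal ratio change: "
              f"{allrow.get('carb_ratio_pct_change', float('nan')):+.1f}%")
    wd = df["weight_delta_lbs"].dropna()
    if len(wd):
        print(f"  mean weight change: {wd.mean():+.2f} lbs "
              f"({df['weight_delta_pct'].dropna().mean():+.2f}%) on n={len(wd)}")
    hr_b, hr_e = df["hr110_baseline"].dropna(), df["hr110_end"].dropna()
    print(f"  HR>110 min/day: {hr_b.mean():.1f} -> {hr_e.mean():.1f}")


if __name__ == "__main__":
    main()
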