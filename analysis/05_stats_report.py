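"""Paired baseline-vs-end statistics over glycemic, dietary and behavior
outcomes; writes report tables plus a plain-text summary.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from glucolab.glycemic import AnalysisWindows, participant_deltas
from glucolab.io import read_cohort
from glucolab.stats import cohort_report

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default=ROOT / "results" / "cohort")
    ap.add_argument("--qc", default=ROOT / "results" / "qc_report.csv")
    ap.add_argument("--behavior", default=ROOT / "results" / "behavior.csv")
    ap.add_argument("--out-dir", default=ROOT / "results" / "report")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    qc = pd.read_csv(args.qc)
    glucose_set = set(qc.loc[qc["glucose_set"], "id"])
    deltas = participant_deltas(cohort, AnalysisWindows(), include_ids=glucose_set)

    beh = pd.read_csv(args.behavior)
    nutrient_pairs = {}
    for col in ("carb_ratio", "sugar_ratio", "protein_ratio", "fat_ratio",
                "satfat_ratio", "kcal", "fiber_per_kcal"):
        b, e = f"{col}_base", f"{col}_end"
        if b in beh and e in beh:
            nutrient_pairs[col] = (beh[b].to_numpy(), beh[e].to_numpy())
    behavior_pairs = {
        "hr110_min_per_day": (beh["hr110_baseline"].to_numpy(),
                              beh["hr110_end"].to_numpy()),
        "adjusted_activity": (beh["adjusted_activity_baseline"].to_numpy(),
                              beh["adjusted_activity_end"].to_numpy()),
        "weight_lbs": (beh["weight_first"].to_numpy(),
                       beh["weight_last"].to_numpy()),
    }

    report = cohort_report(deltas, nutrient_pairs, behavior_pairs)

    out_dir = Path(args.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (group, category), entry in report["glycemic"].items():
        for metric, c in entry.items():
            rows.append({
                "subgroup": group, "category": category, "metric": metric,
                "n": c.n, "mean_baseline": c.mean_baseline,
                "mean_end": c.mean_end, "mean_delta": c.mean_delta,
                "t": c.t_stat, "p": c.p_value, "normal": c.normal_deltas,
                "degenerate": c.degenerate,
            })
    pd.DataFrame(rows).to_csv(out_dir / "glycemic_tests.csv", index=False)

    other_rows = []
    for section in ("nutrients", "behavior"):
        for name, c in report[section].items():
            other_rows.append({
                "section": section, "metric": name, "n": c.n,
                "mean_baseline": c.mean_baseline, "mean_end": c.mean_end,
                "mean_delta": c.mean_delta, "t": c.t_stat, "p": c.p_value,
            })
    pd.DataFrame(other_rows).to_csv(out_dir / "behavior_tests.csv", index=False)

    lines = ["paired baseline-vs-end comparisons (alpha = 0.05)", ""]
    key = ("overall", "all")
    if key in report["glycemic"]:
        for metric, c in report["glycemic"][key].items():
            star = "*" if c.significant else " "
            lines.append(
                f"  {metric:<13} n={c.n:<4} delta={c.mean_delta:+8.3f} "
                f"t={c.t_stat:+7.2f} p={c.p_value:.2e} {star}"
            )
    lines.append("")
    for row in other_rows:
        sig = "*" if row["p"] < 0.05 else " "
        lines.append(
            f"  {row['metric']:<18} n={row['n']:<4} "
            f"delta={row['mean_delta']:+10.4f} p={row['p']:.2e} {sig}"
        )
    text = "\n".join(lines)
    (out_dir / "summary.txt").write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
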