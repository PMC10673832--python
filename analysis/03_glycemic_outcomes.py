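"""Per-window glycemic metrics and baseline-vs-end subgroup deltas.

Writes metrics.csv (one row per participant x window) and subgroups.csv
(mean change per baseline-defined subgroup and glycemic category).
"""
import argparse
from pathlib import Path

import pandas as pd

from glucolab.glycemic import (
    AnalysisWindows,
    participant_deltas,
    subgroup_deltas,
)
from glucolab.io import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default=ROOT / "results" / "cohort")
    ap.add_argument("--qc", default=ROOT / "results" / "qc_report.csv")
    ap.add_argument("--out-dir", default=ROOT / "results")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    qc = pd.read_csv(args.qc)
    glucose_set = set(qc.loc[qc["glucose_set"], "id"])
    deltas = participant_deltas(cohort, AnalysisWindows(), include_ids=glucose_set)

    rows = []
    for d in deltas:
        for window, s in (("baseline", d.baseline), ("end", d.end)):
            rows.append({
                "id": d.id, "category": d.category, "window": window,
                "tir_pct": s.tir_pct, "gmi_pct": s.gmi_pct, "cv_pct": s.cv_pct,
                "mean_glucose": s.mean_glucose,
                "lost_time_fraction": s.lost_time_fraction,
                **{f"events_{k}": v for k, v in s.events_per_day.items()},
            })
    out_dir = Path(args.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)

    table = subgroup_deltas(deltas)
    sub_rows = []
    for (group, category), entry in table.items():
        row = {"subgroup": group, "category": category, "n": entry["n"]}
        for metric, vals in entry.items():
            if metric == "n":
                continue
            row[f"d_{metric}"] = vals["mean_delta"]
        sub_rows.append(row)
    pd.DataFrame(sub_rows).to_csv(out_dir / "subgroups.csv", index=False)

    print(f"{len(deltas)} participants with both windows -> metrics.csv")
    key = ("overall", "all")
    print(f"  overall mean dTIR: {table[key]['tir_pct']['mean_delta']:+.2f} pct pts")
    print(f"  overall mean dGMI: {table[key]['gmi_pct']['mean_delta']:+.3f} pct pts")
    print(f"  overall mean dCV:  {table[key]['cv_pct']['mean_delta']:+.2f} pct pts")
    for sub in ("tir_lt_90", "tir_lt_70", "gmi_gt_6", "gmi_gt_7"):
        k = (sub, "all")
        if k in table:
            print(f"  {sub} (n={table[k]['n']}): "
                  f"dTIR {table[k]['tir_pct']['mean_delta']:+.2f}, "
                  f"dGMI {table[k]['gmi_pct']['mean_delta']:+.3f}")


if __name__ == "__main__":
    main()
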