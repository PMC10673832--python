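"""Apply the inclusion criteria to results/cohort/ and write qc_report.csv.

Rules: >=70% CGM coverage on at least half the days of the baseline and end
QC windows; active logging (>=2 events/day) on at least half the days of
the first week and last two weeks; a weigh-in in both weight windows; >=20h
HR capture per day.  Participants with resting HR > 110 bpm stay in the
glucose analyses but are flagged out of HR measures.
"""
import argparse
from pathlib import Path

import pandas as pd

from glucolab.io import read_cohort
from glucolab.qc import QcThresholds, select_analysis_sets

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default=ROOT / "results" / "cohort")
    ap.add_argument("--out", default=ROOT / "results" / "qc_report.csv")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    report = select_analysis_sets(cohort, QcThresholds())
    df = pd.DataFrame(report.rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    print(f"QC on {len(cohort)} participants -> {args.out}")
    for key in ("cgm_ok", "meals_ok", "weight_ok", "hr_ok"):
        print(f"  {key}: {int(df[key].sum())}")
    print(f"  glucose analysis set: {len(report.glucose_set)}")
    print(f"  weight analysis set:  {len(report.weight_set)}")
    print(f"  diet analysis set:    {len(report.diet_set)}")
    print(f"  resting-HR excluded:  {int(df['resting_hr_excluded'].sum())}")


if __name__ == "__main__":
    main()
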