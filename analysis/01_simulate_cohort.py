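"""Generate the synthetic program cohort and write it to results/cohort/.

The cohort emulates a 28-day CGM + wearable lifestyle program: ~70/19/9%
healthy/prediabetes/T2D mix, meal-driven glucose excursions, decaying
logging adherence (81% of days at the start, 43% at the end), contiguous
CGM signal-loss gaps, and an injected end-of-program behavior change (30%
carbohydrate reduction, doubled activity-session probability).
"""
import argparse
from pathlib import Path

import numpy as np

from glucolab.io import write_cohort
from glucolab.simulate import GeneratorConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=200)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    cfg = GeneratorConfig(n_participants=args.n, seed=args.seed)
    cohort = generate_cohort(cfg)
    out = write_cohort(cohort, args.out)

    by_cat = {c: sum(r.category == c for r in cohort) for c in
              ("healthy", "prediabetes", "t2d")}
    missing = np.mean([
        np.mean(~np.isfinite(r.glucose.values)) for r in cohort
    ])
    print(f"wrote {len(cohort)} participants to {out}")
    print(f"  category counts: {by_cat}")
    print(f"  mean CGM signal loss: {missing:.1%}")
    print(f"  meals logged: {sum(len(r.meals) for r in cohort)}")


if __name__ == "__main__":
    main()
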