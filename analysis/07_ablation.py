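"""Feature-importance ablation for the glucose predictor: retrain with each
feature group zeroed, rank by held-out RMSE degradation, then produce the
forward (remove-most-important) and reverse (add-from-glucose-only) RMSE
ladders.  Writes ablation.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from glucolab.cgp import CgpConfig, ablation, build_sequences, complete_days
from glucolab.simulate import cgp_training_config, generate_participant

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=ROOT / "results" / "ablation.csv")
    args = ap.parse_args()

    rec = generate_participant(
        cgp_training_config(), "healthy", "ABL", seed=args.seed
    )
    days = complete_days(rec)
    tr = build_sequences(rec, 16, days=days[:14])
    te = build_sequences(rec, 16, days=days[14:21])
    cfg = CgpConfig(lstm_units=12, epochs=15, seed=args.seed)

    fwd = ablation(tr, te, cfg, mode="remove_most_important")
    rev = ablation(tr, te, cfg, mode="reverse")

    print(f"full-model held-out RMSE: {fwd.full_rmse:.2f} mg/dL")
    print("single-group removal RMSE (higher = group more important):")
    for g in fwd.ranking:
        print(f"  {g:<12} {fwd.single_removal_rmse[g]:.2f}")
    print(f"importance ranking: {' > '.join(fwd.ranking)}")
    print("forward ladder:")
    for label, rmse in fwd.ladder:
        print(f"  {label:<16} {rmse:.2f}")
    print("reverse ladder (starting from glucose history only):")
    for label, rmse in rev.ladder:
        print(f"  {label:<16} {rmse:.2f}")

    rows = (
        [{"mode": "single_removal", "step": g, "rmse": v}
         for g, v in fwd.single_removal_rmse.items()]
        + [{"mode": "forward", "step": s, "rmse": v} for s, v in fwd.ladder]
        + [{"mode": "reverse", "step": s, "rmse": v} for s, v in rev.ladder]
    )
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
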