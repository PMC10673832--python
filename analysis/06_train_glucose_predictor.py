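"""Train the recurrent glucose predictor on one synthetic participant,
evaluate next-step and 2-h postprandial forecasts, and run a virtual-CGM
day rollout.  Writes predictions.csv (long format with percentile bands).
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from glucolab.cgp import (
    CgpConfig,
    baseline_rmses,
    build_sequences,
    complete_days,
    evaluate,
    holdout_rmse,
    predict_postprandial,
    train,
    vcgm_rollout,
)
from glucolab.cgp.features import GLUCOSE_CHANNEL, day_frames
from glucolab.simulate import cgp_training_config, generate_participant

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--units", type=int, default=16)
    ap.add_argument("--epochs", type=int, default=20)
    ap.add_argument("--out-dir", default=ROOT / "results")
    args = ap.parse_args()

    rec = generate_participant(
        cgp_training_config(), "healthy", "TRAIN1", seed=args.seed
    )
    days = complete_days(rec)
    tr = build_sequences(rec, 16, days=days[:21])
    te = build_sequences(rec, 16, days=days[21:])
    cfg = CgpConfig(lstm_units=args.units, epochs=args.epochs, seed=args.seed)
    model = train(tr, cfg)

    rmse = holdout_rmse(model, te)
    base = baseline_rmses(tr, te)
    print(f"trained {args.units}-unit LSTM, {args.epochs} epochs "
          f"on {tr.n} sequences ({len(days[:21])} days)")
    print(f"  held-out next-step RMSE: {rmse:.2f} mg/dL "
          f"(mean {base['mean']:.2f}, persistence {base['persistence']:.2f})")

    # 2-h postprandial forecast around a real logged meal on a held-out day
    day = days[-1]
    frames = day_frames(rec, day)
    meal = next(m for m in rec.meals if m.day == day and m.t_min % 1440 > 600)
    k = int((meal.t_min - (day - 1) * 1440) // 15)
    context = frames[k - 16 : k]
    dist = predict_postprandial(
        model, context, meal.nutrients.as_array(), t0_min=meal.t_min
    )
    actual = frames[k : k + 8, GLUCOSE_CHANNEL]
    rep = evaluate(dist.point()[: actual.size], actual)
    print(f"  2-h post-meal forecast RMSE: {rep.rmse_point_by_point:.2f} mg/dL "
          f"(peak {rep.rmse_peak:.2f}, shifted {rep.rmse_shifted:.2f}, "
          f"r={rep.correlation:.3f})")

    # virtual-CGM rollout over the held-out day
    ctx = day_frames(rec, day - 1)[-16:]
    roll = vcgm_rollout(model, frames, init_glucose=frames[0, GLUCOSE_CHANNEL],
                        context=ctx)
    actual_day = frames[:, GLUCOSE_CHANNEL]
    day_rep = evaluate(roll.point(), actual_day)
    b = roll.bands()
    coverage = np.mean((actual_day >= b["p10"]) & (actual_day <= b["p90"]))
    print(f"  virtual-CGM 24-h rollout RMSE: {day_rep.rmse_point_by_point:.2f} "
          f"mg/dL; 10-90 band coverage {coverage:.0%}")

    out_dir = Path(args.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "step": np.arange(roll.probs.shape[0]),
        "actual": actual_day,
        "p10": b["p10"], "p25": b["p25"], "mean": roll.point(),
        "p75": b["p75"], "p90": b["p90"],
    }).to_csv(out_dir / "predictions.csv", index=False)
    print(f"  wrote {out_dir / 'predictions.csv'}")


if __name__ == "__main__":
    main()
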