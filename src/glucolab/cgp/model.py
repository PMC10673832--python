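"""Training, forecasting and evaluation for the recurrent glucose predictor.

The network predicts, at every 15-min step, a categorical distribution over
a 100-point glucose grid (40-400 mg/dL); the point estimate is the
distribution's expectation.  Training minimizes the negative log-likelihood
of the observed next glucose with Adam, with scheduled sampling: the
probability of feeding the model's own previous prediction back in place of
the measured glucose ramps linearly over the epochs, so the network learns
to run autoregressively (2-h post-meal forecasts and full-day virtual-CGM
rollouts use no measured glucose beyond the context).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import (
    FEATURE_GROUPS,
    GLUCOSE_CHANNEL,
    N_FEATURES,
    SequenceSet,
    build_sequences,
    zero_feature_groups,
)
from .nn import Adam, LstmCore, LstmParams, nll, soft_targets


@dataclass(frozen=True)
class CgpConfig:
    lstm_units: int = 16
    glucose_grid_min: float = 40.0
    glucose_grid_max: float = 400.0
    glucose_grid_points: int = 100
    sequence_length: int = 16
    learning_rate: float = 0.01
    batch_size: int = 64
    epochs: int = 20
    feedback_final_prob: float = 1.0  # scheduled-sampling endpoint
    seed: int = 0

    def __post_init__(self):
        if self.glucose_grid_points < 2 or self.glucose_grid_max <= self.glucose_grid_min:
            raise ValueError("glucose grid must be increasing with >= 2 points")
        for f in ("lstm_units", "sequence_length", "learning_rate", "batch_size",
                  "epochs"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def grid(self) -> np.ndarray:
        return np.linspace(
            self.glucose_grid_min, self.glucose_grid_max, self.glucose_grid_points
        )


@dataclass
class PredictionDistribution:
    """Per-step categorical distributions over the glucose grid."""

    grid: np.ndarray  # (K,)
    probs: np.ndarray  # (T, K)

    def point(self) -> np.ndarray:
        """Expectation per step, mg/dL."""
        return self.probs @ self.grid

    def percentile(self, q: float) -> np.ndarray:
        """Grid value at the q-th percentile of each step's distribution."""
        cdf = np.cumsum(self.probs, axis=1)
        idx = np.argmax(cdf >= q / 100.0 - 1e-12, axis=1)
        return self.grid[idx]

    def bands(self) -> dict[str, np.ndarray]:
        return {f"p{q}": self.percentile(q) for q in (10, 25, 75, 90)}


@dataclass
class CgpModel:
    cfg: CgpConfig
    params: LstmParams
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feat_mean) / self.feat_sd

    def _grid_std(self) -> np.ndarray:
        g = self.cfg.grid()
        return (g - self.feat_mean[GLUCOSE_CHANNEL]) / self.feat_sd[GLUCOSE_CHANNEL]

    def predict_stepwise(self, X: np.ndarray) -> PredictionDistribution:
        """Teacher-forced next-step distributions for one sequence (L, F)."""
        core = LstmCore(self.params)
        probs, _ = core.forward(self._standardize(X[None]))
        return PredictionDistribution(grid=self.cfg.grid(), probs=probs[0])

    def predict_batch_points(self, X: np.ndarray) -> np.ndarray:
        """Teacher-forced point estimates for sequences (N, L, F) -> (N, L)."""
        core = LstmCore(self.params)
        probs, _ = core.forward(self._standardize(X))
        return probs @ self.cfg.grid()

    def _autoregress(
        self, context: np.ndarray, future: np.ndarray
    ) -> PredictionDistribution:
        """Run the context teacher-forced, then roll forward feeding the
        point estimate into the glucose channel of each future frame."""
        core = LstmCore(self.params)
        grid = self.cfg.grid()
        ctx = self._standardize(context[None])
        B, T, _ = ctx.shape
        h = np.zeros((1, self.params.hidden))
        c = np.zeros((1, self.params.hidden))
        for t in range(T):
            h, c, _ = core.step(ctx[:, t, :], h, c)
        from .nn import softmax

        probs_out = np.empty((future.shape[0], grid.size))
        pred = None
        for t in range(future.shape[0]):
            frame = future[t].copy()
            if pred is not None:
                frame[GLUCOSE_CHANNEL] = pred
            x = self._standardize(frame[None])
            h, c, _ = core.step(x, h, c)
            logits = h @ self.params.Wy + self.params.by
            pt = softmax(logits)[0]
            probs_out[t] = pt
            pred = float(pt @ grid)
        return PredictionDistribution(grid=grid, probs=probs_out)


def train(
    sequences: SequenceSet,
    cfg: CgpConfig | None = None,
    verbose: bool = False,
) -> CgpModel:
    """Fit the predictor by NLL minimization with Adam; deterministic given
    cfg.seed.  Aborts with diagnostics if the loss goes non-finite."""
    cfg = cfg or CgpConfig()
    if sequences.n < 1:
        raise ValueError("need at least one training sequence")
    rng = np.random.default_rng(cfg.seed)
    X, Y = sequences.X, sequences.Y

    feat_mean = X.reshape(-1, X.shape[-1]).mean(axis=0)
    feat_sd = X.reshape(-1, X.shape[-1]).std(axis=0)
    feat_sd[feat_sd < 1e-6] = 1.0

    params = LstmParams.init(X.shape[-1], cfg.lstm_units, cfg.glucose_grid_points, rng)
    core = LstmCore(params)
    opt = Adam(params, lr=cfg.learning_rate)
    grid = cfg.grid()
    grid_std = (grid - feat_mean[GLUCOSE_CHANNEL]) / feat_sd[GLUCOSE_CHANNEL]
    targets_all = soft_targets(Y, grid)
    Xs = (X - feat_mean) / feat_sd

    model = CgpModel(cfg=cfg, params=params, feat_mean=feat_mean, feat_sd=feat_sd)
    n = sequences.n
    for epoch in range(cfg.epochs):
        fb = cfg.feedback_final_prob * epoch / max(1, cfg.epochs - 1)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, tb = Xs[idx], targets_all[idx]
            probs, caches = core.forward(
                xb, feedback_prob=fb, rng=rng, grid_std=grid_std
            )
            loss = nll(probs, tb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            epoch_loss += loss * idx.size
            grads = core.backward(caches, probs, tb)
            opt.update(grads)
        model.loss_history.append(epoch_loss / n)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  nll={model.loss_history[-1]:.4f}")
    return model


# ---------------------------------------------------------------------------
# Forecasting
# ---------------------------------------------------------------------------

def _future_frames(
    n_steps: int,
    t0_min: float,
    step_min: float,
    hr_bpm: float,
    meal_nutrients: np.ndarray | None = None,
    meal_step: int = 0,
) -> np.ndarray:
    frames = np.zeros((n_steps, N_FEATURES))
    t = t0_min + (np.arange(n_steps) + 1) * step_min
    hod = (t / 60.0) % 24.0
    frames[:, 1] = hr_bpm
    frames[:, 3] = np.sin(2 * np.pi * hod / 24.0)
    frames[:, 4] = np.cos(2 * np.pi * hod / 24.0)
    if meal_nutrients is not None:
        frames[meal_step, 5:12] = meal_nutrients
    return frames


def predict_postprandial(
    model: CgpModel,
    context: np.ndarray,
    meal_nutrients: np.ndarray,
    t0_min: float,
    horizon_steps: int = 8,
    step_min: float = 15.0,
) -> PredictionDistribution:
    """2-h forecast of the glycemic impact of a (hypothetical) meal.

    ``context`` is the most recent (>= sequence_length, F) observed frames;
    the meal's nutrient vector lands in the first future frame and the
    forecast runs autoregressively on the model's own point estimates.
    """
    if context.shape[0] < model.cfg.sequence_length:
        raise ValueError(
            f"context of {context.shape[0]} frames < sequence_length "
            f"{model.cfg.sequence_length}"
        )
    future = _future_frames(
        horizon_steps, t0_min, step_min,
        hr_bpm=float(context[-1, 1]),
        meal_nutrients=np.asarray(meal_nutrients, dtype=float),
    )
    return model._autoregress(context, future)


def vcgm_rollout(
    model: CgpModel,
    exog_frames: np.ndarray,
    init_glucose: float,
    context: np.ndarray | None = None,
) -> PredictionDistribution:
    """Virtual CGM: a fully autoregressive trajectory over exogenous frames
    (food + HR + time; the glucose channel is ignored after step 0).

    ``init_glucose`` seeds the first frame's glucose input; every later step
    consumes the previous step's point estimate.
    """
    future = exog_frames.copy()
    future[0, GLUCOSE_CHANNEL] = init_glucose
    if context is None:
        context = np.repeat(future[:1], model.cfg.sequence_length, axis=0)
        context[:, GLUCOSE_CHANNEL] = init_glucose
        context[:, 5:12] = 0.0
    # _autoregress overwrites glucose from step 1 on with fed-back estimates
    core_pred = model._autoregress(context, future)
    return core_pred


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    rmse_peak: float
    rmse_point_by_point: float
    rmse_shifted: float
    percent_error: float
    correlation: float


def evaluate(
    predicted: np.ndarray,
    actual: np.ndarray,
    window_steps: int = 8,
    max_shift: int = 2,
) -> EvalReport:
    """Accuracy metrics over aligned step grids.

    rmse_peak pools, over consecutive 2-h windows, the error between the
    predicted and actual window maxima; rmse_shifted is the minimum
    point-by-point RMSE over lags within +/- max_shift steps (lag 0
    included, so rmse_shifted <= rmse_point_by_point).
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("predicted and actual must share a step grid")
    err = p - a
    rmse = float(np.sqrt(np.mean(err**2)))

    peaks = []
    for s in range(0, p.size, window_steps):
        pe = p[s : s + window_steps]
        ae = a[s : s + window_steps]
        if pe.size:
            peaks.append(pe.max() - ae.max())
    rmse_peak = float(np.sqrt(np.mean(np.square(peaks)))) if peaks else float("nan")

    shifted = rmse
    for lag in range(-max_shift, max_shift + 1):
        if lag == 0:
            continue
        if lag > 0:
            pp, aa = p[lag:], a[: a.size - lag]
        else:
            pp, aa = p[: p.size + lag], a[-lag:]
        if pp.size:
            shifted = min(shifted, float(np.sqrt(np.mean((pp - aa) ** 2))))

    nonzero = a != 0
    mape = float(np.mean(np.abs(err[nonzero]) / np.abs(a[nonzero]))) * 100.0
    if p.size > 1 and p.std() > 0 and a.std() > 0:
        corr = float(np.corrcoef(p, a)[0, 1])
    else:
        corr = float("nan")
    return EvalReport(
        rmse_peak=rmse_peak,
        rmse_point_by_point=rmse,
        rmse_shifted=shifted,
        percent_error=mape,
        correlation=corr,
    )


def holdout_rmse(model: CgpModel, test: SequenceSet) -> float:
    """Teacher-forced next-step point RMSE on held-out sequences."""
    points = model.predict_batch_points(test.X)
    return float(np.sqrt(np.mean((points - test.Y) ** 2)))


def baseline_rmses(train_set: SequenceSet, test: SequenceSet) -> dict[str, float]:
    """Mean predictor and persistence (last value) on the same targets."""
    mean_pred = float(train_set.Y.mean())
    persistence = test.X[:, :, GLUCOSE_CHANNEL]
    return {
        "mean": float(np.sqrt(np.mean((test.Y - mean_pred) ** 2))),
        "persistence": float(np.sqrt(np.mean((test.Y - persistence) ** 2))),
    }


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    full_rmse: float
    single_removal_rmse: dict[str, float]
    ranking: list[str]  # descending importance
    ladder: list[tuple[str, float]]  # (description, rmse) per step
    mode: str


def ablation(
    train_set: SequenceSet,
    test_set: SequenceSet,
    cfg: CgpConfig,
    mode: str = "remove_most_important",
    include_ladder: bool = True,
) -> AblationResult:
    """Feature-group importance by retraining with groups zeroed.

    Importance of a group = held-out RMSE after retraining without it
    (higher = more important).  remove_most_important then drops groups
    cumulatively in that order; reverse starts from glucose history only and
    adds groups in descending importance.
    """
    if mode not in ("remove_most_important", "reverse"):
        raise ValueError(f"unknown ablation mode {mode!r}")

    def fit_rmse(removed: tuple[str, ...]) -> float:
        Xtr = zero_feature_groups(train_set.X, removed)
        Xte = zero_feature_groups(test_set.X, removed)
        m = train(SequenceSet(Xtr, train_set.Y), cfg)
        return holdout_rmse(m, SequenceSet(Xte, test_set.Y))

    full = fit_rmse(())
    singles = {g: fit_rmse((g,)) for g in FEATURE_GROUPS}
    ranking = sorted(singles, key=lambda g: -singles[g])

    ladder: list[tuple[str, float]] = []
    if not include_ladder:
        pass
    elif mode == "remove_most_important":
        removed: list[str] = []
        ladder.append(("all features", full))
        for g in ranking:
            removed.append(g)
            ladder.append((f"- {g}", fit_rmse(tuple(removed))))
    else:  # reverse: start from glucose-only, add groups by importance
        all_groups = tuple(FEATURE_GROUPS)
        ladder.append(("glucose only", fit_rmse(all_groups)))
        added: list[str] = []
        for g in ranking:
            added.append(g)
            remaining = tuple(x for x in all_groups if x not in added)
            ladder.append((f"+ {g}", fit_rmse(remaining)))
    return AblationResult(
        full_rmse=full,
        single_removal_rmse=singles,
        ranking=ranking,
        ladder=ladder,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Per-user hyperparameter tuning
# ---------------------------------------------------------------------------

def per_user_tune(
    base_cfg: CgpConfig,
    record,
    budget: int,
    seed: int = 0,
    val_fraction: float = 0.25,
) -> CgpConfig:
    """Seeded random search over (lstm_units, learning_rate,
    sequence_length), selecting the lowest validation NLL; returns base_cfg
    unless a candidate beats it."""
    from .features import complete_days

    if budget <= 0:
        return base_cfg
    rng = np.random.default_rng(seed)
    days = complete_days(record)
    n_val = max(1, int(round(val_fraction * len(days))))
    train_days, val_days = days[:-n_val], days[-n_val:]

    def val_nll(cfg: CgpConfig) -> float:
        tr = build_sequences(record, cfg.sequence_length, days=train_days)
        va = build_sequences(record, cfg.sequence_length, days=val_days)
        m = train(tr, cfg)
        core = LstmCore(m.params)
        probs, _ = core.forward(m._standardize(va.X))
        return nll(probs, soft_targets(va.Y, cfg.grid()))

    best_cfg, best = base_cfg, val_nll(base_cfg)
    for _ in range(budget):
        cand = replace(
            base_cfg,
            lstm_units=int(rng.choice([8, 16, 24, 32])),
            learning_rate=float(10 ** rng.uniform(-2.5, -1.5)),
            sequence_length=int(rng.choice([8, 12, 16, 24])),
        )
        score = val_nll(cand)
        if score < best:
            best_cfg, best = cand, score
    return best_cfg
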