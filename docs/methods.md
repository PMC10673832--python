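# Methods

`glucolab` re-implements, as a tested pipeline over synthetic data, the
analysis stack of a 28-day digital metabolic-health program in which
participants wear a CGM and heart-rate monitor, log meals, activity and body
weight in an app, and receive personalized lifestyle recommendations.  The
real study cohort is not public, so every stage runs against a synthetic
cohort whose generative parameters are known exactly; the tests check each
stage against independent oracles built from those parameters.

## Synthetic cohort generator

Each participant carries a glycemic category (healthy / prediabetes /
non-insulin-treated T2D, mixed 746:206:94 by default), a basal glucose level
(90 / 105 / 135 mg/dL category means, ±5 participant scatter), a dawn-peaked
circadian term (3–7 mg/dL amplitude — deliberately low so time of day is a
real but secondary signal), meal-driven excursions, white CGM noise
(sd 5 mg/dL), and contiguous CGM signal-loss gaps.

**Meal kernel.**  A meal's incremental glucose is a unit-peak gamma-like
shape `(t/tp)^a · exp(a(1 − t/tp))` with `a = rise/decay`, scaled by
`amplitude · carb_g · max(0, 1 − fiber_atten · fiber_g)`.  Defaults:
amplitude 1.0 mg/dL per gram of carbohydrate, fiber attenuation 0.02/g,
rise (time to peak) 40 min, tail time constant 20 min, under which the
response of a typical meal has decayed below 1 mg/dL by 4 h.  Carbohydrate
is the dominant glucose driver by construction, which is what makes the
ablation ordering a testable property rather than an accident.

**Meals and logging.**  A day is *logged* with probability equal to the
program's observed adherence, interpolated linearly from 81% (day 1) to 43%
(day 28); a logged day carries three meals (~8:00/13:00/19:00 ± 1 h) with
per-meal composition carb ~ N(70, 15) g, protein ~ N(35, 8) g, fat ~
N(35, 8) g, fiber ~ N(7, 3) g, sugar ≈ 35% of carbohydrate, and logged
kcal = 4·(carb+protein) + 9·fat.  Meals exist only on logged days — the
pipeline, like the program it emulates, can only analyse what was logged —
so decaying adherence is itself a systematic baseline-vs-end behavior
change.  The *null* configuration (`null_config`) therefore switches off
both the injected effect **and** the adherence decay; it is the
configuration under which the paired t-test's type-I error is calibrated.

**Injected effect.**  From day 15 on, per-meal carbohydrate is cut by a
configurable fraction (default 30%) and the daily exercise-session
probability rises (default doubled, capped at 0.95).  The generator exposes
`expected_carb_ratio_delta`, the exact expectation of the end-minus-baseline
carb-kcal:total-kcal change, computed by enumerating the Poisson-binomial
distribution of logged pre-/post-effect days inside each analysis window
(the end window, days 14–28, starts one day before the effect).  Effect
recovery is asserted against this value within 3 Monte-Carlo standard
errors.

**Other streams.**  Heart rate is per-minute: resting ~N(62, 5) bpm plus a
small diurnal swing and noise, elevated to 115–135 bpm during exercise
sessions (25–50 min, base probability 0.75/day), giving HR>110 exposure of
roughly half an hour per day.  Weigh-ins occur on days {2, 7, 14, 21, 27}
with probability 0.6 each; weight drifts by cumulative energy deficit at
3,500 kcal/lb.  Signal loss is placed as contiguous 1–8 h gaps whose total
hits the configured fraction exactly (±1 slot).

**What the generator does not emulate:** sensor drift and compression-low
artifacts, inter-day habit correlation, mixed-meal absorption differences,
insulin dynamics, or any demographic structure in glycemic response.
Passing tests show the *pipeline arithmetic* is right and that the methods
recover a known injected effect; they say nothing about physiological
fidelity on real cohorts.

## Quality control

Inclusion rules (all comparisons inclusive, since every rule is stated as
"at least"): ≥70% CGM coverage on ≥half the days of the baseline and end QC
windows; ≥2 log events/day on at least half the days of the first week and
the last two weeks; one weigh-in in days 1–7 and one in days 15–28; ≥20 h/day
HR capture.  Sets: `glucose_set` = CGM ∧ meals ∧ HR; `weight_set` and
`diet_set` are subsets of it.  The protocol text gives the baseline CGM-QC
window inconsistently (days 3–7 in one place, days 1–5 excluding day 1 in
another); we adopt days 2–7, aligned with the glycemic baseline window, and
keep it configurable.  "Active logging" is likewise not operationalized in
the source beyond "two events per day"; requiring literally every day would
exclude almost everyone under the program's own adherence figures, so the
rule here is ≥2 events/day on ≥50% of each window's days (configurable).
A "good logging day" for diet analysis needs ≥2 logs, all within a 16-h
window and spread ≥4 h, totalling ≥1600 kcal.  Resting HR is the 5th
percentile of per-minute HR; above 110 bpm the participant is excluded from
HR-based measures only.

## Glycemic metrics

Per analysis window (baseline days 2–7 — day 1 dropped for first-day sensor
inaccuracy — vs end days 14–28):

- **TIR**: percent of non-missing samples in 70–180 mg/dL (T2D) or
  70–140 mg/dL (everyone else).
- **GMI**: 3.31 + 0.02392 × mean glucose (mg/dL) — the standard
  CGM-consensus linear map; coefficients configurable.
- **Excursion events** (>140, >180, >250, <70 mg/dL): a maximal run of ≥2
  consecutive beyond-threshold samples; runs separated by <30 min merge.
  Rates divide by window days scaled by (1 − lost-time fraction); the
  lost-time correction applies **only** to event rates, not to averaged
  metrics (TIR/GMI/CV), whose denominators simply drop missing samples.
- **CV**: 100 × sample SD (n−1) / mean over the pooled window (not
  per-day averaged) — the simplest reading of "coefficient of variation".

Subgroups form on baseline values only (<90% TIR, <70% TIR, GMI>6%, GMI>7%,
overall), each reporting mean end-minus-baseline change per metric and per
glycemic category; empty subgroups are absent from the output, never zero.

A note on a tempting "invariant": with the run/merge event definition,
events(>180) ≤ events(>140) is *not* a theorem — two >180 runs separated by
a 30-min dip can merge into a single >140 event.  It holds empirically on
smooth meal-driven traces (0 violations over 300 generated windows) and the
property test asserts it there.

## Behavior metrics

Dietary summaries pool only good logging days and express macronutrients as
energy ratios (grams ×4 for carbohydrate/sugar/protein, ×9 for fat and
saturated fat, divided by *logged* total kcal; fiber as g/kcal), which makes
them invariant to logging frequency — duplicating a day's logs changes no
ratio.  Activity minutes are divided by the ratio of the window's
app-interaction rate (all log events: meals, activities, weigh-ins) to the
baseline window's rate, so unchanged behavior maps to the identity; the
program describes this adjustment without a formula, and this ratio
normalization is our choice, exposed as such.  HR>110 min/day averages over
window days with ≥20 h capture.  Weight change is last weigh-in of days
15–28 minus first of days 1–7, also as percent of the initial weight, and is
stratified by baseline weight ({<150, 150–199, 200–249, 250–300} lbs,
lower-inclusive boundaries).  Activity/diet baselines use days 1–5 / 1–7
respectively; the glycemic baseline (days 2–7) is configured separately.

## Statistics

Every outcome is a paired Student t-test on per-participant end-minus-
baseline deltas, two-sided, α = 0.05.  Deltas are screened with Shapiro-Wilk
and the result carried as a flag (a log-transform hook exists but is off, as
none of the emulated analyses needed it).  Zero-variance deltas are flagged
degenerate rather than producing a t-value.  P-values are reported
uncorrected across subgroups and thresholds to mirror the emulated program's
reporting; `benjamini_hochberg` is available as an explicit sensitivity
switch.  Calibration and power are acceptance-tested: type-I error 0.05 ±
0.02 over 500 null cohorts, and ≥95% rejection over replicate cohorts with
the default 30% carb cut.

## Glucose predictor

A single-layer LSTM (numpy implementation with full backpropagation through
time; gradients verified against central finite differences) reads one
frame per 15-min step — glucose, mean HR, exercise minutes, time-of-day as
(sin, cos), and the 7-component nutrient vector of foods logged in the step
— and emits a categorical distribution over a uniform 100-point glucose grid
(40–400 mg/dL).  The source describes "a dense layer with a sigmoid" yet
also 100 candidate values with likelihoods and a log-likelihood loss; the
categorical softmax head is the only reading consistent with the latter two
and is what we implement.  Targets are encoded as a two-bin linear
interpolation on the grid so the distribution's expectation (the point
estimate) can resolve glucose below the 3.6 mg/dL grid spacing.  Training:
Adam (lr 0.01, batch 64, 20 epochs, global-norm gradient clipping at 5),
NLL loss at every step of each window, with *scheduled sampling* — the
probability of feeding the model's own previous point estimate back into
the glucose input channel ramps linearly 0 → 1 over the epochs (the
feedback is treated as constant in the backward pass).  Deterministic given
the seed.

Sequences slide within "complete" days only (≥12 h of both CGM and HR plus
a logged food day; small in-day CGM gaps are linearly interpolated), never
across midnight, and a participant needs ≥5 complete days.  Forecasting is
autoregressive: the 2-h postprandial forecast places a (possibly
hypothetical) meal's nutrients in the first future frame and rolls 8 steps
on its own point estimates; the virtual-CGM rollout does the same for 96
steps from food + HR + time alone, warmed up on the previous day's observed
frames.  Percentile bands (10/25/75/90) come from each step's distribution
CDF and are nested by construction.

Evaluation metrics: point-by-point RMSE; peak RMSE (pooled error between
window maxima over consecutive 2-h windows); shifted RMSE (minimum over
lags within ±2 steps, so never above the point-by-point value); MAPE; and
Pearson correlation.  Ablation retrains with feature groups (nutrients,
time-of-day, heart rate, activity) zeroed; a group's importance is the
held-out RMSE after removing it, and forward/reverse ladders remove/add
groups in importance order.  Per-user tuning is a seeded random search over
(units, learning rate, sequence length) on validation NLL, returning the
base configuration unless a candidate beats it — the source's meta-learning
procedure is unnamed and not reproducible as stated, so this deliberately
simple stand-in is our design choice.

Desk scales used by the tests and analysis scripts (chosen as the smallest
sizes at which the learning signals are stable): 16 units / 20 epochs / 21
training days for learning sanity; 12 units / 15 epochs / 14 training days
per ablation fit.

## Food recommender

Four fixed stages: (1) similarity = 0.5 × cosine of per-100-kcal nutrient
densities + 0.5 × category match, thresholded at τ; (2) blacklist removal;
(3) healthiness ranking with score = 2 × fiber density − 1 × net-carb
(carb − fiber) density per 100 kcal — an invented formula within the source's
stated ingredients (carbohydrate and fiber composition), weights
configurable; (4) cleanup drops incomplete-nutrient items and anything not
*strictly* healthier than the query, then truncates to k.  Ties break by
item id for determinism.  Spiking foods rank by mean 2-h incremental AUC
(trapezoidal, baseline = median of the 15 pre-meal minutes); foods with <2
usable exposures are flagged low-confidence, and meals inside CGM gaps
contribute nothing.  The lever plan combines the spiking-food list with a
Mifflin-St Jeor maintenance estimate × activity factor, a calorie target
capped below maintenance (default 85%), the sex-specific fiber band
(21–25 g/day female, 30–35 g/day male), a post-meal activity suggestion,
and a 16-h fasting target with achieved fast = mean overnight gap between
consecutive logged days.

## Numerical and interface choices

- Time is naive minutes since program start; day boundaries at local
  midnight of a single implicit timezone; days are 1-based.
- Glucose values are validated to (20, 600) mg/dL; the generator clips to
  [45, 500].
- Metric functions raise `NoDataError` on empty windows rather than
  returning sentinels; QC predicates return plain booleans.
- Cohorts serialize to one directory of long-format CSVs plus
  `ground_truth.json`; timestamps round-trip exactly through ISO-8601.
- The numbered scripts under `analysis/` are the pipeline's user interface;
  every computation they drive lives in the library so tests and the
  acceptance script import the same code.

## Known limitations

- The generator's effect injection changes only carbohydrate and activity;
  protein/fat substitution patterns seen in real diet change are absent.
- Virtual-CGM band coverage is assessed on the training participant's
  held-out days, not across subjects.
- The per-user tuner searches three hyperparameters with a small budget; it
  demonstrates the interface, not a serious meta-learning result.
- No AGP-style visualization, no laboratory HbA1c integration, no device
  APIs; nutrient vectors are inputs, not parsed from food databases.
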