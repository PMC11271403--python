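# Methods

## Synthetic cohort generator

The generator emulates a two-arm randomized rate-control cohort in
permanent AF wearing a wrist device: ~50 patients, 20 weeks, heart rate
emitted every 10 s and step counts once per minute.

Heart rate for patient *i* at minute *t*:

    hr_i(t) = μ + δ·1[arm_i = digoxin] + b_i + w_{i,week(t)}
              + A·cos(2π(hour(t) − 16)/24) + γ·steps_i(t) + e_i(t)

- `μ = 72 bpm` (baseline_hr_bpm) — the control-arm heart rate.
- `b_i ~ N(0, σ_b²)` patient intercepts with `σ_b = 5.72 bpm`, and
  week effects `w ~ N(0, σ_w²)` with `σ_w = σ_b·√((1−ρ)/ρ)`. These two
  components make weekly means compound-symmetric with s.d.
  `σ_b/√ρ = 6 bpm` and exchangeable correlation `ρ = 0.91`
  (week_correlation), the design values of the repeated-measures
  analysis. Minute-level AR(1) noise `e` (φ = 0.8, stationary s.d.
  7 bpm) contributes negligibly to weekly means but gives the CNN
  short-range autocorrelation to exploit.
- Circadian term: amplitude 3 bpm with acrophase 16:00. The overall
  minute-level cohort s.d. that results (~9–10 bpm) is below the raw
  pooled spread a real cohort shows, a deliberate trade against keeping
  the weekly-mean variance at its design value.
- Activity: each daytime minute (07:00–23:00) is active with
  patient-specific probability `p_i` (median 0.15, log-normal spread
  0.4, clipped to [0.02, 0.6]); active minutes draw
  `steps ~ Poisson(λ_i)` (median 18, log-normal spread 0.2). Patient
  differences live mostly in the *fraction* of active minutes, as in
  frail cohorts, which keeps activity level visible after the per-patient
  [0, 1] step normalization. Median weekly totals land near 20,000
  steps, straddling the 15,000/30,000 CDC category thresholds.
- Activity coupling: `γ = 0.25 bpm per step/min` by default, i.e. an
  active minute raises heart rate by ~4–5 bpm.

Missingness deletes contiguous device-off gaps (geometric lengths,
mean 30 min, both channels) until a target fraction (default 10%) of
minutes is removed; overlap is counted once, so the realized fraction
lands within ±2 percentage points for long streams.

Covariates approximate an older AF/heart-failure population: age
N(75.6, 8.4²), 40% women, 50% heart-failure diagnosis, log-normal
NT-proBNP (median 1000 pg/ml), BMI N(29, 5²). Six-minute-walk distance
is tied to activity propensity (80 m per s.d., residual s.d. 60 m) so
that conventional clinic measures genuinely carry functional-capacity
signal, as they do clinically; ECG heart rate shares the patient's HR
intercept.

NYHA classes come from an ordinal probit-style latent model:
`latent = (−c·z(mean weekly steps) + ε)/√(c²+1)` with thresholds set so
the marginal end-of-trial distribution is ≈8% I, 64% II, 26% III, 2% IV
(baseline: 72/26/2 over II–IV). `c` (nyha_activity_coef, default 1)
controls how strongly activity capacity drives class; `c = 0` makes
labels independent of the streams, which the negative-control tests
rely on.

### Weekly fast path

Replicate simulation studies (effect recovery, CI coverage, null
calibration) need hundreds of cohorts, for which materializing
per-minute streams is wasteful. `simulate_weekly_cohort` draws weekly
mean HR and weekly step totals directly from the marginal model the
stream generator induces (`μ + δ·arm + b_i + w_iw`; Poisson weekly
steps), so replicate studies run in milliseconds per cohort with the
same statistical structure. Stream-level tests exercise the full path.

### What the generator does not emulate

No photoplethysmography artifacts or signal-quality failure modes; no
dose titration or pharmacodynamics (the arm effect is a constant bpm
shift); no weekend/weekday structure; activity bursts are conditionally
independent minutes rather than walks with duration. Tests passing on
this generator show the *pipeline machinery* is correct and calibrated,
not that real wearable data would yield any particular effect size.

## Preprocessing

Pooling: HR averaged and steps summed within each calendar minute; empty
minutes stay missing (no imputation anywhere). The missingness mask is 1
when either channel is missing in that minute — one union mask stays
truthful for both channels and becomes the CNN's third input channel.

Normalization is per patient: HR to z-scores over nonmissing minutes
(constant series are an error), steps divided by the patient's maximum
per-minute count, guarded at 1 for fully sedentary patients. Missing
minutes are then filled with 0 — the patient's mean HR and zero steps —
which is neutral under both normalizations and leaves the mask to carry
the missingness information.

Windows are 240 min, staggered by a configurable stride (default 60 min;
the replicate studies use 480 for speed), and flagged available when at
least 50% of minutes are nonmissing. Weekly summaries index weeks from
the first device minute, keep at most 20 weeks, and drop weeks with
under 10% nonmissing HR. Daytime (07:00–23:00) HR–activity association
uses Spearman rank correlation on interval bins, with the qualitative
bands `<0.2` very weak, `0.2–0.6` weak to moderate, `≥0.6` strong.

## Treatment comparison

`fit_gee_exchangeable` is an identity-link Gaussian GEE: iterate
(1) GLS at the current ρ, (2) moment re-estimation of ρ from Pearson
residual cross-products, to convergence (tolerance 1e-8, max 100
iterations; non-convergence returns `converged=False` with a warning).
Inference is cluster-robust (sandwich), Wald CIs and normal-approximation
p-values. `rho_fixed=0` reproduces OLS exactly; the test suite also
checks equality against a dense-matrix GLS oracle and against
statsmodels' independent GEE implementation.

Covariate coding: woman and heart-failure indicators, log NT-proBNP
(right-skewed), age centered; weekly activity enters as total steps per
1000. The analysis suite fits unadjusted, covariate-adjusted,
activity-adjusted, and three activity-subgroup models where *week-level*
records are filtered by that week's CDC category, so one patient can
contribute weeks to several subgroups ("N weeks from M patients"
accounting).

Power: for *m* equi-correlated weekly means per patient the variance of
a patient mean is `σ²(1+(m−1)ρ)/m`, and the two-sample normal formula
gives `n/arm = ⌈2(z_{1−α/2}+z_{pow})²·var/δ²⌉`. A Monte-Carlo power
check (`simulate_power`) verifies the formula. Note that at δ = 2 bpm,
σ = 6 bpm, ρ = 0.91, m = 20 this yields 173 per arm — the design
effect 1 + 19·0.91 ≈ 18.3 makes extra weeks almost worthless — so a
claim that ~40 participants suffice at these parameters is not
reproducible from the standard formula; the calculator reports the
formula's answer rather than matching any particular figure.

## Self-supervised CNN

Architecture (fixed by `CNNSpec` defaults): conv(8 filters, kernel 21,
valid) → ReLU → max-pool size/stride 2 → conv(20, 21) → ReLU →
conv(32, 21) → ReLU → global average pool → 32-vector → dropout 0.5 →
single sigmoid unit. Binary cross-entropy, Adam (lr 3e-4), L2 1e-8 on
non-bias parameters. Implemented directly in NumPy (im2col + matmul
convolutions, hand-written backprop verified against numerical
gradients); all randomness flows through explicit generators, so runs
are reproducible seed-for-seed on one thread.

Scrambling: one negative per original window, keeping the original's HR
channel and substituting the step channel of a uniformly drawn window
from a *different* patient in the same 4-hour clock bucket (so circadian
phase alone cannot solve the task; configurable off). The scrambled mask
is the union of both donors' masks and the neutral fill is re-applied
beneath it, so mask/channel consistency offers no shortcut.

Training uses patient-level 5-fold splits: ~20% of patients are held
out per fold for early stopping on held-out loss (patience 10, up to
200 epochs, batch 64; studies in this repository use shorter schedules
and a higher learning rate at their small problem sizes). First-week
windows are excluded from training for every patient, and scrambling
donors come only from the fold's training patients.

Embeddings: the dropout and sigmoid head are removed and the
post-pooling 32-vector is averaged over a patient's available first-week
windows. By default the whole cohort is embedded by the single fold
model with the best held-out loss: the five fold models' embedding
coordinates are not mutually aligned, so mixing them feeds the
downstream classifier incoherent features (verified empirically), while
a single reference model keeps one coordinate system. This is
leakage-free for what is embedded — first-week windows never enter
training and the pretext task never sees outcome labels. An
`out_of_fold` mode (each patient embedded by the model that never saw
any of their data) is retained for leakage audits.

## NYHA prediction

NYHA is binarized to I–II vs III–IV, keeping one F1/AUROC well-defined;
targets are smoothed as `y' = y(1−ε)+ε/2` with ε = 0.1, and the ridge
logistic objective (L-BFGS on BCE + L2, intercept unpenalized) is fit
out-of-fold with stratified patient folds; features are standardized
with training-fold statistics only. The L2 strength comes from an inner
3-fold log-loss grid over {0.01, 0.1, 1, 10} unless fixed. Feature
sets: 32 embedding dims; ECG HR + 6MW distance/time/speed; embedding +
age, gender, BMI (35 columns).

## Evaluation

F1 from confusion counts (zero-division → 0; binary default, macro and
weighted available) and AUROC by midrank Mann–Whitney, both cross-checked
against scikit-learn and brute-force enumeration in tests. CIs are
patient-level percentile bootstrap (2000 resamples default; degenerate
resamples skipped). The chance-F1 level is the expected F1 when
predictions are a uniformly random permutation of the labels (exact
enumeration for n ≤ 8). Models are compared by paired patient-level
bootstrap of ΔF1 with two-sided p = 2·min(P(Δ≤0), P(Δ≥0)); a
permutation alternative (`permutation_pvalue`) tests a single model
against chance.

## Problem sizes and numerical choices

Replicate studies use the weekly fast path (100–200 cohorts of 50–100
patients × 20 weeks). Stream-level end-to-end studies use 10–24
patients × 2 weeks with window stride 480 min, a learning rate of 1e-3
and ~20–60 epochs, which the positive/negative control experiments show
is ample for the discriminator at these sizes; the
positive-control/negative-control discriminator uses a reduced
(4/8/8, kernel 11) network. Ties in max-pooling resolve to the first
index; GEE ρ is clipped to its positive-definite range
(−1/(m−1), 0.999); the step-normalization denominator is guarded at 1;
bootstrap quantiles are the 2.5/97.5 percentiles.

## Known limitations

The generator's distributional choices beyond the stated design values
are plausible stand-ins, not estimates from any dataset. The GEE is the
Gaussian/identity case only. The CNN implementation is CPU-bound NumPy —
adequate at these problem sizes, not for device-scale corpora. Headline
metrics computed on synthetic cohorts characterize the pipeline, not any
clinical population; no multiplicity correction is applied across the
model ladder.
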