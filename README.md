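# afwear

Analysis toolkit for wearable heart-rate and step-count streams from
randomized rate-control trials in permanent atrial fibrillation (AF),
for biostatisticians and ML researchers working with minute-level
wrist-device data. It provides, end to end:

- a **seeded synthetic cohort generator** — two treatment arms (digoxin
  vs beta-blockers), per-minute heart rate/steps with circadian and
  activity-coupled structure, device-off missingness, clinical
  covariates and NYHA functional-class outcomes;
- **preprocessing** — pooling to 1-minute resolution (HR averaged, steps
  summed), per-patient normalization (HR z-scores, steps scaled to
  [0, 1]), a missingness mask as a third channel, staggered 4-hour
  windows, and weekly summaries with CDC activity categories
  (<15,000 / 15,000–30,000 / ≥30,000 steps per week);
- a **repeated-measures treatment comparison** — identity-link Gaussian
  GEE with exchangeable working correlation and robust (sandwich)
  standard errors on weekly mean heart rate, with covariate adjustment,
  activity adjustment, activity subgroups, and a repeated-measures
  power calculator;
- a **self-supervised CNN** — a 1D convolutional network (8/20/32
  filters, kernel 21 minutes, max pool 2/2, global average pooling to a
  32-vector, dropout 0.5, sigmoid head) trained to discriminate
  original windows from windows whose heart-rate and step channels were
  *scrambled across patients*, so it must learn the cross-channel
  temporal coupling; first-week windows give a 32-dim patient embedding;
- **NYHA prediction and evaluation** — label-smoothed ridge logistic
  regression on wearable embeddings, conventional clinic measures (ECG
  heart rate + 6-minute-walk distance/time/speed), or both plus
  clinical factors; scored by F1 with patient-level bootstrap CIs,
  AUROC, a permutation-based chance-F1 level, and paired model
  comparison.

## Model summary

Weekly mean heart rate for patient *i*, week *t* is modelled marginally
as `E[Y_it] = β₀ + β₁·digoxin_i + covariates`, with working correlation
`corr(Y_it, Y_is) = ρ` for all `t ≠ s` (compound symmetry). β is solved
by iterated GLS with a moment estimator for ρ, and inference uses the
cluster-robust sandwich covariance — for balanced Gaussian data the
point estimate coincides with the random-intercept GLS fit. The power
calculator uses the design effect `1 + (m−1)ρ` for the variance of a
mean of *m* equi-correlated weeks.

The self-supervised objective is binary cross-entropy on
original-vs-scrambled windows; because scrambled windows pair patient
A's heart rate with patient B's steps (mask = union of both donors'
masks, time-of-day matched), chance performance is the ceiling unless
the network captures genuine HR–activity coupling.

## Worked example

```python
import afwear as aw

cfg = aw.CohortConfig(n_patients=50, n_weeks=20, treatment_effect_bpm=0.0)
profiles, weekly = aw.simulate_weekly_cohort(cfg, seed=7)
fit = aw.fit_gee_exchangeable(weekly, profiles)
j = fit.names.index("digoxin")
print(f"arm coefficient: {fit.beta[j]:+.2f} bpm  "
      f"(95% CI {fit.ci95[j,0]:.2f} to {fit.ci95[j,1]:.2f}; P = {fit.p_values[j]:.2f})")
print(f"exchangeable rho: {fit.rho_hat:.3f};  "
      f"{fit.n_weeks_total} weeks from {fit.n_patients} patients")
print("power n/arm:", aw.power_repeated_measures(2.0, 6.0, 0.91, 20))
```

prints

```
arm coefficient: -0.33 bpm  (95% CI -3.05 to 2.39; P = 0.81)
exchangeable rho: 0.887;  1000 weeks from 50 patients
power n/arm: 173
```

With no injected treatment effect the digoxin coefficient is a null
−0.33 bpm with a CI spanning zero; the estimated week-to-week
correlation 0.887 recovers the generator's 0.91 up to sampling error;
and a 2 bpm difference at s.d. 6 bpm and ρ = 0.91 over 20 weeks needs
173 patients per arm by the standard design-effect formula.

The same pipeline runs from the shell:

```bash
afwear simulate --config cohort.yaml --out data/ --seed 1
afwear preprocess --in data/ --out prep/
afwear fit-gee --summaries prep/weekly.csv --profiles data/profiles.csv --model suite
afwear train-ssl --in data/ --out ssl/ --seed 1
afwear predict-nyha --features wearable --embeddings ssl/embeddings.csv \
    --profiles data/profiles.csv --out preds.csv
afwear evaluate --preds preds.csv
```

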