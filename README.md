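# locoage

Parametric Gompertz proportional-hazards modelling, perturbation-theory
hazard learning, and biological-age scores from wearable locomotor-activity
records — with a synthetic cohort generator so the whole pipeline runs and
is tested without any external data.

`locoage` is aimed at biostatisticians and quantitative-aging researchers
working with accelerometer cohorts linked to a death register (e.g.
minute-level activity counts with survival follow-up). It provides:

- **`locoage.gompertz`** — the Cox–Gompertz model
  `M(t, x) = M0 · exp(Γt) · exp(β·x)`, with the left-truncated
  negative log-likelihood

  ```
  −log LH = Σₙ (M0/Γ) e^{β·xⁿ} fₙ − Σₙ δⁿ (log M0 + β·xⁿ + Γ t₂ⁿ),
  fₙ = e^{Γt₂ⁿ} − e^{Γt₁ⁿ},
  ```

  maximised by quasi-Newton descent on `(log M0, log Γ, β)` with analytic
  gradients (`GompertzPH`, a scikit-learn-style estimator).
- **`locoage.perturbation`** — the first-order expansion of that
  likelihood around a fitted baseline ("zero-order") model: sample
  weights `ρⁿ ∝ fₙ e^{β̄·xⁿ}`, martingale-residual targets
  `Rⁿ = δⁿ/(ρⁿN_d) − 1`, the closed-form effect
  `β_ξ = C_ρ⁻¹ Σₙ ξⁿ(δⁿ − N_d ρⁿ)` with analytic error
  `σ² = 1/(N_d⟨δξ²⟩_ρ)`, and the equivalent sample-weighted square loss
  `L = Σₙ ρⁿ(β_ξ·ξⁿ − Rⁿ)²` — a drop-in training objective for **any**
  regressor that accepts per-sample weights.
- **`locoage.activity`** — descriptors from raw counts: quality filters,
  discretization into 8 e-fold intensity states, per-subject 8×8
  transition-rate matrices, log-scaled 64-d descriptor vectors.
- **`locoage.bioage`** — unsupervised (`PCAAge`) and supervised
  (`RidgeAge`, 5-fold CV) biological-age scores over the descriptors.
- **`locoage.evaluate`** — detrending/standardization, delayed-entry Cox
  significance tests (via lifelines), the hazard-ratio-to-years
  conversion `years = ln(HR)/0.085`, and Kaplan–Meier risk stratification
  by aging acceleration.
- **`locoage.synthetic`** — seeded generators for survival registers
  (Gompertz baseline, proportional covariate effects, delayed entry,
  administrative censoring) and age/frailty-linked activity tracks.

## Worked example

```python
import numpy as np
import locoage as la

cfg = la.SimConfig(n_subjects=8000, seed=7)
cohort = la.generate_cohort(cfg)
print(f"cohort: {len(cohort)} subjects, {cohort['delta'].sum()} deaths")

fit = la.fit_gompertz(cohort, covariate_cols=["gender"])
print(f"zero-order fit: M0 = {fit.M0:.2e}/yr, Gamma = {fit.Gamma:.4f}/yr")
print(f"mortality doubling time: {np.log(2)/fit.Gamma:.1f} yr")

lin = la.compute_weights(cohort, fit)
xi = (cohort["frailty"] - cohort["frailty"].mean()) / cohort["frailty"].std()
eff = la.effect_closed_form(lin, xi.to_numpy(), ["frailty"])
print(f"linearized effect: beta = {eff.beta_xi[0]:.3f} +- {eff.sigma[0]:.3f}")

rep = la.cox_ph_test(cohort, xi.to_numpy(),
                     adjusters=cohort[["gender"]], name="frailty")
print(f"Cox check: HR = {rep.hazard_ratio:.2f} per SD, "
      f"{rep.years_equivalent:+.1f} yr of life")
```

prints

```
cohort: 8000 subjects, 508 deaths
zero-order fit: M0 = 7.35e-05/yr, Gamma = 0.0789/yr
mortality doubling time: 8.8 yr
linearized effect: beta = 0.456 +- 0.044
Cox check: HR = 1.59 per SD, +5.4 yr of life
```

The simulated cohort carries a latent frailty score entering the log
hazard at 0.5 per SD. The fitted Gompertz exponent (0.079/yr, doubling
time ~8.8 yr) matches the simulated 0.085/yr within its sampling spread at
~500 deaths; the closed-form linearized effect (0.456 ± 0.044) and the
independent semiparametric Cox fit (ln 1.59 = 0.46) agree, and the effect
converts to about +5 years of life expectancy per SD of frailty.

A full staged pipeline (simulate → featurize → fit-bioage → fit-gompertz →
linearize → evaluate) is available from the shell:

```bash
locoage run-all --seed 1 --out results/demo
```

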