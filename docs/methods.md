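# Methods

## The Cox–Gompertz model

Adult all-cause mortality is modelled as a Gompertz baseline with
proportional covariate effects,

    M(t, x) = M0 · exp(Γt) · exp(β·x),

where `t` is age in years, `M0` (1/yr) the initial mortality rate, `Γ`
(1/yr) the Gompertz exponent (mortality doubling time `ln 2 / Γ`; at the
widely used value Γ = 0.085/yr the doubling time is 8 years), and `β` the
log hazard ratios of the covariates `x`. A subject is observed from
enrollment age `t1` to death or last contact `t2` with event indicator
`δ`. Conditioning on survival to `t1` (left truncation) gives the
negative log-likelihood

    −log LH = Σₙ (M0/Γ) e^{β·xⁿ} fₙ − Σₙ δⁿ (log M0 + β·xⁿ + Γ t2ⁿ),
    fₙ = e^{Γ t2ⁿ} − e^{Γ t1ⁿ}.

**Fitting.** `GompertzPH` minimises this in the unconstrained coordinates
`(log M0, log Γ, β)` with analytic gradients: BFGS (gradient tolerance
1e-8, ≤500 iterations) followed by a few damped Newton steps on the
finite-differenced observed information. The polish matters because the
first-order condition in `log M0` is the identity *expected deaths =
observed deaths*, `(M0/Γ) Σ fₙ e^{β·xⁿ} = Σ δⁿ`, which downstream
algebra (the perturbation weights) relies on holding to near machine
precision. An optional L2 penalty `λ‖β‖²` applies to `β` only, never to
the baseline parameters. Initialisation: `Γ₀ = 0.085/yr`; `M0₀` chosen so
expected deaths match observed deaths at `Γ₀`; `β₀ = 0`. Standard errors
come from the inverse observed information. With few deaths the joint
`(M0, Γ)` profile is shallow; `fix_Gamma` pins the exponent, which the
tests show shrinks the seed-to-seed variance of `log M0`.

## Perturbation expansion and hazard learning

To ask whether new features `ξ` (activity descriptors, model scores)
improve a baseline hazard model with fitted effects `β̄` — the
"zero-order" model, here age (through `Γt`) plus gender by default — the
likelihood is expanded to first order in the new effect, with `Γ` held
fixed (the shallow `(M0, Γ)` profile makes joint variation ill-posed).
The expansion yields

- weights `ρⁿ = fₙ e^{β̄·xⁿ} / Σₘ fₘ e^{β̄·xⁿ}` (so `N_d ρⁿ` is the
  zero-order hazard integrated over subject n's follow-up; `δⁿ − N_d ρⁿ`
  is a martingale residual),
- targets `Rⁿ = δⁿ/(ρⁿ N_d) − 1`,
- the closed-form effect `β_ξ = C_ρ⁻¹ Σₙ ξⁿ(δⁿ − N_d ρⁿ)` with
  `C_ρ = N_d(⟨ξᵀξ⟩_ρ − ⟨ξᵀ⟩_ρ⟨ξ⟩_ρ)`,
- the analytic error `σ²_{β_ξ} = 1/(N_d ⟨δξ²⟩_ρ)` — it scales with the
  number of deaths, not the cohort size.

The closed form is exactly the minimiser of the sample-weighted square
loss `L = Σₙ ρⁿ(β_ξ·ξⁿ − Rⁿ)²` over ρ-centred features, which is why any
regressor accepting per-sample weights (including neural networks) can be
trained against `Rⁿ` with weights `ρⁿ`; the package verifies the
equivalence numerically on every test run. Algebraic identities of the
construction — `Σρⁿ = 1`, `ΣρⁿRⁿ = 0`, `Σ(δⁿ − N_dρⁿ) = 0` — hold
whenever the zero-order `M0` is at its MLE, and are asserted to 1e-8
relative in the acceptance tests.

Numerical choices: subjects with zero exposure (`t1 = t2`, hence
`fₙ = 0`) carry no likelihood information and are dropped from the
linearized stage with a logged count; a zero-exposure *death* is a
degeneracy error. For vector `ξ` the reported `σ` is the diagonal of
`C_ρ⁻¹` (the information-matrix generalisation; the scalar formula above
is its one-feature case). `C_ρ` with condition number above 1e12, or a
feature whose ρ-weighted variance is zero up to rounding, raises a
collinearity error naming the features. The rank-based inverse-normal
transform of the targets uses the Blom offset `(rank − 3/8)/(n + 1/4)`
with ties sharing mean ranks; it is monotone, and near-identity in the
bulk for already-normal targets (deviations concentrate in the extreme
order statistics).

The linearization is first-order: `linearized_vs_full_fit` reports the
closed form next to a full maximum-likelihood refit with `ξ` as an extra
covariate. At planted effects ≤ 0.1 per SD the median discrepancy is well
under 0.2 analytic SE; at effects of order 1 a systematic gap appears —
the method's intended regime is small corrections on top of a strong
baseline.

## Activity descriptors

Minute-level activity counts (7 days, 10,080 samples) are discretized
into K = 8 intensity states with bin edges `b_k = e^k − 1`, k = 1…7
(state 0: `a < e − 1`; state k: `b_k ≤ a < b_{k+1}`; state 7:
`a ≥ e⁷ − 1`). Eight states with seven e-fold edges match the 64-d
descriptor; the per-subject transition matrix `T_ij` holds the empirical
rate of moving from state j (columns) to state i, diagonal = staying
put, and visited-source columns sum to 1. The matrix is flattened
**row-major** (a fixed, documented convention), entries below 1e-3
(roughly ten transitions per week) floored at 1e-3, and natural-log
scaled — the natural log pairs with the e-fold bins, and any fixed base
only rescales linear models. Transitions are counted only between
consecutive minutes that both lie in valid days: junctions created by
deleting a non-wear day are artifacts.

Quality filters: overall mean count within [50, 5000]; a day is valid
with ≥ 200 minutes above the rest state; subjects need ≥ 4 valid days
and age < 85 (ages at and above 85 are top-coded in the surveys this
pipeline targets). Aggregate covariates are the mean daily count over
valid days and its negative natural log.

## Biological age

`PCAAge` centres the descriptors (no variance scaling — classical PCA on
log-rates of comparable scale), takes the first right singular vector,
fixes its sign by positive correlation of the score with training age,
and rescales the score to years by univariate regression of age on the
score. No cross-validation: thousands of samples against 64 features.
`RidgeAge` standardises columns (so one penalty is comparable across
features), and picks the penalty from `logspace(−3, 3, 25) · n` by
5-fold cross-validated squared error with a recorded shuffle seed; the
CV path and chosen penalty are kept in `cv_metadata_`. Both predictors
are affine in the descriptor.

## Evaluation

Candidate scores are tested with a semiparametric Cox model on the age
axis (lifelines `CoxPHFitter`, delayed entry at `t1`, Efron tie
handling — the default of both lifelines and R's `survival::coxph`).
Scores are linearly detrended by the other covariates (each column
residualized by OLS on all others, age protected) and standardized, so
hazard ratios are per SD of the residual score. Effects convert to years
of life via the Gompertz exponent: `years = ln(HR)/0.085`, reported to
one decimal.

Risk stratification: per gender, a Gaussian-kernel local-linear smoother
(bandwidth 5 years) of predicted biological age on chronological age
defines the matched-peer reference; a smooth curve rather than a global
line because the biological-chronological relation is visibly nonlinear.
Aging acceleration is the excess over the reference, the sign of the
acceleration splits high/low-risk groups, and the groups are compared
with a delayed-entry log-rank test (hypergeometric variance over risk
sets `{n: t1 < t ≤ t2}`), implemented in-package because lifelines'
log-rank does not support delayed entry. Kaplan–Meier curves use the
product-limit estimator conditioned on the first age with ≥ 10 subjects
at risk: with staggered entry the earliest risk sets hold a handful of
subjects and a single death there would implausibly zero the curve.

## Synthetic data

**Survival register.** Enrollment ages uniform on [18, 84]; independent
Bernoulli risk factors (gender 0.5, smoking 0.2, diabetes 0.1,
hypertension 0.3) with default log hazard ratios ln 1.5, ln 2.3, ln 1.7,
ln 1.2 — order-of-magnitude realistic for adult cohorts; a latent
standard-normal frailty entering the log hazard at 0.5 per SD;
`M0 = 3e-5`/yr and `Γ = 0.085`/yr; administrative censoring uniform on
(0, 9] years, independent of covariates — the simplest mechanism
consistent with "follow-up up to 9 years". Event times are exact
inverse-CDF draws from the Gompertz law conditional on survival to
enrollment: `t = (1/Γ)·ln(e^{Γt1} + ΓE/(M0 e^{β·x}))`, `E ~ Exp(1)`.
At the defaults an 8,000-subject cohort yields roughly 500–550 deaths
(6–7%). All sampling flows from one seeded generator; identical seeds
give bit-identical output.

**Activity tracks.** A mean-reverting minute-level chain over the 8
analysis states: the daytime target level falls linearly with age
(0.030 states/yr) and frailty (0.55 states/SD) from 4.2 at age 18;
nights (7 h) revert to near rest; persistence 0.65, innovation SD 1.1;
counts are drawn uniformly within the occupied state's bin. This plants,
by construction, the feature the descriptor pipeline is meant to
recover: transition behaviour and mean activity decline monotonically
with age and frailty. Setting both slopes to zero gives a null generator
under which the descriptor→PCA pipeline shows no age correlation
(|r| < 0.1 at n = 2000), the negative control the tests assert.

**Descriptor-level cohorts.** For experiments that need many replicates
at n = 5000, `generate_descriptor_cohort` plants the structure directly
in feature space: `dⁿ = s₁(aⁿ + c·zⁿ)u₁ + s₂aⁿu₂ + noise` with
orthonormal `u₁ ⊥ u₂`, standardized age `a`, a mortality-linked
acceleration `z ~ N(0,1)` entering the log hazard (0.4/SD), `s₁ = 3 >
s₂ = 1.5`, `c = 0.5`, unit noise. The dominant component is "biological
age" (age plus acceleration), the secondary component is pure age — so
an unsupervised first principal component inherits the acceleration
(noisier age estimate, strong mortality association) while a supervised
regression exploits both directions to cancel part of `z` (better age
prediction, weaker mortality association). The acceptance suite asserts
exactly this ordering as medians over 20 replicates.

**What the generators do not emulate.** Device physics, non-wear
artifacts beyond the count filters, population age structure (entries
are uniform, not survey-weighted), dependence between censoring and
covariates, and any nonlinearity in the activity–hazard link (the
planted link is linear on the log-hazard scale — the joint law of
activity and mortality beyond proportional hazards is a modelling
choice of this package). Passing tests therefore validate the
estimators and their algebra under the model's own assumptions, not the
numerical values any particular real cohort would produce.

## Problem sizes and tolerances used in the tests

Closed-form/regression equivalence: 50 cohorts of n = 500, agreement to
1e-8. Algebraic identities: 1e-8 relative. Parameter recovery: 20
replicates at n = 8000 (Γ within ±0.01, β within 3 SE, ≥18/20).
Analytic-error calibration: 200 replicates at ~470 and ~950 deaths
(SD ratio within 15%, variance halving within [0.35, 0.70]).
Supervised-vs-unsupervised contrast: 20 replicates at n = 5000, median
comparison. Monte-Carlo track checks use 300–2000 subjects.

## Known limitations

- The perturbation effect is first-order; large effects (≳0.5 per SD)
  are systematically attenuated relative to the full MLE — by design,
  the regime is small corrections to a strong baseline model.
- `Γ` is treated as free only in the full fit; the linearized stage
  requires it fixed, so feature effects that act through the age slope
  are out of reach there.
- The per-feature analytic `σ` assumes the zero-order model is correct;
  misspecified baselines inflate the empirical spread beyond it.
- The local-linear reference curve uses a fixed 5-year bandwidth; very
  sparse age ranges at the extremes borrow strength from the interior.
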