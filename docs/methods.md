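# Methods

This note documents the statistical machinery implemented in `ppct`: the
estimators, the prognostic models that feed them, the synthetic study
conditions used throughout the test suite, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Setting and notation

A two-arm randomized trial has N = m + n patients, treatment indicator
T ∈ {0,1} (m treated, n control), outcome Y (here: 1-year change of a bounded
clinical severity score, SARA 0–40) and baseline covariates X including
pre-inclusion visit history. The estimand is the average treatment effect
ATE = E[Y|T=1] − E[Y|T=0]. A *prognostic score* f(X) is an external model's
prediction of the untreated outcome, trained on natural-history data from
patients never exposed to treatment and personalized only on pre-treatment
visits, so f(X) is a pre-randomization variable and any estimator that
adjusts for it linearly remains unbiased under randomization.

Moment conventions: all sample variances and covariances use n−1
denominators. σ_f is the pooled (both-arm) SD of the scores;
ρ_t = Cov(f, Y | T=t) / (σ_f σ_t) as in the estimator-variance algebra (this
is not exactly a within-arm Pearson correlation unless the score spread is
arm-independent, which randomization delivers asymptotically).

## Estimators

**Classic.** Difference in arm means; variance s₀²/n + s₁²/m; CI from the
exact normal quantile (never the 1.96 shortcut, so printed-interval
round-trips carry no extra rounding error).

**PPI / PPI++ / PPCT.** The naive prediction ATE, mean(Y|1) − mean(f|1), is
biased by both model error and the placebo effect; the control-arm rectifier
Δ = mean(Y − f | 0) absorbs exactly those two terms because they are common
to both arms. Subtracting gives the PPI estimator, the λ = 1 member of

    ATE(λ) = mean(Y − λ f | T=1) − mean(Y − λ f | T=0),

unbiased for every fixed λ. Its plug-in variance is the quadratic

    V(λ) = s₀²/n + s₁²/m − 2λ (c₁/m + c₀/n) + λ² s_f² (1/m + 1/n),

with c_t the within-arm score–outcome covariance and s_f² the pooled score
variance. Minimizing over λ gives the closed form

    λ* = (c₁/m + c₀/n) / (s_f² (1/m + 1/n)),

and V(λ*) = s₀²/n + s₁²/m − λ*² s_f² (1/m + 1/n): a non-negative quantity is
subtracted from the classic variance, so the dominance V(λ*) ≤ V(classic)
holds exactly, dataset by dataset (asserted as an exact inequality in the
tests). In the simplified regime σ₀ = σ₁ = σ_f and ρ₀ = ρ₁ = ρ the ratio
collapses to V(PPCT)/V(classic) = 1 − ρ² = 1 − R².

Estimating λ on the analysis data voids exact unbiasedness in small samples
whenever sample covariances correlate with sample means (any non-Gaussian
outcome; with bounded, clipped scores this is the norm). The `cross_fit`
mode therefore estimates λ on K−1 arm-stratified folds and applies it to the
held-out fold; since each patient's λ is independent of their own data the
cross-fitted estimator is exactly unbiased, at the price of extra λ noise
(slightly larger variance). Defaults: K = 5, seeded fold assignment; the
reported λ and plug-in variance use the fold average. A negative plug-in
variance (possible when λ is fixed far from λ* in tiny samples) is floored
at 0 with a warning rather than raised.

**Prognostic-covariate ANCOVA.** OLS of Y on (1, T, f); the reported
variance is the HC1 heteroskedasticity-robust sandwich variance of the T
coefficient (HC1's small-sample df scaling suits 45-patient trials; HC0 is a
one-line change). The π-weighted asymptotic form
(σ₀²/π₀ + σ₁²/π₁ − ξ*² V(f)/(π₀π₁))/N with ξ* = π₀ρ₁ + π₁ρ₀ is attached as
`AncovaComponents` for diagnostics; written with correlations it coincides
with the covariance-based asymptotic variance only when σ₀ = σ₁ = σ_f, so
the sandwich value is authoritative and the plug-in is verified against it
in the equal-SD regime.

**AIPW.** Influence function
φ = μ̂₁(X) − μ̂₀(X) + T(Y−μ̂₁)/π − (1−T)(Y−μ̂₀)/(1−π) with the known
randomization probability π = m/N; estimate = mean(φ), variance =
Var(φ)/N. Outcome regressions μ̂_t are per-arm ridge fits (standardized
covariates, α = 1) cross-fitted over arm-stratified folds so no patient is
predicted by a model trained on their own outcome. The default covariate set
is the baseline primary score alone — in sparse baseline data a single
strong covariate out-predicts the larger set.

**H-AIPW.** One influence-function component per information source: the
trial-only AIPW φ⁰, plus for each external prognostic model k the component
with f_k substituted for both potential-outcome regressions (external models
are trained on untreated cohorts and carry no arm information, so
μ̂₁ = μ̂₀ = f_k and the first term cancels). Every component is unbiased for
the ATE; the combination weight vector minimizes w'Σ̂w over the probability
simplex, Σ̂ the empirical covariance of the components divided by N plus a
1e−8 ridge for conditioning (the simplex constraint is a design choice — it
keeps the combination interpretable and the estimate inside the convex hull
of the component estimates). Solved by SLSQP on the trace-normalized matrix
(the raw entries are O(1/N) and would sit below optimizer tolerances).

**Permutation test.** Arm labels are permuted preserving arm sizes;
two-sided p = (1 + #{|stat_perm| ≥ |stat_obs|})/(B+1). The standardized
skewness and excess kurtosis of the permutation null are returned as a
diagnostic for how well the normal-theory CIs can be trusted at N = 45.

## Prognostic models

**Linear.** For each training patient the two visits whose gap is closest to
one year (admissible window 0.5–1.5 years, ties toward the earlier pair)
define a (baseline, annualized progression) pair; OLS of progression on
baseline. Single-visit patients cannot form a pair and are excluded.

**Linear mixed.** Random intercept + random slope of score on time, REML via
statsmodels MixedLM (optimizers tried in order bfgs → lbfgs → powell; a
non-converged fit raises with the attempt log). A new patient's prediction
is the BLUP-conditional slope given their pre-inclusion visits, applied over
the horizon; with fewer than two distinct visit times the individual slope
is not identified and the population slope is used.

**Disease-course model (DCM).** Scores normalized by their ceilings (SARA
40; INAS 16, configurable) follow a population logistic curve evaluated at
the reparametrized disease age ψᵢ(t) = t̄ + e^{ξᵢ}(t − t̄ − τᵢ):
g(ψ) = expit(b(ψ − t̄) + logit(p₀)) with b = v₀/(p₀(1−p₀)), so the curve
passes through p₀ at t̄ with slope v₀ (normalized units/year). τᵢ (years,
Gaussian, SD σ_τ) moves a patient's disease earlier or later; ξᵢ (Gaussian,
SD σ_ξ) multiplies their progression speed. The multivariate variant shares
(τᵢ, ξᵢ) across features with per-feature (p₀, v₀) and noise, all anchored
at a common t̄. Per-feature individual intercept offsets exist in the
parameter container but are not estimated by the default fitter; the shared
latent disease age carries the individual variation.

*Identifiability.* (p₀, t̄) slide jointly along the curve, so t̄ is anchored
at the mean observation time rather than optimized; recovery is assessed on
the curve itself (fitted (p₀, v₀) against the generating curve evaluated at
the same anchor).

*Calibration.* Deterministic alternating MAP (block coordinate descent)
instead of a stochastic EM: per sweep, (1) per-feature quasi-Newton update
of (logit p₀, log v₀) — run before the individual step so the first sweep
fits the marginal average curve; doing individuals first lets per-patient
parameters absorb the initial curve misfit and traps the fit — then (2)
per-patient 2-parameter L-BFGS-B MAP of (τ, ξ) with analytic gradients,
bounded (|τ| ≤ 80 y, |ξ| ≤ 3) against overflow, warm-started and, on the
first sweep, also started from a curve-inversion guess of τ; then (3)
closed-form hyper-parameter updates. The noise update is SSE/n_obs; the
random-effect updates are Laplace-corrected, σ² ← mean(MAP² + posterior
variance) with the posterior variance from the Gauss–Newton Hessian —
without the correction the MAP shrinkage collapses σ_ξ to its floor on
sparse (2–5 visit) records and biases v₀ upward by >20%. Floors: noise 1e−3
(normalized), σ_τ 1e−2 y, σ_ξ 1e−3. The outer loop stops when the penalized
objective improves by < 1e−6 (relative) or after 200 sweeps; a run that
never decreases the objective raises `ConvergenceError`. Per-patient
optimizer tolerance 1e−8.

*Personalization and prediction.* MAP of (τ, ξ) for a new patient under the
fitted priors; with a single distinct timepoint ξ is not identifiable and is
pinned at its prior mean (only τ is estimated). The prognostic score is
f(X) = curve(t_baseline + horizon) − curve(t_baseline) on the raw scale,
horizon 1 year by default (0 allowed, returning exactly 0). All visits are
weighted equally in the personalization likelihood. `score_trial` refuses
any overlap between training-cohort and trial patient ids.

## Evaluation and design

R² is the squared Pearson correlation between predicted and observed
progression — the quantity that governs linear-adjustment variance
reduction; it is sign-invariant and undefined (error) for constant inputs.
Trial-simulating cross-validation reduces each held-out natural-history
patient to the visit pair closest to a one-year gap (window 0.5–1.5 y, ties
to the earlier pair), keeps strictly earlier visits as pre-inclusion data,
drops later ones, and averages per-fold R² unweighted over the 10 folds;
patients with no admissible pair are excluded with a logged count.
Predictions for a record use the record's actual pair gap as horizon, so
model and outcome refer to the same interval. The sample-size rule is
n_required = ⌈n_classic (1 − R²)⌉ (ceiling on the required size, hence a
conservative floor on patients saved); R² = 1 is rejected as degenerate.
CI-width reduction between two estimators with symmetric normal intervals is
100(1 − √(V_c/V_r)).

## Synthetic study conditions

The generators define the conditions under which every stochastic test runs.

*Natural-history cohort* (defaults): 218 patients, 2–5 visits each (median
3; probabilities 0.3/0.3/0.2/0.2), entry age ~ N(45, 8²) on the latent
disease-age axis, follow-up uniform 1–4 years — the sparse, short-follow-up
structure of pooled ataxia registries. Trajectories: logistic with ceiling
40, midpoint age 45, rate 0.18/y (population slope 1.8 SARA pts/y at the
midpoint), τ ~ N(0, 8²) years, ξ ~ N(0, 0.8²), visit noise SD 1.1 SARA
points (within the 1–5.5 point intra-rater variability reported for SARA).
The secondary score is an independent-noise monotone transform of the same
latent disease age (ceiling 16, rate 0.12, midpoint 3 years later, noise
0.8), so it genuinely sharpens the estimate of (τ, ξ) in the multivariate
model. *Trial*: 23 placebo / 22 treated, visits at months 0/6/12, 1–4
retrospective pre-inclusion visits (probabilities 0.35/0.25/0.2/0.2, i.e.
60% of patients with at most two — chart-review sparsity), drawn 0.25–3
years before baseline; entry age N(41, 4²) — early-stage recruitment, below
the curve midpoint; treatment effect and placebo effect enter as additive
shifts on post-baseline progression, pro-rated by time on trial; all values
clipped to the score bounds after noise. The outcome is the noisy month-12
minus month-0 score.

These defaults were calibrated once, by tracing the signal chain, to land in
a realistic operating regime: classic ATE variance ≈ 0.35, DCM R² with
pre-inclusion ≈ 0.17 on average (long-run mean; single 45-patient replicates
scatter widely), baseline-only R² ≈ 0.06, annual progression ~1–1.5 points.

What the generator deliberately reproduces — and what it does not:

- *Bounded scores with clipping.* Near the floor/ceiling the realized
  treatment effect is attenuated, so the generator's `true_ate` is the
  effect on the latent progression, not exactly the realized ATE there.
  Unbiasedness oracles are therefore run in interior regimes where the
  bounds do not bind.
- *Baseline-noise coupling.* The noisy month-0 measurement enters both the
  outcome (Y = S₁₂ − S₀) and the personalization data, correlating
  prediction error with outcome noise (regression to the mean). This channel
  exists in the real design and is kept; it is the main reason baseline-only
  personalization predicts poorly.
- Not modeled: item-level score structure, informative dropout, rater
  effects, visit-time irregularity correlated with severity, or distribution
  shift between cohort and trial populations. Passing tests therefore speak
  to estimator correctness and model recovery under the stated conditions,
  not to robustness against those real-data features.

The Gaussian regime sampler bypasses trajectories entirely and draws
(Y, f) pairs with exact prescribed moments per arm; it is the reference
condition for coverage and for the 1 − R² variance-ratio law, and its score
column doubles as the baseline covariate for the AIPW-family estimators.

## Problem sizes used in the test suite

Monte-Carlo checks use: 3000 replicates at n = m = 500 for the
variance-ratio law (tolerance 0.03); 2000 replicates at n = m = 100 for
coverage (0.95 ± 0.02); 4000 replicate 45-patient trials for the cross-fit
bias/variance comparison; 50 replicate trials for the pre-inclusion vs
baseline-only R² comparison; a 200-patient low-noise (SD 0.3) cohort for
population-parameter recovery (15% tolerance on the curve, 35% on
random-effect SDs — the Laplace-EM point estimates of variance components
carry more sampling error than the curve itself). The λ* grid oracle scans
step 1e−4 over [−3, 3). These sizes give Monte-Carlo error comfortably below
each asserted tolerance while keeping the full suite around five minutes on
one CPU.

## Known limitations

- The DCM fitter is a MAP/Laplace approximation, not a posterior sampler:
  random-effect SDs inherit some shrinkage bias on very sparse records, and
  the noise SD is underestimated when individuals absorb residual structure.
- λ* uses the pooled score variance in the denominator (the form whose
  minimizer it is); with strongly arm-dependent score spread a per-arm
  variance profile would differ slightly.
- The H-AIPW weight rule (simplex-constrained minimum variance with a small
  ridge) is one faithful reading of hybrid combination; unconstrained
  weights could in principle do better asymptotically but can leave the
  convex hull in small samples.
- `required_sample_size` treats R² as known; it does not propagate the
  substantial sampling error of an R² estimated from a 45-patient trial.
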