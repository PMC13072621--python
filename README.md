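# ppct — prediction-powered treatment-effect estimation for small trials

Randomized controlled trials in rare neurodegenerative diseases are chronically
underpowered: eligible patients are scarce, outcomes are noisy clinical scores,
and placebo arms are ethically costly. `ppct` implements a family of average
treatment effect (ATE) estimators that fold *prognostic scores* — predictions
of each patient's untreated outcome, learned from external natural-history
cohorts — into the trial analysis, shrinking confidence intervals and required
sample sizes without biasing the estimate.

The package targets the spinocerebellar-ataxia setting (SARA score 0–40,
1-year progression as primary outcome, a ~45-patient trial backed by a
~218-patient natural-history cohort) but every component is generic.

## What it provides

**Estimators** (`ppct.estimators`), for a trial with `m` treated and `n`
control patients, outcomes `Y`, prognostic scores `f(X)`:

- classic difference in means, `Var = σ₀²/n + σ₁²/m`;
- PPI: the naive prediction-based ATE debiased by the control-arm *rectifier*
  `Δ = mean(Y − f(X) | T=0)`, which absorbs prediction error and placebo effect;
- PPI++/PPCT: predictions weighted by λ, with the variance-minimizing

  `λ* = (Ĉov(f,Y|T=1)/m + Ĉov(f,Y|T=0)/n) / (σ̂_f² (1/m + 1/n))`

  giving `Var(PPCT; λ*) = σ₀²/n + σ₁²/m − λ*² σ_f² (1/m + 1/n)`, never larger
  than the classic variance; optional K-fold cross-fitted λ removes the
  small-sample bias of tuning λ on the analysis data;
- prognostic-covariate ANCOVA (`Y ~ T + f(X)`) with HC1 sandwich variance;
- AIPW with cross-fitted ridge outcome regressions, and hybrid H-AIPW, a
  minimum-variance simplex combination of the trial-only AIPW influence
  function with one influence function per external prognostic model;
- exact-quantile normal CIs and arm-label permutation tests.

In the simplified regime (σ₀ = σ₁ = σ_f, ρ₀ = ρ₁) the PPCT variance obeys
`Var(PPCT; λ*) = (1 − R²) · Var(classic)`, where R² is the squared correlation
between predicted and observed progression — so a model with R² = 0.145 buys a
14.5% smaller trial at equal power.

**Prognostic models** (`ppct.prognostic_models`): linear regression of 1-year
progression on baseline, a random-intercept/random-slope mixed model (BLUP
personalization), and a nonlinear mixed-effects *disease-course model*:
normalized scores follow a population logistic curve evaluated at a
reparametrized disease age `ψᵢ(t) = t̄ + e^{ξᵢ}(t − t̄ − τᵢ)`; per-patient MAP
personalization from pre-inclusion visits yields the predicted untreated
1-year progression f(X). The multivariate variant shares (τᵢ, ξᵢ) across SARA
and INAS curves.

**Evaluation & design** (`ppct.evaluation_design`): squared-correlation R²,
trial-simulating 10-fold cross-validation (each test patient truncated to a
baseline/≈1-year pair plus pre-inclusion history), CI-width accounting, the
variance-ratio Monte-Carlo experiment, and the sample-size rule
`n_required = ⌈n·(1 − R²)⌉`.

**Synthetic data** (`ppct.synthetic_data`): seeded generators for
natural-history cohorts, ATRIL-like 45-patient trials with known ground-truth
treatment effect, and a direct Gaussian sampler of (outcome, score) pairs with
prescribed moments.

## Worked example

```python
from ppct import (TrajectoryParams, TrialScenario, generate_cohort,
                  generate_trial, fit_dcm, score_trial, difference_in_means,
                  ppct_ate, r_squared, required_sample_size,
                  ci_width_reduction)

params = TrajectoryParams()                       # SCA2-like trajectories
cohort = generate_cohort(params, 218, seed=11)    # natural-history cohort
trial = generate_trial(TrialScenario(seed=57), params)   # 23 placebo / 22 treated

model = fit_dcm(cohort, features=["SARA"])        # disease-course model
scores = score_trial(model, trial)                # prognostic scores f(X)

classic = difference_in_means(trial)
ppct = ppct_ate(trial, scores)
r2 = r_squared(scores.scores, trial.outcome).r_squared

print(f"classic: {classic.estimate:+.3f}  var {classic.variance:.3f}  "
      f"CI [{classic.ci_low:.3f}, {classic.ci_high:.3f}]")
print(f"ppct:    {ppct.estimate:+.3f}  var {ppct.variance:.3f}  "
      f"CI [{ppct.ci_low:.3f}, {ppct.ci_high:.3f}]  lambda*={ppct.lam:.3f}")
print(f"R^2 = {r2:.3f}; width reduction {ci_width_reduction(ppct, classic):.1f}%")
print(required_sample_size(45, r2))
```

prints (seeds as above):

```
classic: +0.455  var 0.493  CI [-0.921, 1.831]
ppct:    +0.060  var 0.410  CI [-1.195, 1.315]  lambda*=0.912
R^2 = 0.171; width reduction 8.8%
SampleSizeResult(n_classic=45, r_squared=0.17079578959567107, required_n=38,
                 patients_saved=7, reduction_pct=17.079578959567108)
```

The trial has no true effect; both intervals cover zero, but the
prognostic-score estimator's interval is 8.8% narrower — the score explains
17% of the outcome variance, so PPCT removes that share from the estimator's
variance. A model of this accuracy would let an equally powered trial enroll
7 fewer patients. (R² varies substantially across 45-patient replicates;
this draw sits near the long-run mean of the default conditions.)

A command-line pipeline wraps the same flow:

```bash
ppct run --out-dir results/demo --seed 1 --families linear,dcm_univariate
```

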