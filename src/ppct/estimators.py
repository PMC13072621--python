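"""Average-treatment-effect estimators for two-arm trials with prognostic scores.

Implements the family of estimators that trade prognostic-model accuracy for
confidence-interval width:

* classic difference in means, with variance sigma0^2/n + sigma1^2/m;
* prediction-powered inference (PPI): naive prediction-based ATE debiased by
  the control-arm rectifier, i.e. the lambda = 1 member of the family below;
* PPI++/PPCT: predictions weighted by lambda, with the variance-minimizing
  closed-form lambda* and an optional cross-fitted lambda;
* prognostic-covariate ANCOVA with heteroskedasticity-robust (sandwich)
  variance;
* AIPW with cross-fitted ridge outcome regressions, and the hybrid H-AIPW
  that adds influence-function components built from external
  natural-history-trained prognostic models;
* exact-quantile normal confidence intervals and label-permutation tests.

The PPI++ point estimate is

    ATE(lambda) = mean(Y - lambda f | T=1) - mean(Y - lambda f | T=0)

whose plug-in variance is the quadratic

    V(lambda) = s0^2/n + s1^2/m - 2 lambda (c1/m + c0/n)
                + lambda^2 sf^2 (1/m + 1/n)

with arm-wise outcome variances s_t^2, arm-wise covariances c_t = Cov(f, Y |
T=t) and pooled score variance sf^2 (all with n-1 denominators). Minimizing
over lambda gives

    lambda* = (c1/m + c0/n) / (sf^2 (1/m + 1/n))

and substituting back yields the familiar subtracted form
V(lambda*) = s0^2/n + s1^2/m - lambda*^2 sf^2 (1/m + 1/n), manifestly no
larger than the classic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.linear_model import Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .datasets import PrognosticScoreSet, TrialDataset


@dataclass
class AteEstimate:
    """Point estimate, variance and normal CI of one ATE estimator."""

    method: str
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    lam: float | None = None
    n: int = 0
    m: int = 0
    level: float = 0.95
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


@dataclass
class AncovaComponents:
    """Plug-in ingredients of the ANCOVA asymptotic variance.

    ``eq_variance`` is the asymptotic value pi-weighted form
    (sigma0^2/pi0 + sigma1^2/pi1 - xi*^2 V / (pi0 pi1)) / N with
    xi* = pi0 rho1 + pi1 rho0 and V = Var(f); ``sandwich_variance`` is the
    finite-sample robust estimate actually reported.
    """

    pi0: float
    pi1: float
    xi_star: float
    v_f: float
    eq_variance: float
    sandwich_variance: float


@dataclass
class PpctConfig:
    """How the prediction weight lambda is chosen for PPCT."""

    lambda_mode: str = "optimal"  # fixed | optimal | cross_fit
    lambda_value: float = 1.0
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_mode not in ("fixed", "optimal", "cross_fit"):
            raise ValueError(f"unknown lambda_mode: {self.lambda_mode!r}")
        if self.lambda_mode == "cross_fit" and self.k_folds < 2:
            raise ValueError("cross_fit mode needs k_folds >= 2")


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    n_perm: int
    null_mean: float
    null_sd: float
    null_skewness: float
    null_excess_kurtosis: float
    null_stats: np.ndarray


def normal_ci(estimate: float, variance: float, level: float = 0.95) -> tuple[float, float]:
    """estimate +/- z_{(1+level)/2} * sqrt(variance), exact normal quantile."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    if variance < 0:
        raise ValueError("variance must be non-negative")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(variance)
    return float(estimate - half), float(estimate + half)


def _arm_split(trial: TrialDataset):
    y = trial.outcome
    t = trial.arm
    y1, y0 = y[t == 1], y[t == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValueError("both arms must be non-empty")
    return y0, y1


def _classic_variance(y0: np.ndarray, y1: np.ndarray) -> float:
    # shared expression (same floating-point order) for classic and PPCT(0)
    return float(np.var(y0, ddof=1)) / len(y0) + float(np.var(y1, ddof=1)) / len(y1)


def difference_in_means(trial: TrialDataset, level: float = 0.95) -> AteEstimate:
    """Classic difference-in-means ATE with variance s0^2/n + s1^2/m."""
    y0, y1 = _arm_split(trial)
    est = float(np.mean(y1) - np.mean(y0))
    var = _classic_variance(y0, y1)
    lo, hi = normal_ci(est, var, level)
    return AteEstimate("classic", est, var, lo, hi, lam=None,
                       n=len(y0), m=len(y1), level=level)


def _scores_array(trial: TrialDataset, scores) -> np.ndarray:
    if isinstance(scores, PrognosticScoreSet):
        return scores.aligned_with(trial)
    f = np.asarray(scores, dtype=float)
    if len(f) != trial.n_total:
        raise ValueError("need exactly one score per trial patient")
    return f


def naive_ate(trial: TrialDataset, scores) -> float:
    """Treated-arm mean outcome minus treated-arm mean prediction (biased)."""
    f = _scores_array(trial, scores)
    t = trial.arm
    return float(np.mean(trial.outcome[t == 1]) - np.mean(f[t == 1]))


def rectifier(trial: TrialDataset, scores) -> float:
    """Control-arm mean of (observed - predicted) outcomes.

    Absorbs both the model's prediction bias and any arm-common (placebo)
    shift, which is what makes the prediction-powered estimators unbiased.
    """
    f = _scores_array(trial, scores)
    t = trial.arm
    return float(np.mean(trial.outcome[t == 0] - f[t == 0]))


def _ppi_moments(trial: TrialDataset, f: np.ndarray):
    y = trial.outcome
    t = trial.arm
    y0, y1 = y[t == 0], y[t == 1]
    f0, f1 = f[t == 0], f[t == 1]
    n, m = len(y0), len(y1)
    s0 = float(np.var(y0, ddof=1))
    s1 = float(np.var(y1, ddof=1))
    sf = float(np.var(f, ddof=1))
    c0 = float(np.cov(f0, y0, ddof=1)[0, 1])
    c1 = float(np.cov(f1, y1, ddof=1)[0, 1])
    return n, m, s0, s1, sf, c0, c1


def lambda_star(trial: TrialDataset, scores) -> float:
    """Closed-form variance-minimizing prediction weight.

    lambda* = (c1/m + c0/n) / (sf^2 (1/m + 1/n)); errors on zero score
    variance, where every lambda gives the same estimator.
    """
    f = _scores_array(trial, scores)
    n, m, _, _, sf, c0, c1 = _ppi_moments(trial, f)
    if sf <= 0:
        raise ValueError("prognostic scores have zero variance; lambda* undefined")
    return (c1 / m + c0 / n) / (sf * (1.0 / m + 1.0 / n))


def ppi_variance(trial: TrialDataset, scores, lam):
    """Plug-in variance of the PPI++ estimator at a given lambda.

    ``lam`` may be a scalar or an array (the quadratic is evaluated
    elementwise, convenient for profiling over a lambda grid). May be
    negative in tiny samples before flooring; callers floor at 0.
    """
    f = _scores_array(trial, scores)
    n, m, s0, s1, sf, c0, c1 = _ppi_moments(trial, f)
    lam = np.asarray(lam, dtype=float)
    base = s0 / n + s1 / m
    out = base - 2.0 * lam * (c1 / m + c0 / n) + lam * lam * sf * (1.0 / m + 1.0 / n)
    return float(out) if out.ndim == 0 else out


def _ppi_point(trial: TrialDataset, f: np.ndarray, lam) -> float:
    y = trial.outcome
    t = trial.arm
    adj = y - np.asarray(lam) * f
    return float(np.mean(adj[t == 1]) - np.mean(adj[t == 0]))


def _stratified_folds(arm: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold ids balanced within each arm, seed-controlled."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(arm), dtype=int)
    for a in (0, 1):
        idx = np.flatnonzero(arm == a)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def ppct_ate(
    trial: TrialDataset,
    scores,
    config: PpctConfig | None = None,
    level: float = 0.95,
) -> AteEstimate:
    """PPI++/PPCT estimator with fixed, optimal or cross-fitted lambda.

    At lambda = 0 this reproduces the difference-in-means estimator exactly
    (bit for bit); at the closed-form lambda* its plug-in variance is the
    classic variance minus lambda*^2 sf^2 (1/m + 1/n). In cross-fit mode
    lambda is estimated on K-1 folds and applied to the held-out fold
    (stratified by arm), removing the small-sample bias of tuning lambda on
    the same data; the reported lambda and variance use the fold average.
    """
    config = config or PpctConfig()
    f = _scores_array(trial, scores)
    t = trial.arm
    n, m = int((t == 0).sum()), int((t == 1).sum())

    if config.lambda_mode == "fixed":
        lam_report = float(config.lambda_value)
        est = _ppi_point(trial, f, lam_report)
    elif config.lambda_mode == "optimal":
        lam_report = lambda_star(trial, scores)
        est = _ppi_point(trial, f, lam_report)
    else:  # cross_fit
        k = min(config.k_folds, n, m)
        fold = _stratified_folds(t, k, config.seed)
        lam_patient = np.empty(trial.n_total)
        fold_lams = []
        for j in range(k):
            train = fold != j
            sub = TrialDataset(patients=trial.patients.loc[train])
            lam_j = lambda_star(sub, f[train])
            lam_patient[fold == j] = lam_j
            fold_lams.append(lam_j)
        lam_report = float(np.mean(fold_lams))
        est = _ppi_point(trial, f, lam_patient)

    var = ppi_variance(trial, f, lam_report)
    if var < 0:
        warnings.warn(
            "plug-in PPCT variance was negative in this small sample; floored at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        var = 0.0
    lo, hi = normal_ci(est, var, level)
    return AteEstimate("ppct", est, var, lo, hi, lam=lam_report,
                       n=n, m=m, level=level,
                       extras={"lambda_mode": config.lambda_mode})


def ppi_ate(trial: TrialDataset, scores, level: float = 0.95) -> AteEstimate:
    """Prediction-powered inference estimator: naive ATE minus rectifier
    (the lambda = 1 member of the PPI++ family)."""
    out = ppct_ate(trial, scores,
                   PpctConfig(lambda_mode="fixed", lambda_value=1.0), level)
    out.method = "ppi"
    return out


def ancova_ate(trial: TrialDataset, scores, level: float = 0.95) -> AteEstimate:
    """Prognostic-covariate ANCOVA: OLS of Y on treatment and f(X).

    The reported variance is the heteroskedasticity-robust HC1 sandwich
    variance of the treatment coefficient; the plug-in asymptotic form is
    attached as :class:`AncovaComponents`.
    """
    f = _scores_array(trial, scores)
    if np.std(f) == 0:
        raise ValueError("prognostic score is constant; collinear with intercept")
    y = trial.outcome
    t = trial.arm.astype(float)
    X = sm.add_constant(np.column_stack([t, f]))
    res = sm.OLS(y, X).fit(cov_type="HC1")
    est = float(res.params[1])
    var = float(res.cov_params()[1, 1])

    y0, y1 = _arm_split(trial)
    n, m, big_n = len(y0), len(y1), trial.n_total
    pi1 = m / big_n
    pi0 = n / big_n
    summary = (scores if isinstance(scores, PrognosticScoreSet)
               else PrognosticScoreSet.from_trial(trial, f))
    v_f = float(np.var(f, ddof=1))
    xi = pi0 * summary.rho1 + pi1 * summary.rho0
    s0 = float(np.var(y0, ddof=1))
    s1 = float(np.var(y1, ddof=1))
    eq_var = (s0 / pi0 + s1 / pi1 - (xi * xi) * v_f / (pi0 * pi1)) / big_n
    comp = AncovaComponents(pi0=pi0, pi1=pi1, xi_star=float(xi), v_f=v_f,
                            eq_variance=float(eq_var), sandwich_variance=var)
    lo, hi = normal_ci(est, var, level)
    return AteEstimate("ancova", est, var, lo, hi, lam=None, n=n, m=m,
                       level=level, extras={"components": comp})


def _aipw_influence(trial: TrialDataset, mu0, mu1, propensity: float) -> np.ndarray:
    y = trial.outcome
    t = trial.arm.astype(float)
    mu0 = np.asarray(mu0, dtype=float)
    mu1 = np.asarray(mu1, dtype=float)
    return (mu1 - mu0
            + t * (y - mu1) / propensity
            - (1.0 - t) * (y - mu0) / (1.0 - propensity))


def aipw_from_predictions(
    trial: TrialDataset,
    mu0,
    mu1,
    propensity: float | None = None,
    level: float = 0.95,
    method: str = "aipw",
) -> AteEstimate:
    """Doubly robust AIPW estimator from supplied per-arm outcome predictions.

    With the known randomization probability the estimator is consistent for
    any outcome model; variance is the sample variance of the influence
    function divided by N.
    """
    if propensity is None:
        propensity = trial.m_treated / trial.n_total
    if not 0.0 < propensity < 1.0:
        raise ValueError("propensity must lie strictly inside (0, 1)")
    phi = _aipw_influence(trial, mu0, mu1, propensity)
    est = float(np.mean(phi))
    var = float(np.var(phi, ddof=1)) / trial.n_total
    lo, hi = normal_ci(est, var, level)
    return AteEstimate(method, est, var, lo, hi, lam=None,
                       n=trial.n_control, m=trial.m_treated, level=level)


def crossfit_outcome_predictions(
    trial: TrialDataset,
    covariates: tuple[str, ...] = ("baseline_sara",),
    ridge_alpha: float = 1.0,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-fitted per-arm ridge predictions mu0(X_i), mu1(X_i) for all i."""
    missing = [c for c in covariates if c not in trial.patients.columns]
    if missing:
        raise ValueError(f"trial table lacks covariate columns: {missing}")
    X = np.asarray(trial.patients[list(covariates)], dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    y = trial.outcome
    t = trial.arm
    k = max(2, min(k_folds, trial.n_control, trial.m_treated))
    fold = _stratified_folds(t, k, seed)
    mu = {0: np.empty(len(y)), 1: np.empty(len(y))}
    for j in range(k):
        test = fold == j
        for a in (0, 1):
            train = (~test) & (t == a)
            model = make_pipeline(StandardScaler(), Ridge(alpha=ridge_alpha))
            model.fit(X[train], y[train])
            mu[a][test] = model.predict(X[test])
    return mu[0], mu[1]


def aipw_ate(
    trial: TrialDataset,
    level: float = 0.95,
    covariates: tuple[str, ...] = ("baseline_sara",),
    ridge_alpha: float = 1.0,
    k_folds: int = 5,
    seed: int = 0,
    propensity: float | None = None,
) -> AteEstimate:
    """Trial-only AIPW with cross-fitted ridge outcome regressions.

    Defaults to the single baseline primary-score covariate, the
    specification with the best predictive accuracy in sparse baseline data.
    """
    mu0, mu1 = crossfit_outcome_predictions(trial, covariates, ridge_alpha,
                                            k_folds, seed)
    return aipw_from_predictions(trial, mu0, mu1, propensity, level)


def _simplex_min_variance(cov: np.ndarray) -> np.ndarray:
    """argmin_w w' cov w over the probability simplex.

    The matrix is rescaled to unit mean diagonal first (the argmin is scale
    invariant) so the optimizer's tolerances are meaningful for the tiny
    per-N variances involved.
    """
    k = cov.shape[0]
    scale = float(np.trace(cov)) / k
    c = cov / scale if scale > 0 else cov
    x0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        lambda w: w @ c @ w,
        x0,
        jac=lambda w: 2.0 * c @ w,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(k)}],
        options={"ftol": 1e-12, "maxiter": 300},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def haipw_ate(
    trial: TrialDataset,
    external_scores: list,
    level: float = 0.95,
    covariates: tuple[str, ...] = ("baseline_sara",),
    ridge_alpha: float = 1.0,
    k_folds: int = 5,
    seed: int = 0,
    propensity: float | None = None,
    weight_ridge: float = 1e-8,
) -> AteEstimate:
    """Hybrid AIPW combining the trial-only estimator with external models.

    One influence-function component per external prognostic model is formed
    by plugging its prediction in for both potential outcomes (external
    models are trained on untreated natural-history data and do not
    distinguish arms). The convex combination weights minimize the estimated
    variance of the combined estimator over the simplex, so the result is
    never asymptotically worse than trial-only AIPW.
    """
    if not external_scores:
        raise ValueError("haipw_ate needs at least one external score set")
    if propensity is None:
        propensity = trial.m_treated / trial.n_total
    if not 0.0 < propensity < 1.0:
        raise ValueError("propensity must lie strictly inside (0, 1)")

    mu0, mu1 = crossfit_outcome_predictions(trial, covariates, ridge_alpha,
                                            k_folds, seed)
    components = [_aipw_influence(trial, mu0, mu1, propensity)]
    for s in external_scores:
        f = _scores_array(trial, s)
        components.append(_aipw_influence(trial, f, f, propensity))
    phi = np.vstack(components)
    big_n = trial.n_total
    cov = np.cov(phi, ddof=1) / big_n
    cov = np.atleast_2d(cov) + weight_ridge * np.eye(phi.shape[0])
    w = _simplex_min_variance(cov)
    est = float(w @ phi.mean(axis=1))
    var = float(w @ cov @ w)
    lo, hi = normal_ci(est, var, level)
    return AteEstimate("haipw", est, var, lo, hi, lam=None,
                       n=trial.n_control, m=trial.m_treated, level=level,
                       extras={"weights": w})


def permutation_test(
    trial: TrialDataset,
    statistic,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided label-permutation test of a treatment-effect statistic.

    ``statistic`` maps a TrialDataset to a scalar (or an AteEstimate, whose
    point estimate is used). Arm labels are permuted preserving arm sizes;
    p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1). The standardized
    null moments diagnose how close the permutation distribution is to the
    normal distribution assumed by the reported CIs.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful p-value")

    def evaluate(t: TrialDataset) -> float:
        out = statistic(t)
        return float(out.estimate) if isinstance(out, AteEstimate) else float(out)

    rng = np.random.default_rng(seed)
    observed = evaluate(trial)
    null = np.empty(n_perm)
    base_arm = trial.arm
    for b in range(n_perm):
        perm = rng.permutation(base_arm)
        try:
            null[b] = evaluate(trial.with_arm_labels(perm))
        except Exception as exc:  # noqa: BLE001 - re-raise with permutation context
            raise RuntimeError(
                f"statistic failed on permutation {b} (seed {seed})"
            ) from exc
    count = int(np.sum(np.abs(null) >= abs(observed)))
    p = (1.0 + count) / (n_perm + 1.0)
    return PermutationResult(
        p_value=float(p),
        observed=observed,
        n_perm=n_perm,
        null_mean=float(np.mean(null)),
        null_sd=float(np.std(null, ddof=1)),
        null_skewness=float(stats.skew(null)),
        null_excess_kurtosis=float(stats.kurtosis(null)),
        null_stats=null,
    )
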