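"""Disease-progression models and prognostic-score prediction.

A prognostic model is calibrated on a natural-history cohort and, for each
trial patient, predicts the untreated 1-year progression of the primary score
from pre-treatment data only. Three families are provided:

``linear``
    OLS of annualized progression (from the visit pair closest to a one-year
    gap) on the baseline score.
``linear_mixed``
    Random intercept + random slope of score on time (REML via statsmodels
    MixedLM); a new patient's prediction is their BLUP-conditional slope,
    computed from pre-inclusion visits, applied over the horizon.
``dcm_univariate`` / ``dcm_multivariate``
    A disease-course model: scores normalized by their ceilings follow a
    population logistic curve evaluated at the reparametrized disease age
    psi_i(t) = t_ref + exp(xi_i) (t - t_ref - tau_i), with Gaussian random
    effects tau_i (time shift, years) and xi_i (log-acceleration). The
    multivariate variant shares (tau_i, xi_i) across features with per-feature
    population curves, so a secondary score sharpens the estimate of the
    latent disease age. Calibration is deterministic alternating MAP
    optimization: population fixed effects by quasi-Newton with individual
    parameters held at their MAP values, hyper-parameters (noise and
    random-effect SDs) by closed-form updates, iterated until the penalized
    objective stalls.

Personalization (MAP estimation of an individual's tau, xi from their own
visits with the fitted Gaussian priors) and raw-scale progression prediction
close the loop from cohort to prognostic score.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logit

from .datasets import LongitudinalCohort, PrognosticScoreSet, TrialDataset
from .visit_selection import one_year_pair

logger = logging.getLogger(__name__)

FAMILIES = ("linear", "linear_mixed", "dcm_univariate", "dcm_multivariate")

# Outer loop: stop when the penalized objective improves by < OUTER_TOL
# (relative) or after MAX_OUTER sweeps; per-patient optimizer tolerance below.
MAX_OUTER = 200
OUTER_TOL = 1e-6
INNER_TOL = 1e-8

# Floors keep the closed-form hyper updates away from degenerate zeros.
_NOISE_FLOOR = 1e-3      # normalized-score units
_SHIFT_SD_FLOOR = 1e-2   # years
_ACCEL_SD_FLOOR = 1e-3


class ConvergenceError(RuntimeError):
    """Raised when a fitting routine fails to make progress."""


@dataclass
class IndividualParams:
    """MAP individual parameters of the disease-course model."""

    time_shift: float = 0.0   # tau_i, years
    log_accel: float = 0.0    # xi_i, unitless
    #: per-feature intercept offsets (multivariate models); the default fitter
    #: keeps these at zero and lets (tau, xi) carry the individual variation.
    feature_offsets: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time_shift) and math.isfinite(self.log_accel)):
            raise ValueError("individual parameters must be finite")


@dataclass
class ProgressionModel:
    """A fitted disease-progression model of any family.

    ``population_params`` is family-specific; for DCM families it holds per-
    feature curve anchors ``p0`` (normalized value at ``t_ref``, strictly in
    (0,1)), per-feature speeds ``v0`` (> 0, normalized units/year at the
    anchor) and the shared reference time ``t_ref``. ``noise_sd`` is the
    per-feature residual SD on the raw score scale.
    """

    family: str
    population_params: dict
    random_effect_sds: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    feature_names: list = field(default_factory=lambda: ["SARA"])
    score_maxima: dict = field(default_factory=dict)
    training_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family: {self.family!r}")
        if self.family.startswith("dcm"):
            for feat in self.feature_names:
                p0 = self.population_params["p0"][feat]
                v0 = self.population_params["v0"][feat]
                if not 0.0 < p0 < 1.0:
                    raise ValueError("p0 must lie strictly inside (0, 1)")
                if v0 <= 0:
                    raise ValueError("v0 must be positive")

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "format_version": 1,
            "family": self.family,
            "population_params": self.population_params,
            "random_effect_sds": self.random_effect_sds,
            "noise_sd": self.noise_sd,
            "feature_names": list(self.feature_names),
            "score_maxima": self.score_maxima,
            "training_ids": sorted(str(i) for i in self.training_ids),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ProgressionModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("format_version") != 1:
            raise ValueError("unsupported model document version")
        return cls(
            family=doc["family"],
            population_params=doc["population_params"],
            random_effect_sds=doc["random_effect_sds"],
            noise_sd=doc["noise_sd"],
            feature_names=doc["feature_names"],
            score_maxima=doc["score_maxima"],
            training_ids=frozenset(doc["training_ids"]),
        )


# ---------------------------------------------------------------------------
# DCM curve primitives
# ---------------------------------------------------------------------------

def _curve_normalized(t, p0: float, v0: float, t_ref: float,
                      tau: float = 0.0, xi: float = 0.0):
    """Logistic curve through (t_ref, p0) with slope v0 there, evaluated at the
    reparametrized age of an individual with effects (tau, xi)."""
    psi = t_ref + math.exp(xi) * (np.asarray(t, dtype=float) - t_ref - tau)
    b = v0 / (p0 * (1.0 - p0))
    return expit(b * (psi - t_ref) + logit(p0))


def _dcm_curve_raw(model: ProgressionModel, feature: str, t,
                   indiv: IndividualParams):
    pp = model.population_params
    smax = model.score_maxima[feature]
    return smax * _curve_normalized(
        t, pp["p0"][feature], pp["v0"][feature], pp["t_ref"],
        indiv.time_shift, indiv.log_accel,
    )


# ---------------------------------------------------------------------------
# Training-pair extraction (shared with the evaluation module's fold builder)
# ---------------------------------------------------------------------------

def _progression_pairs(cohort: LongitudinalCohort, score_name: str = "SARA"):
    """Per-patient (baseline value, annualized progression) from the visit
    pair closest to a one-year gap; single-visit patients are excluded."""
    baselines, progressions, ids = [], [], []
    for pid, grp in cohort.visits[cohort.visits["score_name"] == score_name].groupby(
        "patient_id", sort=False
    ):
        times = grp["time_years"].to_numpy()
        values = grp["value"].to_numpy()
        pair = one_year_pair(times)
        if pair is None:
            continue
        i, j = pair
        gap = times[j] - times[i]
        baselines.append(values[i])
        progressions.append((values[j] - values[i]) / gap)
        ids.append(pid)
    return np.asarray(baselines), np.asarray(progressions), ids


# ---------------------------------------------------------------------------
# Linear families
# ---------------------------------------------------------------------------

def fit_linear(cohort: LongitudinalCohort, score_name: str = "SARA") -> ProgressionModel:
    """OLS of annualized 1-year progression on baseline score."""
    x, y, ids = _progression_pairs(cohort, score_name)
    if len(x) < 2:
        raise ValueError("need at least 2 patients with a usable visit pair")
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient design: baseline score is constant")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - 2, 1)
    return ProgressionModel(
        family="linear",
        population_params={"intercept": float(coef[0]), "slope": float(coef[1])},
        noise_sd={score_name: float(np.sqrt(resid @ resid / dof))},
        feature_names=[score_name],
        score_maxima=dict(cohort.score_maxima),
        training_ids=frozenset(ids),
    )


def fit_linear_mixed(cohort: LongitudinalCohort, score_name: str = "SARA") -> ProgressionModel:
    """Random intercept + random slope mixed model of score on time (REML)."""
    sub = cohort.visits[cohort.visits["score_name"] == score_name]
    counts = sub.groupby("patient_id")["time_years"].count()
    keep = counts[counts >= 2].index
    sub = sub[sub["patient_id"].isin(keep)]
    if sub["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients with >= 2 visits")
    t_center = float(sub["time_years"].mean())
    tc = sub["time_years"].to_numpy() - t_center
    X = np.column_stack([np.ones(len(sub)), tc])
    md = sm.MixedLM(sub["value"].to_numpy(), X, groups=sub["patient_id"].to_numpy(),
                    exog_re=X)
    import warnings as _warnings

    res = None
    tried = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # boundary variance warnings are expected
        for method in ("bfgs", "lbfgs", "powell"):
            try:
                candidate = md.fit(reml=True, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as exc:
                tried.append(f"{method}: {exc}")
                continue
            if candidate.converged:
                res = candidate
                break
            tried.append(f"{method}: not converged (loglike={candidate.llf:.4g})")
    if res is None:
        raise ConvergenceError(
            "mixed model did not converge; attempts: " + "; ".join(tried)
        )
    cov_re = np.asarray(res.cov_re)
    return ProgressionModel(
        family="linear_mixed",
        population_params={
            "intercept": float(res.fe_params[0]),
            "slope": float(res.fe_params[1]),
            "t_center": t_center,
            "cov_re": cov_re.tolist(),
            "resid_var": float(res.scale),
        },
        random_effect_sds={
            "intercept": float(np.sqrt(max(cov_re[0, 0], 0.0))),
            "slope": float(np.sqrt(max(cov_re[1, 1], 0.0))),
        },
        noise_sd={score_name: float(np.sqrt(res.scale))},
        feature_names=[score_name],
        score_maxima=dict(cohort.score_maxima),
        training_ids=frozenset(keep),
    )


def _blup_slope(model: ProgressionModel, times: np.ndarray, values: np.ndarray) -> float:
    """Conditional (BLUP) individual slope given a patient's visits; falls
    back to the population slope when fewer than 2 distinct times exist."""
    pp = model.population_params
    if len(np.unique(np.round(times, 9))) < 2:
        return float(pp["slope"])
    tc = times - pp["t_center"]
    Z = np.column_stack([np.ones(len(tc)), tc])
    D = np.asarray(pp["cov_re"])
    V = Z @ D @ Z.T + pp["resid_var"] * np.eye(len(tc))
    resid = values - (pp["intercept"] + pp["slope"] * tc)
    b = D @ Z.T @ np.linalg.solve(V, resid)
    return float(pp["slope"] + b[1])


# ---------------------------------------------------------------------------
# DCM fitting
# ---------------------------------------------------------------------------

def _patient_arrays(cohort: LongitudinalCohort, features) -> dict:
    """patient_id -> {feature: (times, normalized values)} with >= 2 total
    visits of the first feature required (single-visit patients excluded)."""
    data = {}
    for feat in features:
        if feat not in cohort.score_maxima:
            raise ValueError(f"no score ceiling configured for feature {feat!r}")
        sub = cohort.visits[cohort.visits["score_name"] == feat]
        smax = cohort.score_maxima[feat]
        for pid, grp in sub.groupby("patient_id", sort=False):
            entry = data.setdefault(pid, {})
            entry[feat] = (
                grp["time_years"].to_numpy(dtype=float),
                grp["value"].to_numpy(dtype=float) / smax,
            )
    primary = features[0]
    return {
        pid: obs for pid, obs in data.items()
        if primary in obs and len(obs[primary][0]) >= 2
    }


def _indiv_objective_grad(x, obs, pop, sig2, shift_sd, accel_sd):
    """Penalized negative log posterior of one patient's (tau, xi), with
    analytic gradient. ``pop`` maps feature -> (b, alpha, t_ref)."""
    tau, xi = x
    e = math.exp(xi)
    val = 0.5 * (tau / shift_sd) ** 2 + 0.5 * (xi / accel_sd) ** 2
    g_tau = tau / shift_sd**2
    g_xi = xi / accel_sd**2
    for feat, (t, y) in obs.items():
        b, alpha, t_ref = pop[feat]
        centered = t - t_ref - tau
        u = b * (e * centered) + alpha
        pred = expit(u)
        r = y - pred
        w = pred * (1.0 - pred) / sig2[feat]
        val += 0.5 * float(r @ r) / sig2[feat]
        g_tau += float((r * w).sum()) * b * e
        g_xi += -float((r * w * centered).sum()) * b * e
    return val, np.array([g_tau, g_xi])


def _fit_individual(obs, pop, sig2, shift_sd, accel_sd, x0=None,
                    extra_starts=()):
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    if not starts:
        starts.append(np.zeros(2))
    best = None
    for s in starts:
        res = optimize.minimize(
            _indiv_objective_grad, s, args=(obs, pop, sig2, shift_sd, accel_sd),
            jac=True, method="L-BFGS-B", tol=INNER_TOL,
            # generous physical bounds keep the optimizer out of overflow
            # territory when a patient's visits are totally uninformative
            bounds=[(-80.0, 80.0), (-3.0, 3.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, float(best.fun)


def _indiv_posterior_cov(x, obs, pop, sig2, shift_sd, accel_sd) -> np.ndarray:
    """Laplace (Gauss-Newton) posterior covariance of (tau, xi) at the MAP.

    Used by the EM-style hyper updates: plain means of squared MAP estimates
    collapse the random-effect SDs when visits are sparse (the MAP shrinks
    towards the prior), so the updates add back the posterior variance.
    """
    tau, xi = x
    e = math.exp(xi)
    H = np.diag([1.0 / shift_sd**2, 1.0 / accel_sd**2])
    for feat, (t, y) in obs.items():
        b, alpha, t_ref = pop[feat]
        centered = t - t_ref - tau
        pred = expit(b * e * centered + alpha)
        w = pred * (1.0 - pred) * b * e
        g_tau = -w
        g_xi = w * centered
        H[0, 0] += float((g_tau * g_tau).sum()) / sig2[feat]
        H[0, 1] += float((g_tau * g_xi).sum()) / sig2[feat]
        H[1, 1] += float((g_xi * g_xi).sum()) / sig2[feat]
    H[1, 0] = H[0, 1]
    return np.linalg.inv(H)


def _tau_init(obs, pop, feature):
    """Invert the population curve at the first visit (xi = 0 start)."""
    t, y = obs[feature]
    b, alpha, t_ref = pop[feature]
    y0 = float(np.clip(y[0], 1e-3, 1.0 - 1e-3))
    return t[0] - t_ref - (logit(y0) - alpha) / b


def _pop_from_params(p0, v0, t_ref):
    return (v0 / (p0 * (1.0 - p0)), float(logit(p0)), t_ref)


def fit_dcm(
    cohort: LongitudinalCohort,
    features=("SARA",),
    max_outer: int = MAX_OUTER,
    tol: float = OUTER_TOL,
) -> ProgressionModel:
    """Calibrate the disease-course model by alternating MAP optimization.

    Sweeps alternate (1) per-patient MAP of (tau_i, xi_i), (2) per-feature
    quasi-Newton updates of the curve parameters (p0, v0) with the reference
    time anchored at the mean observation time — the anchor removes the
    sliding redundancy between p0 and t_ref along the logistic curve — and
    (3) closed-form updates of the noise and random-effect SDs. Raises
    :class:`ConvergenceError` if the penalized objective never decreases.
    """
    features = list(features)
    data = _patient_arrays(cohort, features)
    if len(data) < 2:
        raise ValueError("need at least 2 patients with >= 2 visits")
    pids = list(data)
    primary = features[0]

    all_times = np.concatenate([obs[f][0] for obs in data.values() for f in obs])
    t_ref = float(all_times.mean())

    # init: anchor value = mean normalized score; speed from a global OLS slope
    p0 = {}
    v0 = {}
    sig2 = {}
    for feat in features:
        ts = np.concatenate([obs[feat][0] for obs in data.values() if feat in obs])
        ys = np.concatenate([obs[feat][1] for obs in data.values() if feat in obs])
        p0[feat] = float(np.clip(ys.mean(), 0.05, 0.95))
        slope = float(np.polyfit(ts, ys, 1)[0])
        v0[feat] = max(slope, 1e-3)
        sig2[feat] = max(float(np.var(ys)), _NOISE_FLOOR**2)
    shift_sd, accel_sd = 5.0, 0.3
    indiv = {pid: np.zeros(2) for pid in pids}

    def pop_dict():
        return {f: _pop_from_params(p0[f], v0[f], t_ref) for f in features}

    def objective() -> float:
        pop = pop_dict()
        total = 0.0
        for pid in pids:
            tau, xi = indiv[pid]
            for feat, (t, y) in data[pid].items():
                b, alpha, _ = pop[feat]
                u = b * math.exp(xi) * (t - t_ref - tau) + alpha
                r = y - expit(u)
                total += (0.5 * float(r @ r) / sig2[feat]
                          + len(t) * 0.5 * math.log(sig2[feat]))
            total += (0.5 * (tau / shift_sd) ** 2 + math.log(shift_sd)
                      + 0.5 * (xi / accel_sd) ** 2 + math.log(accel_sd))
        return total

    def feature_sse(feat, x):
        """SSE of one feature's curve in (logit p0, log v0) coordinates."""
        pf, vf = float(expit(x[0])), float(math.exp(x[1]))
        b, alpha, _ = _pop_from_params(pf, vf, t_ref)
        sse = 0.0
        for pid in pids:
            if feat not in data[pid]:
                continue
            tau, xi = indiv[pid]
            t, y = data[pid][feat]
            u = b * math.exp(xi) * (t - t_ref - tau) + alpha
            r = y - expit(u)
            sse += float(r @ r)
        return sse

    j_prev = objective()
    j_init = j_prev
    history = [j_prev]
    for outer in range(max_outer):
        # (1) population curve step, per feature (run before the individual
        # step so the first sweep fits the marginal average curve with all
        # individual effects at zero — otherwise the per-patient parameters
        # absorb the initial curve misfit and trap the fit in a local
        # optimum)
        for feat in features:
            x0 = np.array([logit(p0[feat]), math.log(v0[feat])])
            res = optimize.minimize(lambda x, f=feat: feature_sse(f, x), x0,
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-10})
            p0[feat] = float(expit(res.x[0]))
            v0[feat] = float(math.exp(res.x[1]))

        # (2) individual MAP step
        pop = pop_dict()
        for pid in pids:
            starts = [indiv[pid]]
            if outer == 0:
                starts.append(np.array([_tau_init(data[pid], pop, primary), 0.0]))
            x, _ = _fit_individual(data[pid], pop, sig2, shift_sd, accel_sd,
                                   x0=starts[0], extra_starts=starts[1:])
            indiv[pid] = x

        # (3) closed-form hyper updates
        for feat in features:
            n_obs = sum(len(data[pid][feat][0]) for pid in pids if feat in data[pid])
            sig2[feat] = max(feature_sse(feat, np.array(
                [logit(p0[feat]), math.log(v0[feat])])) / n_obs, _NOISE_FLOOR**2)
        pop = pop_dict()
        second_moments = np.zeros(2)
        for pid in pids:
            cov_post = _indiv_posterior_cov(indiv[pid], data[pid], pop, sig2,
                                            shift_sd, accel_sd)
            second_moments += indiv[pid] ** 2 + np.diag(cov_post)
        second_moments /= len(pids)
        shift_sd = max(float(np.sqrt(second_moments[0])), _SHIFT_SD_FLOOR)
        accel_sd = max(float(np.sqrt(second_moments[1])), _ACCEL_SD_FLOOR)

        j_new = objective()
        history.append(j_new)
        if abs(j_prev - j_new) < tol * max(1.0, abs(j_prev)):
            j_prev = j_new
            break
        j_prev = j_new
    else:
        logger.info("dcm fit reached max_outer=%d sweeps (last improvement %.3g)",
                    max_outer, history[-2] - history[-1])

    if j_prev >= j_init - 1e-12 and len(history) - 1 >= max_outer:
        raise ConvergenceError(
            f"objective failed to decrease over {len(history) - 1} sweeps "
            f"(start {j_init:.6g}, end {j_prev:.6g})"
        )

    family = "dcm_univariate" if len(features) == 1 else "dcm_multivariate"
    return ProgressionModel(
        family=family,
        population_params={
            "p0": {f: p0[f] for f in features},
            "v0": {f: v0[f] for f in features},
            "t_ref": t_ref,
        },
        random_effect_sds={"time_shift": shift_sd, "log_accel": accel_sd},
        noise_sd={f: float(np.sqrt(sig2[f])) * cohort.score_maxima[f]
                  for f in features},
        feature_names=features,
        score_maxima=dict(cohort.score_maxima),
        training_ids=frozenset(pids),
    )


# ---------------------------------------------------------------------------
# Personalization and prediction
# ---------------------------------------------------------------------------

def _visits_to_obs(model: ProgressionModel, visits: pd.DataFrame) -> dict:
    obs = {}
    for feat in model.feature_names:
        sub = visits[visits["score_name"] == feat]
        if len(sub):
            obs[feat] = (
                sub["time_years"].to_numpy(dtype=float),
                sub["value"].to_numpy(dtype=float) / model.score_maxima[feat],
            )
    return obs


def personalize(model: ProgressionModel, visits: pd.DataFrame) -> IndividualParams:
    """MAP estimate of (tau, xi) from one patient's visits.

    Gaussian likelihood under the individual curve plus centered Gaussian
    priors with the fitted random-effect SDs. With a single distinct
    timepoint the log-acceleration is not identifiable and is pinned at its
    prior mean; only the time shift is estimated.
    """
    if not model.family.startswith("dcm"):
        raise ValueError("personalize applies to disease-course models only")
    obs = _visits_to_obs(model, visits)
    if not obs:
        raise ValueError("need at least one visit of a modelled feature")
    distinct_times = len({round(float(t), 9)
                          for ts, _ in obs.values() for t in ts})
    pp = model.population_params
    pop = {f: _pop_from_params(pp["p0"][f], pp["v0"][f], pp["t_ref"])
           for f in model.feature_names if f in obs}
    sig2 = {f: max(model.noise_sd[f] / model.score_maxima[f], _NOISE_FLOOR) ** 2
            for f in obs}
    shift_sd = max(model.random_effect_sds["time_shift"], _SHIFT_SD_FLOOR)
    accel_sd = max(model.random_effect_sds["log_accel"], _ACCEL_SD_FLOOR)
    anchor = next(f for f in model.feature_names if f in obs)
    if distinct_times < 2:
        # 1-D MAP over tau with xi fixed at the prior mean
        def obj(tau):
            val, _ = _indiv_objective_grad(np.array([float(tau[0]), 0.0]),
                                           obs, pop, sig2, shift_sd, accel_sd)
            return val

        best = None
        for start in (0.0, _tau_init(obs, pop, anchor)):
            res = optimize.minimize(obj, [start], method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        return IndividualParams(time_shift=float(best.x[0]), log_accel=0.0)
    starts = [np.zeros(2), np.array([_tau_init(obs, pop, anchor), 0.0])]
    x, _ = _fit_individual(obs, pop, sig2, shift_sd, accel_sd,
                           x0=starts[0], extra_starts=starts[1:])
    return IndividualParams(time_shift=float(x[0]), log_accel=float(x[1]))


def predict_progression(
    model: ProgressionModel,
    indiv: IndividualParams,
    t_baseline: float,
    horizon: float = 1.0,
    feature: str | None = None,
) -> float:
    """Predicted raw-scale change of ``feature`` over ``horizon`` years from
    ``t_baseline`` for an individual's personalized curve (0 at horizon 0;
    near 0 in the saturated tails of the curve)."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if not model.family.startswith("dcm"):
        raise ValueError("predict_progression applies to disease-course models")
    feature = feature or model.feature_names[0]
    start = float(_dcm_curve_raw(model, feature, t_baseline, indiv))
    end = float(_dcm_curve_raw(model, feature, t_baseline + horizon, indiv))
    return end - start


def predict_from_visits(
    model: ProgressionModel,
    visits: pd.DataFrame | None,
    t_baseline: float,
    baseline_value: float,
    horizon: float = 1.0,
) -> float:
    """Family-dispatching prognostic prediction of the primary-score change
    over ``horizon`` years; ``visits`` holds the personalization data
    (ignored by the linear family, which uses only the baseline value)."""
    if model.family == "linear":
        pp = model.population_params
        return float((pp["intercept"] + pp["slope"] * baseline_value) * horizon)
    if model.family == "linear_mixed":
        primary = model.feature_names[0]
        if visits is None or not len(visits):
            return float(model.population_params["slope"] * horizon)
        sub = visits[visits["score_name"] == primary]
        slope = _blup_slope(model, sub["time_years"].to_numpy(dtype=float),
                            sub["value"].to_numpy(dtype=float))
        return float(slope * horizon)
    indiv = personalize(model, visits)
    return predict_progression(model, indiv, t_baseline, horizon)


def score_trial(
    model: ProgressionModel,
    trial: TrialDataset,
    use_pre_inclusion: bool = True,
    horizon: float = 1.0,
) -> PrognosticScoreSet:
    """Prognostic scores f(X_i) for every trial patient.

    Personalization uses the baseline visit only, or baseline plus
    pre-inclusion history, per ``use_pre_inclusion``; on-trial (post-baseline)
    visits are never used. Refuses trials that share patient ids with the
    model's training cohort (no training on the prediction set).
    """
    overlap = model.training_ids & set(trial.patient_ids)
    if overlap:
        raise ValueError(
            f"trial patients were in the training cohort: {sorted(overlap)[:5]}"
        )
    needs_visits = model.family != "linear"
    if needs_visits and (trial.visits is None or "baseline_age" not in trial.patients):
        raise ValueError(f"{model.family} scoring needs trial visits and baseline_age")

    scores = np.empty(trial.n_total)
    for i, row in trial.patients.iterrows():
        baseline_value = float(row.get("baseline_sara", np.nan))
        if model.family == "linear":
            scores[i] = predict_from_visits(model, None, 0.0, baseline_value, horizon)
            continue
        t_b = float(row["baseline_age"])
        sub = trial.visits[trial.visits["patient_id"] == row["patient_id"]]
        if use_pre_inclusion:
            sub = sub[sub["time_years"] <= t_b + 1e-9]
        else:
            sub = sub[np.isclose(sub["time_years"], t_b, atol=1e-9)]
        scores[i] = predict_from_visits(model, sub, t_b, baseline_value, horizon)
    tag = f"{model.family}" + ("" if use_pre_inclusion else "-baseline-only")
    return PrognosticScoreSet.from_trial(trial, scores, model_tag=tag)
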