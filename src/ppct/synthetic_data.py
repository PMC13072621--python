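"""Synthetic natural-history cohorts and trials with known ground truth.

The generators emulate a rare-ataxia setting: a sparse observational cohort of
SARA (0-40) and INAS (0-16) scores following bounded logistic trajectories,
and a small two-arm trial whose outcome is the 1-year SARA change. Every
patient follows the population logistic curve evaluated at a reparametrized
disease age

    psi_i(t) = t_mid + exp(xi_i) * (t - t_mid - tau_i)

with an individual time shift ``tau_i`` (years, how early/late the disease
runs) and log-acceleration ``xi_i`` (progression speed multiplier), the same
two random effects the disease-course model estimates. A direct Gaussian
sampler of (outcome, prognostic score) pairs with prescribed SDs and
correlations is also provided for studying the estimators under controlled
moments.

All generators take an explicit integer seed and are deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datasets import LongitudinalCohort, PrognosticScoreSet, TrialDataset


@dataclass
class TrajectoryParams:
    """Population trajectory and individual-variation parameters.

    The primary score follows ``score_max * expit(rate * (psi - midpoint_age))``
    so the curve crosses half its ceiling at ``midpoint_age`` and has raw-scale
    slope ``score_max * rate / 4`` there (1.8 SARA points/year with defaults;
    combined with the individual effects and the early-stage trial entry this
    puts typical annual progression near the 1-1.5 points reported for SCA
    natural history). The secondary score is a
    monotone transform of the same latent disease age with its own midpoint
    and rate, so it carries genuine extra signal about (tau, xi).
    """

    score_max: float = 40.0
    midpoint_age: float = 45.0
    rate: float = 0.18          # per-year logistic growth rate of the primary score
    shift_sd: float = 8.0       # SD of individual time shift tau_i (years)
    log_accel_sd: float = 0.8   # SD of individual log-acceleration xi_i
    noise_sd: float = 1.1       # visit-level Gaussian noise, primary score units
    inas_max: float = 16.0
    inas_rate: float = 0.12
    inas_age_offset: float = 3.0   # secondary score reaches midpoint later
    inas_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.score_max <= 0 or self.inas_max <= 0:
            raise ValueError("score ceilings must be positive")
        if self.rate <= 0 or self.inas_rate <= 0:
            raise ValueError("growth rates must be positive")
        for sd in (self.shift_sd, self.log_accel_sd, self.noise_sd, self.inas_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")

    def reparametrized_age(self, t, tau: float, xi: float):
        return self.midpoint_age + math.exp(xi) * (np.asarray(t, dtype=float)
                                                   - self.midpoint_age - tau)

    def curve(self, t, tau: float = 0.0, xi: float = 0.0):
        """Noise-free primary-score trajectory for one individual."""
        psi = self.reparametrized_age(t, tau, xi)
        return self.score_max * expit(self.rate * (psi - self.midpoint_age))

    def inas_curve(self, t, tau: float = 0.0, xi: float = 0.0):
        psi = self.reparametrized_age(t, tau, xi)
        return self.inas_max * expit(
            self.inas_rate * (psi - self.midpoint_age - self.inas_age_offset)
        )


@dataclass
class VisitSchedule:
    """Observation design of the natural-history cohort.

    Visit counts are drawn from ``visit_count_probs`` (defaults give 2-5
    visits, median 3); visit times are the entry visit plus uniform draws over
    a follow-up window of 1-4 years, matching the sparse 1-4 year median
    follow-up of pooled ataxia registries.
    """

    visit_count_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.3, 3: 0.3, 4: 0.2, 5: 0.2}
    )
    followup_years: tuple[float, float] = (1.0, 4.0)
    entry_age_mean: float = 45.0
    entry_age_sd: float = 8.0

    def __post_init__(self) -> None:
        probs = self.visit_count_probs
        if not probs or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("visit_count_probs must sum to 1")
        if min(probs) < 2:
            raise ValueError("every patient needs at least 2 visits")
        if self.followup_years[1] <= 0:
            raise ValueError("degenerate schedule: all visits at a single time")
        if self.entry_age_sd < 0:
            raise ValueError("entry_age_sd must be non-negative")


@dataclass
class TrialScenario:
    """Design of a simulated ATRIL-like randomized trial.

    ``true_ate`` is the treatment effect on the 1-year progression of the
    primary score (score units per year; negative = slowed worsening).
    ``placebo_effect`` is an arm-independent additive shift on post-baseline
    progression — exactly the kind of common shift the rectifier absorbs.
    The pre-inclusion visit count distribution defaults to the sparsity of a
    retrospective chart review (60% of patients with only 1-2 pre-inclusion
    timepoints).
    """

    n_placebo: int = 23
    n_treated: int = 22
    true_ate: float = 0.0
    placebo_effect: float = 0.0
    pre_inclusion_visit_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.25, 3: 0.2, 4: 0.2}
    )
    visit_months: tuple[float, ...] = (0.0, 6.0, 12.0)
    entry_age_mean: float = 41.0   # early-stage recruitment, below the curve midpoint
    entry_age_sd: float = 4.0
    pre_inclusion_window: tuple[float, float] = (0.25, 3.0)  # years before baseline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_placebo < 2 or self.n_treated < 2:
            raise ValueError("each arm needs at least 2 patients")
        months = tuple(self.visit_months)
        if list(months) != sorted(months) or months[0] != 0.0:
            raise ValueError("visit_months must be sorted and start at 0")
        probs = self.pre_inclusion_visit_probs
        if not probs or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("pre_inclusion_visit_probs must sum to 1")


@dataclass
class GaussianRegime:
    """Moment-controlled sampler regime for (outcome, score) pairs.

    Houses the simplified setting in which the PPCT variance identity
    Var(PPCT; lambda*) = (1 - R^2) Var(classic) is exact: equal SDs
    (sigma0 = sigma1 = sigma_f) and equal correlations (rho0 = rho1).
    """

    sigma0: float = 1.0
    sigma1: float = 1.0
    sigma_f: float = 1.0
    rho0: float = 0.0
    rho1: float = 0.0
    n: int = 23
    m: int = 22
    true_ate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma0, self.sigma1, self.sigma_f) <= 0:
            raise ValueError("standard deviations must be positive")
        if max(abs(self.rho0), abs(self.rho1)) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n < 2 or self.m < 2:
            raise ValueError("each arm needs at least 2 patients")

    @property
    def simplified(self) -> bool:
        return (self.sigma0 == self.sigma1 == self.sigma_f
                and self.rho0 == self.rho1)

    def arm_covariance(self, arm: int) -> np.ndarray:
        s = self.sigma1 if arm == 1 else self.sigma0
        r = self.rho1 if arm == 1 else self.rho0
        cov = np.array([[s**2, r * s * self.sigma_f],
                        [r * s * self.sigma_f, self.sigma_f**2]])
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("joint (outcome, score) covariance is not PSD")
        return cov


def _draw_counts(rng: np.random.Generator, probs: dict[int, float], size: int) -> np.ndarray:
    counts = np.array(sorted(probs), dtype=int)
    p = np.array([probs[k] for k in counts], dtype=float)
    return rng.choice(counts, size=size, p=p / p.sum())


def generate_cohort(
    params: TrajectoryParams,
    n_patients: int,
    schedule: VisitSchedule | None = None,
    seed: int = 0,
    include_inas: bool = True,
) -> LongitudinalCohort:
    """Simulate a natural-history cohort of ``n_patients`` untreated patients.

    Each patient gets individual effects (tau, xi), an entry age, and 2-5
    visits over their follow-up window; scores are the individual logistic
    trajectory plus visit-level Gaussian noise, clipped to the score bounds.
    Ground-truth individual parameters are retained for recovery tests.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    schedule = schedule or VisitSchedule()
    rng = np.random.default_rng(seed)

    taus = rng.normal(0.0, params.shift_sd, n_patients)
    xis = rng.normal(0.0, params.log_accel_sd, n_patients)
    entries = rng.normal(schedule.entry_age_mean, schedule.entry_age_sd, n_patients)
    counts = _draw_counts(rng, schedule.visit_count_probs, n_patients)

    rows = []
    truth = []
    for i in range(n_patients):
        pid = f"NH{i:04d}"
        k = int(counts[i])
        fup = rng.uniform(*schedule.followup_years)
        offsets = np.concatenate([[0.0], np.sort(rng.uniform(0.0, fup, k - 1))])
        times = entries[i] + offsets
        sara = params.curve(times, taus[i], xis[i])
        sara = np.clip(sara + rng.normal(0.0, params.noise_sd, k), 0.0, params.score_max)
        for t, v in zip(times, sara):
            rows.append((pid, float(t), "SARA", float(v)))
        if include_inas:
            inas = params.inas_curve(times, taus[i], xis[i])
            inas = np.clip(inas + rng.normal(0.0, params.inas_noise_sd, k),
                           0.0, params.inas_max)
            for t, v in zip(times, inas):
                rows.append((pid, float(t), "INAS", float(v)))
        truth.append((pid, float(taus[i]), float(xis[i]), float(entries[i])))

    visits = pd.DataFrame(rows, columns=["patient_id", "time_years", "score_name", "value"])
    ground_truth = pd.DataFrame(
        truth, columns=["patient_id", "time_shift", "log_accel", "entry_age"]
    )
    return LongitudinalCohort(
        visits=visits,
        score_maxima={"SARA": params.score_max, "INAS": params.inas_max},
        ground_truth=ground_truth,
    )


def generate_trial(scenario: TrialScenario, params: TrajectoryParams) -> TrialDataset:
    """Simulate a randomized trial with retrospective pre-inclusion visits.

    The outcome is the month-12 minus month-0 primary score. Post-baseline
    values receive the arm-independent placebo effect and, in the treated arm,
    the treatment effect, both pro-rated by time since baseline; all values
    are clipped to the score bounds after effects and noise.
    """
    rng = np.random.default_rng(scenario.seed)
    n_total = scenario.n_placebo + scenario.n_treated
    arm = np.array([0] * scenario.n_placebo + [1] * scenario.n_treated)
    rng.shuffle(arm)

    taus = rng.normal(0.0, params.shift_sd, n_total)
    xis = rng.normal(0.0, params.log_accel_sd, n_total)
    entries = rng.normal(scenario.entry_age_mean, scenario.entry_age_sd, n_total)
    pre_counts = _draw_counts(rng, scenario.pre_inclusion_visit_probs, n_total)
    months = np.asarray(scenario.visit_months, dtype=float)

    patient_rows = []
    visit_rows = []
    truth_rows = []
    for i in range(n_total):
        pid = f"TR{i:03d}"
        baseline = float(entries[i])
        pre_offsets = -np.sort(
            rng.uniform(*scenario.pre_inclusion_window, int(pre_counts[i]))
        )[::-1]
        times = np.concatenate([baseline + pre_offsets, baseline + months / 12.0])
        dt = np.maximum(times - baseline, 0.0)  # years on trial
        drift = (scenario.placebo_effect + arm[i] * scenario.true_ate) * dt

        sara = params.curve(times, taus[i], xis[i]) + drift
        sara = np.clip(sara + rng.normal(0.0, params.noise_sd, len(times)),
                       0.0, params.score_max)
        inas = params.inas_curve(times, taus[i], xis[i])
        inas = np.clip(inas + rng.normal(0.0, params.inas_noise_sd, len(times)),
                       0.0, params.inas_max)

        n_pre = len(pre_offsets)
        i_base = n_pre                      # index of the month-0 visit
        i_end = n_pre + len(months) - 1     # index of the month-12 visit
        outcome = float(sara[i_end] - sara[i_base])
        patient_rows.append({
            "patient_id": pid,
            "arm": int(arm[i]),
            "outcome": outcome,
            "baseline_sara": float(sara[i_base]),
            "baseline_inas": float(inas[i_base]),
            "baseline_age": baseline,
        })
        for t, v in zip(times, sara):
            visit_rows.append((pid, float(t), "SARA", float(v)))
        for t, v in zip(times, inas):
            visit_rows.append((pid, float(t), "INAS", float(v)))
        true_prog = float(params.curve(baseline + 1.0, taus[i], xis[i])
                          - params.curve(baseline, taus[i], xis[i]))
        truth_rows.append({
            "patient_id": pid,
            "time_shift": float(taus[i]),
            "log_accel": float(xis[i]),
            "entry_age": baseline,
            "true_untreated_progression": true_prog,
        })

    return TrialDataset(
        patients=pd.DataFrame(patient_rows),
        visits=pd.DataFrame(
            visit_rows, columns=["patient_id", "time_years", "score_name", "value"]
        ),
        ground_truth=pd.DataFrame(truth_rows),
    )


def generate_gaussian_regime(
    regime: GaussianRegime, seed: int = 0
) -> tuple[TrialDataset, PrognosticScoreSet]:
    """Sample (outcome, prognostic score) pairs with prescribed moments.

    Control-arm pairs are bivariate normal with SDs (sigma0, sigma_f) and
    correlation rho0; treated-arm pairs likewise with (sigma1, sigma_f, rho1)
    and outcome mean shifted by ``true_ate``. The score doubles as the
    baseline covariate column so covariate-based estimators apply directly.
    """
    rng = np.random.default_rng(seed)
    y = np.empty(regime.n + regime.m)
    f = np.empty_like(y)
    arm = np.concatenate([np.zeros(regime.n, dtype=int),
                          np.ones(regime.m, dtype=int)])
    for a, mean in ((0, 0.0), (1, regime.true_ate)):
        cov = regime.arm_covariance(a)
        size = regime.n if a == 0 else regime.m
        draws = rng.multivariate_normal([mean, 0.0], cov, size=size)
        y[arm == a] = draws[:, 0]
        f[arm == a] = draws[:, 1]

    patients = pd.DataFrame({
        "patient_id": [f"G{i:05d}" for i in range(len(y))],
        "arm": arm,
        "outcome": y,
        "baseline_sara": f,
    })
    trial = TrialDataset(patients=patients)
    scores = PrognosticScoreSet.from_trial(trial, f, model_tag="gaussian-regime")
    return trial, scores
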