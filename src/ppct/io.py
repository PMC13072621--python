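"""Readers, writers and the reproducible end-to-end pipeline.

CSV schemas (UTF-8, comma-separated, header required, '.' decimal, times in
years as floats):

* longitudinal visits — ``patient_id,time_years,score_name,value``
* trial patients — ``patient_id,arm,outcome,baseline_sara[,baseline_inas,baseline_age]``
* prognostic scores — ``patient_id,score,model_tag``

Scenario files are YAML with optional ``scenario``, ``trajectory`` and
``schedule`` sections whose keys mirror the corresponding dataclasses.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (DEFAULT_SCORE_MAXIMA, LongitudinalCohort,
                       PrognosticScoreSet, TrialDataset)
from .synthetic_data import TrajectoryParams, TrialScenario, VisitSchedule

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Longitudinal CSV
# ---------------------------------------------------------------------------

def read_longitudinal_csv(path, score_maxima: dict | None = None) -> LongitudinalCohort:
    """Read a long-format visit table, validating values row by row.

    Rejects missing columns, non-numeric times/values, duplicate
    (patient, time, score) rows and values outside the configured score
    bounds; error messages carry 1-based data row numbers.
    """
    score_maxima = dict(score_maxima or DEFAULT_SCORE_MAXIMA)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty input file") from exc
    if df.empty:
        raise ValueError(f"{path}: no visit rows")
    required = ["patient_id", "time_years", "score_name", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    for col in ("time_years", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()] + 1
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col!r} at data rows {list(bad[:5])}"
            )
        df[col] = coerced

    dup = df.duplicated(subset=["patient_id", "time_years", "score_name"])
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise ValueError(
            f"{path}: duplicate (patient, time, score) rows at {rows[:5]}"
        )

    for score, smax in score_maxima.items():
        sel = df["score_name"] == score
        bad = df.index[sel & ((df["value"] < 0) | (df["value"] > smax))] + 1
        if len(bad):
            raise ValueError(
                f"{path}: {score} values outside [0, {smax}] at data rows "
                f"{list(bad[:5])}"
            )
    return LongitudinalCohort(visits=df, score_maxima=score_maxima)


def write_longitudinal_csv(cohort: LongitudinalCohort, path) -> None:
    cohort.visits.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trial CSV
# ---------------------------------------------------------------------------

def read_trial_csv(patients_path, visits_path=None,
                   score_maxima: dict | None = None) -> TrialDataset:
    patients = pd.read_csv(patients_path)
    visits = None
    if visits_path is not None:
        visits = read_longitudinal_csv(visits_path, score_maxima).visits
    return TrialDataset(patients=patients, visits=visits)


def write_trial_csv(trial: TrialDataset, patients_path, visits_path=None) -> None:
    trial.patients.to_csv(patients_path, index=False)
    if visits_path is not None and trial.visits is not None:
        trial.visits.to_csv(visits_path, index=False)


def read_scores_csv(path) -> PrognosticScoreSet:
    df = pd.read_csv(path)
    for col in ("patient_id", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    tag = str(df["model_tag"].iloc[0]) if "model_tag" in df.columns else ""
    return PrognosticScoreSet(patient_ids=df["patient_id"].to_numpy(),
                              scores=df["score"].to_numpy(dtype=float),
                              model_tag=tag)


def write_scores_csv(scores: PrognosticScoreSet, path) -> None:
    scores.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scenario YAML
# ---------------------------------------------------------------------------

def _build(cls, section: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in section.items():
        if isinstance(value, dict):
            value = {int(k) if isinstance(k, str) and k.isdigit() else k: v
                     for k, v in value.items()}
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def read_scenario_yaml(path):
    """Load (TrialScenario, TrajectoryParams, VisitSchedule) from YAML;
    absent sections fall back to defaults."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return (
        _build(TrialScenario, doc.get("scenario", {})),
        _build(TrajectoryParams, doc.get("trajectory", {})),
        _build(VisitSchedule, doc.get("schedule", {})),
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One reproducible simulate -> fit -> score -> estimate -> design run."""

    output_dir: str
    seed: int = 0
    n_cohort: int = 218
    scenario: TrialScenario = field(default_factory=TrialScenario)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    schedule: VisitSchedule = field(default_factory=VisitSchedule)
    model_families: tuple[str, ...] = ("linear", "dcm_univariate")
    lambda_mode: str = "optimal"
    k_folds: int = 5
    level: float = 0.95
    n_permutations: int = 0  # 0 disables permutation p-values
    design_n_classic: int | None = None  # defaults to the trial size


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _fit_family(family: str, cohort: LongitudinalCohort):
    from . import prognostic_models as pm

    if family == "linear":
        return pm.fit_linear(cohort)
    if family == "linear_mixed":
        return pm.fit_linear_mixed(cohort)
    if family == "dcm_univariate":
        return pm.fit_dcm(cohort, features=["SARA"])
    if family == "dcm_multivariate":
        return pm.fit_dcm(cohort, features=["SARA", "INAS"])
    raise ValueError(f"unknown model family: {family!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write its result bundle.

    Outputs under ``config.output_dir``: the simulated cohort and trial CSVs,
    one scores CSV per model family, a tidy estimates table over the six
    estimators, an R^2 table (pre-inclusion vs baseline-only personalization),
    the design curve CSV + plot, and a JSON manifest of every derived seed.
    Re-running with the same config reproduces every output byte for byte.
    """
    from . import estimators as est
    from . import evaluation_design as ev
    from . import prognostic_models as pm

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = np.random.SeedSequence(config.seed).generate_state(4) >> 1
    seeds = {
        "cohort": int(state[0]),
        "trial": int(state[1]),
        "crossfit": int(state[2]),
        "permutation": int(state[3]),
    }

    @_stage("simulate")
    def simulate():
        from .synthetic_data import generate_cohort, generate_trial

        cohort = generate_cohort(config.trajectory, config.n_cohort,
                                 config.schedule, seed=seeds["cohort"])
        scenario = dataclasses.replace(config.scenario, seed=seeds["trial"])
        trial = generate_trial(scenario, config.trajectory)
        logger.info("simulate: %d cohort patients / %d visits; trial N=%d "
                    "(m=%d, n=%d)", cohort.n_patients, cohort.n_visits,
                    trial.n_total, trial.m_treated, trial.n_control)
        write_longitudinal_csv(cohort, out / "cohort.csv")
        write_trial_csv(trial, out / "trial_patients.csv", out / "trial_visits.csv")
        return cohort, trial

    cohort, trial = simulate()

    @_stage("fit-score")
    def fit_and_score():
        all_scores = {}
        r2_rows = []
        for family in config.model_families:
            model = _fit_family(family, cohort)
            model.to_json(out / f"model_{family}.json")
            pre = pm.score_trial(model, trial, use_pre_inclusion=True)
            base = pm.score_trial(model, trial, use_pre_inclusion=False)
            all_scores[family] = pre
            write_scores_csv(pre, out / f"scores_{family}.csv")
            r2_rows.append({
                "model": family,
                "r2_pre_inclusion": ev.r_squared(pre.scores, trial.outcome).r_squared,
                "r2_baseline_only": ev.r_squared(base.scores, trial.outcome).r_squared,
                "sigma_f": pre.sigma_f,
                "rho0": pre.rho0,
                "rho1": pre.rho1,
            })
            logger.info("fit-score: %s scored %d patients", family, trial.n_total)
        r2_table = pd.DataFrame(r2_rows)
        r2_table.to_csv(out / "r2.csv", index=False)
        return all_scores, r2_table

    scores_by_family, r2_table = fit_and_score()

    @_stage("estimate")
    def estimate():
        rows = []

        def record(ate, model_tag):
            row = {
                "method": ate.method,
                "model": model_tag,
                "estimate": ate.estimate,
                "variance": ate.variance,
                "ci_low": ate.ci_low,
                "ci_high": ate.ci_high,
                "lambda": np.nan if ate.lam is None else ate.lam,
                "p_perm": np.nan,
            }
            rows.append(row)
            return row

        def maybe_permute(row, statistic):
            if config.n_permutations >= 100:
                res = est.permutation_test(trial, statistic,
                                           n_perm=config.n_permutations,
                                           seed=seeds["permutation"])
                row["p_perm"] = res.p_value

        maybe_permute(record(est.difference_in_means(trial, config.level), "-"),
                      lambda t: est.difference_in_means(t, config.level))
        aipw_kwargs = dict(level=config.level, k_folds=config.k_folds,
                           seed=seeds["crossfit"])
        maybe_permute(record(est.aipw_ate(trial, **aipw_kwargs), "-"),
                      lambda t: est.aipw_ate(t, **aipw_kwargs))
        for family, scores in scores_by_family.items():
            cfg = est.PpctConfig(lambda_mode=config.lambda_mode,
                                 k_folds=config.k_folds, seed=seeds["crossfit"])
            maybe_permute(record(est.ppi_ate(trial, scores, config.level), family),
                          lambda t, s=scores: est.ppi_ate(t, s, config.level))
            maybe_permute(record(est.ppct_ate(trial, scores, cfg, config.level),
                                 family),
                          lambda t, s=scores, c=cfg: est.ppct_ate(t, s, c,
                                                                  config.level))
            maybe_permute(record(est.ancova_ate(trial, scores, config.level),
                                 family),
                          lambda t, s=scores: est.ancova_ate(t, s, config.level))
            maybe_permute(record(est.haipw_ate(trial, [scores], **aipw_kwargs),
                                 family),
                          lambda t, s=scores: est.haipw_ate(t, [s], **aipw_kwargs))
        table = pd.DataFrame(rows)
        table.to_csv(out / "estimates.csv", index=False)
        logger.info("estimate: %d rows over %d prognostic models",
                    len(table), len(scores_by_family))
        return table

    estimates = estimate()

    @_stage("design")
    def design():
        n_classic = config.design_n_classic or trial.n_total
        curve = ev.design_curve(n_classic)
        curve.to_frame().to_csv(out / "design_curve.csv", index=False)
        curve.plot(out / "design_curve.png")
        best_r2 = float(r2_table["r2_pre_inclusion"].max())
        return ev.required_sample_size(n_classic, min(best_r2, 0.999))

    sample_size = design()

    manifest = {
        "package": {"name": "ppct", "version": __version__},
        "seed": config.seed,
        "derived_seeds": seeds,
        "config": {
            "n_cohort": config.n_cohort,
            "model_families": list(config.model_families),
            "lambda_mode": config.lambda_mode,
            "k_folds": config.k_folds,
            "level": config.level,
            "n_permutations": config.n_permutations,
            "scenario": dataclasses.asdict(config.scenario),
            "trajectory": dataclasses.asdict(config.trajectory),
            "schedule": dataclasses.asdict(config.schedule),
        },
        "trial": {"N": trial.n_total, "m": trial.m_treated, "n": trial.n_control},
        "sample_size": dataclasses.asdict(sample_size),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "output_dir": str(out),
        "estimates": estimates,
        "r2": r2_table,
        "sample_size": sample_size,
        "manifest": manifest,
    }
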