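"""Core data containers shared across the pipeline.

Three containers travel through every stage:

* :class:`LongitudinalCohort` — long-format natural-history visits used to
  calibrate prognostic models (one row per patient, time, clinical score).
* :class:`TrialDataset` — a two-arm randomized trial: arm labels, the 1-year
  change of the primary score as outcome, baseline covariates, and optional
  pre-inclusion visit history on the same time axis as the cohort.
* :class:`PrognosticScoreSet` — one model prediction of the untreated 1-year
  progression per trial patient, with the summary moments (sigma_f, rho0,
  rho1) that drive the variance-reduction formulas.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default clinical score ceilings: SARA spans 0-40, INAS counts up to 16 signs.
DEFAULT_SCORE_MAXIMA = {"SARA": 40.0, "INAS": 16.0}

VISIT_COLUMNS = ["patient_id", "time_years", "score_name", "value"]


@dataclass
class LongitudinalCohort:
    """Long-format longitudinal visits of an untreated natural-history cohort.

    Parameters
    ----------
    visits
        DataFrame with columns ``patient_id, time_years, score_name, value``.
        Times are years on a common axis (disease-age-like); rows are sorted
        within patient by time on construction.
    score_maxima
        Mapping score name -> ceiling, used for normalization and bounds.
    ground_truth
        Optional per-patient simulation truth (individual time shift,
        log-acceleration, entry age) retained by the synthetic generators for
        recovery tests. ``None`` for real data.
    """

    visits: pd.DataFrame
    score_maxima: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MAXIMA)
    )
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in VISIT_COLUMNS if c not in self.visits.columns]
        if missing:
            raise ValueError(f"cohort visits missing columns: {missing}")
        self.visits = (
            self.visits.sort_values(["patient_id", "score_name", "time_years"],
                                    kind="stable")
            .reset_index(drop=True)
        )

    @property
    def patient_ids(self) -> np.ndarray:
        return self.visits["patient_id"].unique()

    @property
    def n_patients(self) -> int:
        return int(self.visits["patient_id"].nunique())

    @property
    def n_visits(self) -> int:
        """Number of distinct (patient, time) visit occasions."""
        return int(len(self.visits[["patient_id", "time_years"]].drop_duplicates()))

    def patient_visits(self, patient_id, score_name: str | None = None) -> pd.DataFrame:
        sel = self.visits["patient_id"] == patient_id
        if score_name is not None:
            sel &= self.visits["score_name"] == score_name
        return self.visits.loc[sel]

    def visit_counts(self, score_name: str = "SARA") -> pd.Series:
        sub = self.visits[self.visits["score_name"] == score_name]
        return sub.groupby("patient_id")["time_years"].count()

    def subset(self, patient_ids) -> "LongitudinalCohort":
        ids = set(patient_ids)
        gt = None
        if self.ground_truth is not None:
            gt = self.ground_truth[
                self.ground_truth["patient_id"].isin(ids)
            ].reset_index(drop=True)
        return LongitudinalCohort(
            visits=self.visits[self.visits["patient_id"].isin(ids)].copy(),
            score_maxima=dict(self.score_maxima),
            ground_truth=gt,
        )


@dataclass
class TrialDataset:
    """A randomized two-arm trial.

    ``patients`` must carry ``patient_id``, ``arm`` (0 control / 1 treated) and
    ``outcome`` (1-year change of the primary score); baseline covariate
    columns (``baseline_sara``, ``baseline_inas``) and ``baseline_age`` (the
    inclusion-visit time on the cohort axis) are optional but required by the
    covariate-based estimators and by model personalization respectively.
    ``visits`` optionally holds pre-inclusion + on-trial visit history in the
    cohort's long format (absolute times).
    """

    patients: pd.DataFrame
    visits: pd.DataFrame | None = None
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = ["patient_id", "arm", "outcome"]
        missing = [c for c in required if c not in self.patients.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        arm = np.asarray(self.patients["arm"])
        if not np.isin(arm, [0, 1]).all():
            raise ValueError("arm labels must be binary 0/1")
        y = np.asarray(self.patients["outcome"], dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("outcomes must be finite")
        if (arm == 1).sum() < 2 or (arm == 0).sum() < 2:
            raise ValueError("each arm needs at least 2 patients")
        self.patients = self.patients.reset_index(drop=True)

    @property
    def arm(self) -> np.ndarray:
        return np.asarray(self.patients["arm"], dtype=int)

    @property
    def outcome(self) -> np.ndarray:
        return np.asarray(self.patients["outcome"], dtype=float)

    @property
    def patient_ids(self) -> np.ndarray:
        return np.asarray(self.patients["patient_id"])

    @property
    def n_total(self) -> int:
        return len(self.patients)

    @property
    def m_treated(self) -> int:
        return int((self.arm == 1).sum())

    @property
    def n_control(self) -> int:
        return int((self.arm == 0).sum())

    @property
    def treated_outcomes(self) -> np.ndarray:
        return self.outcome[self.arm == 1]

    @property
    def control_outcomes(self) -> np.ndarray:
        return self.outcome[self.arm == 0]

    def with_arm_labels(self, new_arm) -> "TrialDataset":
        """Copy with replaced arm labels (used by permutation tests)."""
        patients = self.patients.copy()
        patients["arm"] = np.asarray(new_arm, dtype=int)
        return TrialDataset(patients=patients, visits=self.visits,
                            ground_truth=self.ground_truth)


@dataclass
class PrognosticScoreSet:
    """Per-patient prognostic scores f(X) with their summary moments.

    sigma_f is the (pooled, n-1 denominator) SD of the scores; rho0 and rho1
    are Cov(f, Y | arm) / (sigma_f * sigma_arm) — note the pooled sigma_f in
    the denominator, so these are not within-arm Pearson correlations unless
    the score spread is arm-independent (which randomization guarantees
    asymptotically).
    """

    patient_ids: np.ndarray
    scores: np.ndarray
    model_tag: str = ""
    sigma_f: float = float("nan")
    rho0: float = float("nan")
    rho1: float = float("nan")

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.patient_ids) != len(self.scores):
            raise ValueError("patient_ids and scores must have equal length")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    @classmethod
    def from_trial(cls, trial: TrialDataset, scores, model_tag: str = "") -> "PrognosticScoreSet":
        """Attach scores (aligned with ``trial.patients`` order) and compute
        sigma_f, rho0, rho1 against the trial outcomes."""
        scores = np.asarray(scores, dtype=float)
        if len(scores) != trial.n_total:
            raise ValueError("need exactly one score per trial patient")
        t = trial.arm
        y = trial.outcome
        sigma_f = float(np.std(scores, ddof=1))
        out = cls(patient_ids=trial.patient_ids, scores=scores,
                  model_tag=model_tag, sigma_f=sigma_f)
        for label, mask in (("rho0", t == 0), ("rho1", t == 1)):
            s_arm = float(np.std(y[mask], ddof=1))
            if sigma_f > 0 and s_arm > 0:
                c = float(np.cov(scores[mask], y[mask], ddof=1)[0, 1])
                setattr(out, label, c / (sigma_f * s_arm))
        return out

    def aligned_with(self, trial: TrialDataset) -> np.ndarray:
        """Scores reordered to match ``trial.patients``; error on missing ids."""
        mapping = dict(zip(self.patient_ids.tolist(), self.scores.tolist()))
        missing = [p for p in trial.patient_ids if p not in mapping]
        if missing:
            raise ValueError(f"missing prognostic scores for patients: {missing[:5]}")
        return np.array([mapping[p] for p in trial.patient_ids], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "score": self.scores,
            "model_tag": self.model_tag,
        })


def asdict_shallow(obj) -> dict:
    """dataclasses.asdict without deep-copying DataFrames."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
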