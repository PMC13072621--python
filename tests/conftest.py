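"""Shared fixtures: small deterministic cohorts, trials and fitted models."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ppct import (GaussianRegime, TrajectoryParams, TrialDataset,
                  TrialScenario, generate_cohort, generate_gaussian_regime,
                  generate_trial)


@pytest.fixture(scope="session")
def traj_params() -> TrajectoryParams:
    return TrajectoryParams()


@pytest.fixture(scope="session")
def default_cohort(traj_params):
    """Default-condition natural-history cohort (218 patients)."""
    return generate_cohort(traj_params, 218, seed=11)


@pytest.fixture(scope="session")
def default_trial(traj_params):
    return generate_trial(TrialScenario(seed=21), traj_params)


@pytest.fixture(scope="session")
def quiet_params() -> TrajectoryParams:
    """Low-noise trajectory parameters for parameter-recovery checks."""
    return dataclasses.replace(TrajectoryParams(), noise_sd=0.3)


@pytest.fixture(scope="session")
def quiet_cohort(quiet_params):
    return generate_cohort(quiet_params, 200, seed=7)


@pytest.fixture(scope="session")
def fitted_dcm(default_cohort):
    """Univariate disease-course model fitted on the default cohort."""
    from ppct import fit_dcm

    return fit_dcm(default_cohort, features=["SARA"])


@pytest.fixture(scope="session")
def fitted_dcm_quiet(quiet_cohort):
    from ppct import fit_dcm

    return fit_dcm(quiet_cohort, features=["SARA"])


@pytest.fixture
def gaussian_trial():
    """Factory for moment-controlled (trial, scores) pairs."""

    def make(rho=0.5, n=100, m=100, true_ate=0.0, seed=0, **kwargs):
        regime = GaussianRegime(rho0=rho, rho1=rho, n=n, m=m,
                                true_ate=true_ate, **kwargs)
        return generate_gaussian_regime(regime, seed=seed)

    return make


def make_trial(y0, y1, f0=None, f1=None):
    """Tiny hand-built trial (and optional scores) for arithmetic checks."""
    y = np.concatenate([np.asarray(y0, float), np.asarray(y1, float)])
    arm = np.array([0] * len(y0) + [1] * len(y1))
    patients = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(y))],
        "arm": arm,
        "outcome": y,
        "baseline_sara": np.zeros(len(y)),
    })
    trial = TrialDataset(patients=patients)
    if f0 is None:
        return trial
    f = np.concatenate([np.asarray(f0, float), np.asarray(f1, float)])
    return trial, f
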