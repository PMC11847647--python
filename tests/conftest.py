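"""Shared fixtures: toy simulation configs, panels and hand-built fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from leaaf import (
    CohortPanel,
    HazardCoefficients,
    RiskModelFit,
    SimConfig,
    expand_person_years,
    fit_pooled_logistic,
    generate_cohort,
)

COV_COEFS = (0.05, -0.118, -0.209, -0.59, -0.044, 0.792, 0.565, 0.203, 0.172)


def toy_sim_config(**overrides) -> SimConfig:
    """Three-condition cardiovascular toy: hypertension -> stroke cascade."""
    base = dict(
        n_participants=1000,
        seed=3,
        condition_names=("hypertension", "diabetes", "stia"),
        baseline_condition_prevalence={"hypertension": 0.5, "diabetes": 0.2, "stia": 0.08},
        onset_hazard={"hypertension": 0.06, "diabetes": 0.02, "stia": 0.015},
        onset_synergy={("hypertension", "stia"): 1.6, ("diabetes", "stia"): 1.3},
        no_isolated_baseline=(),
        true_coefficients=HazardCoefficients(
            intercept=-4.6, time=0.0761,
            conditions=(0.30, 0.15, 0.65),
            covariates=COV_COEFS,
        ),
    )
    base.update(overrides)
    return SimConfig(**base)


def build_panel(config: SimConfig) -> CohortPanel:
    return expand_person_years(
        generate_cohort(config),
        thresholds=config.thresholds,
        condition_names=tuple(config.condition_names),
        covariate_names=tuple(config.covariate_names),
    )


def random_toy_panel(rng: np.random.Generator, d: int, n_rows: int = 30,
                     n_times: int = 2):
    """A tiny single-purpose panel + fit with random structure.

    Conditions c0..c{d-1}, two binary covariates, random coefficients;
    used to exercise the attribution engine away from the full cohort
    machinery.  Returns (fit, dataframe).
    """
    df = pd.DataFrame({
        "person_id": np.arange(n_rows),
        "t": rng.integers(0, n_times, n_rows),
    })
    for j in range(d):
        df[f"c{j}"] = rng.integers(0, 2, n_rows)
    for k in range(2):
        df[f"z{k}"] = rng.integers(0, 2, n_rows)
    df["outcome"] = 0
    fit = RiskModelFit(
        condition_names=tuple(f"c{j}" for j in range(d)),
        covariate_names=("z0", "z1"),
        beta0=rng.normal(-2.0, 0.5),
        beta_time=rng.normal(0.1, 0.05),
        beta_cond=rng.normal(0.4, 0.5, d),
        beta_cov=rng.normal(0.0, 0.4, 2),
    )
    return fit, df


@pytest.fixture(scope="session")
def toy_config() -> SimConfig:
    return toy_sim_config()


@pytest.fixture(scope="session")
def toy_panel(toy_config) -> CohortPanel:
    return build_panel(toy_config)


@pytest.fixture(scope="session")
def toy_fit(toy_panel) -> RiskModelFit:
    return fit_pooled_logistic(toy_panel)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    """Default eight-condition configuration at a modest size."""
    return SimConfig(n_participants=3000, seed=11)


@pytest.fixture(scope="session")
def default_panel(default_config) -> CohortPanel:
    return build_panel(default_config)


@pytest.fixture(scope="session")
def default_fit(default_panel) -> RiskModelFit:
    return fit_pooled_logistic(default_panel)
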