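"""Pooled (discrete-time) logistic regression of the incident outcome.

One observation per person-year; predictors are continuous time since
individual baseline, the d binary condition flags, and the binary
covariates.  The fitted annual-probability model feeds counterfactual
prediction in the attribution engine.  Estimation is deterministic
maximum likelihood (Newton iterations, via statsmodels).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel_builder import CohortPanel

__all__ = [
    "RiskModelFit",
    "NoEventsError",
    "SeparationError",
    "fit_pooled_logistic",
    "coef_to_or",
    "odds_ratio_table",
    "predict_prob",
]

WALD_Z = 1.96  # conventional multiplier behind printed 95% CIs


class NoEventsError(ValueError):
    """Panel contains no (or only) outcome events; the hazard model is undefined."""


class SeparationError(RuntimeError):
    """Perfect separation detected; estimates would diverge."""


@dataclass
class RiskModelFit:
    """Coefficients of the pooled logistic hazard model.

    Log-odds scale: ``beta0`` intercept, ``beta_time`` per year of
    follow-up, ``beta_cond`` per condition, ``beta_cov`` per covariate.
    Standard errors and diagnostics are present on estimated fits and may
    be ``None`` when the object carries known (generator) coefficients.
    """

    condition_names: tuple[str, ...]
    covariate_names: tuple[str, ...]
    beta0: float
    beta_time: float
    beta_cond: np.ndarray
    beta_cov: np.ndarray
    se: np.ndarray | None = None          # full vector, same order as params
    loglik: float | None = None
    converged: bool = True
    n_person_years: int | None = None
    n_events: int | None = None
    n_persons: int | None = None

    def __post_init__(self) -> None:
        self.beta_cond = np.asarray(self.beta_cond, dtype=float)
        self.beta_cov = np.asarray(self.beta_cov, dtype=float)
        if len(self.beta_cond) != len(self.condition_names):
            raise ValueError("beta_cond length mismatch")
        if len(self.beta_cov) != len(self.covariate_names):
            raise ValueError("beta_cov length mismatch")

    @property
    def param_names(self) -> list[str]:
        return ["intercept", "time", *self.condition_names, *self.covariate_names]

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.beta0, self.beta_time], self.beta_cond, self.beta_cov])

    def linear_predictor(self, t, x_cond, z_cov) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = np.atleast_2d(np.asarray(x_cond, dtype=float))
        z = np.atleast_2d(np.asarray(z_cov, dtype=float))
        if x.shape[-1] != len(self.beta_cond) or z.shape[-1] != len(self.beta_cov):
            raise ValueError(
                f"dimension mismatch: got {x.shape[-1]} conditions / "
                f"{z.shape[-1]} covariates, fit has {len(self.beta_cond)} / {len(self.beta_cov)}"
            )
        return self.beta0 + self.beta_time * t + x @ self.beta_cond + z @ self.beta_cov

    def to_json(self, path=None) -> str:
        payload = {
            "condition_names": list(self.condition_names),
            "covariate_names": list(self.covariate_names),
            "params": {k: float(v) for k, v in zip(self.param_names, self.params)},
            "se": None if self.se is None else [float(s) for s in self.se],
            "loglik": self.loglik,
            "converged": self.converged,
            "n_person_years": self.n_person_years,
            "n_events": self.n_events,
            "n_persons": self.n_persons,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def design_matrix(panel: CohortPanel) -> tuple[np.ndarray, np.ndarray]:
    df = panel.df
    cols = ["t", *panel.condition_names, *panel.covariate_names]
    X = np.column_stack([np.ones(len(df)), df[cols].to_numpy(dtype=float)])
    y = df["outcome"].to_numpy(dtype=float)
    return X, y


def fit_pooled_logistic(panel: CohortPanel, tol: float = 1e-8, maxiter: int = 200) -> RiskModelFit:
    """Deterministic ML fit of the person-year logistic hazard model.

    Raises :class:`NoEventsError` when the outcome is constant and
    :class:`SeparationError` when a predictor perfectly separates events,
    rather than returning silently divergent estimates.
    """
    X, y = design_matrix(panel)
    n_events = int(y.sum())
    if n_events == 0:
        raise NoEventsError("panel contains no outcome events")
    if n_events == len(y):
        raise NoEventsError("panel contains no event-free person-years")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
        except Exception as exc:  # statsmodels PerfectSeparationError and kin
            if "separation" in str(exc).lower() or "Singular" in str(exc):
                raise SeparationError(str(exc)) from exc
            raise
    for w in caught:
        if "separation" in str(w.message).lower():
            raise SeparationError(str(w.message))
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 50:
        raise SeparationError("divergent estimates suggest perfect separation")

    d = len(panel.condition_names)
    return RiskModelFit(
        condition_names=panel.condition_names,
        covariate_names=panel.covariate_names,
        beta0=params[0],
        beta_time=params[1],
        beta_cond=params[2 : 2 + d],
        beta_cov=params[2 + d :],
        se=np.asarray(res.bse, dtype=float),
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_person_years=len(y),
        n_events=n_events,
        n_persons=panel.n_persons,
    )


def newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> np.ndarray:
    """Plain Newton (IRLS) logistic ML point estimates.

    Same estimator as :func:`fit_pooled_logistic` without the inference
    extras; used for the many refits inside bootstrap and jackknife loops
    (warm-starting from the full-sample fit).  Convergence on the
    infinity norm of the score; divergence or a singular Hessian raises
    :class:`SeparationError`.
    """
    n_events = y.sum()
    if n_events == 0:
        raise NoEventsError("no outcome events")
    if n_events == len(y):
        raise NoEventsError("no event-free person-years")
    beta = np.zeros(X.shape[1]) if start is None else np.array(start, dtype=float)
    for _ in range(maxiter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            break
        w = p * (1.0 - p)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular Hessian: {exc}") from exc
        # dampen the occasional overshoot far from the optimum
        if np.max(np.abs(step)) > 5.0:
            step *= 5.0 / np.max(np.abs(step))
        beta += step
    else:
        raise SeparationError("Newton iterations did not converge")
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50:
        raise SeparationError("divergent estimates suggest perfect separation")
    return beta


def odds_ratio_table(
    estimates: pd.Series | dict, ses: pd.Series | dict | None = None, z: float = WALD_Z
) -> pd.DataFrame:
    """OR = exp(estimate); Wald CI = exp(estimate +/- z * SE).

    Accepts any named log-odds vector (a fit's coefficients or published
    estimates).  When an SE is missing the OR is reported with the CI
    left empty (with a warning).
    """
    est = pd.Series(estimates, dtype=float)
    table = pd.DataFrame({"estimate": est, "or": np.exp(est)})
    if ses is None:
        warnings.warn("no standard errors supplied; CIs omitted")
        table["ci_low"] = np.nan
        table["ci_high"] = np.nan
        return table
    se = pd.Series(ses, dtype=float).reindex(est.index)
    if se.isna().any():
        warnings.warn(f"missing SE for {list(se.index[se.isna()])}; CIs omitted there")
    table["se"] = se
    table["ci_low"] = np.exp(est - z * se)
    table["ci_high"] = np.exp(est + z * se)
    return table


def coef_to_or(fit: RiskModelFit) -> pd.DataFrame:
    """Odds-ratio table (with Wald 95% CIs) for every model term."""
    est = pd.Series(fit.params, index=fit.param_names)
    se = None if fit.se is None else pd.Series(fit.se, index=fit.param_names)
    return odds_ratio_table(est, se)


def predict_prob(fit: RiskModelFit, condition_vector, covariate_vector, t) -> np.ndarray:
    """Annual outcome probability: inverse-logit of the linear predictor."""
    lp = fit.linear_predictor(t, condition_vector, covariate_vector)
    out = np.asarray(1.0 / (1.0 + np.exp(-lp)))
    return out if out.size > 1 else float(out.reshape(-1)[0])
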