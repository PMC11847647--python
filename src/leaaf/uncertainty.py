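"""Participant-level bootstrap of the attribution pipeline with
bias-corrected and accelerated (BCa) confidence intervals.

Resampling is clustered on participants: a replicate draws n participants
with replacement and every person-year of a drawn participant moves with
them.  Each replicate refits the pooled logistic model and recomputes all
LE-AAFs, so the intervals reflect the whole estimation pipeline.  The
acceleration constant comes from a leave-one-participant-out (or grouped)
jackknife; bias correction from the share of replicate estimates below
the full-sample estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .aaf_engine import compute_attribution
from .panel_builder import CohortPanel
from .plr import (
    NoEventsError,
    SeparationError,
    fit_pooled_logistic,
    newton_logistic,
)

__all__ = [
    "BCaInterval",
    "bootstrap_leaaf",
    "jackknife_leaaf",
    "bca_interval",
    "leaaf_with_bca",
]

log = logging.getLogger(__name__)

DEFAULT_B = 3000          # replicate count used for the headline intervals
JACKKNIFE_GROUP_CAP = 500  # above this many participants, group deletions
JACKKNIFE_N_GROUPS = 200


@dataclass
class BCaInterval:
    """Point estimate with BCa bounds and the adjustment diagnostics."""

    point: float
    lower: float
    upper: float
    z0: float
    a: float
    B: int
    alpha: float = 0.05


def _replicate_seed_rng(seed: int, i: int) -> np.random.Generator:
    # spawn-key indexing keeps the first replicates identical when B grows
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def resample_participants(panel: CohortPanel, rng: np.random.Generator) -> CohortPanel:
    """Draw participants with replacement; duplicated draws get fresh ids."""
    df = panel.df
    ids = df["person_id"].unique()
    codes, _ = pd.factorize(df["person_id"], sort=False)
    starts = np.flatnonzero(np.r_[1, np.diff(codes)])
    bounds = np.r_[starts, len(df)]
    draw = rng.integers(0, len(ids), size=len(ids))
    take = np.concatenate([np.arange(bounds[k], bounds[k + 1]) for k in draw])
    new = df.iloc[take].copy()
    new["person_id"] = np.repeat(
        np.arange(len(draw)), (bounds[draw + 1] - bounds[draw])
    )
    return CohortPanel(
        df=new.reset_index(drop=True),
        condition_names=panel.condition_names,
        covariate_names=panel.covariate_names,
    )


def _leaaf_vector(panel: CohortPanel, method: str) -> np.ndarray:
    fit = fit_pooled_logistic(panel)
    res = compute_attribution(fit, panel, method=method)
    return np.r_[res.leaaf, res.total]


class _ResamplingPipeline:
    """Array-only refit-and-attribute engine for resampling loops.

    Holds the design matrix, outcome, time codes and per-participant row
    blocks of a panel as plain arrays, so each replicate is a row-index
    selection plus a warm-started Newton refit and a bincount-aggregated
    attribution — the same estimator and arithmetic as the public path,
    without per-replicate DataFrame construction.
    """

    def __init__(self, panel: CohortPanel, method: str = "subset-weights"):
        from .aaf_engine import MAX_CONDITIONS_ENUM, _shapley_tables
        from .plr import design_matrix

        if method not in ("subset-weights", "enumerate"):
            raise ValueError(f"unknown method {method!r}")
        self.method = method
        df = panel.df
        self.X, self.y = design_matrix(panel)
        self.t = df["t"].to_numpy(dtype=np.int64)
        self.n_times = int(self.t.max()) + 1
        self.d = d = len(panel.condition_names)
        if method == "enumerate" and d > MAX_CONDITIONS_ENUM:
            raise ValueError(f"d = {d} exceeds order-enumeration cap")
        codes, _ = pd.factorize(df["person_id"], sort=False)
        starts = np.flatnonzero(np.r_[1, np.diff(codes)])
        self.bounds = np.r_[starts, len(df)]
        self.n_persons = len(starts)
        self.masks = ((np.arange(2 ** d)[:, None] >> np.arange(d)) & 1).astype(float)
        self.shapley = _shapley_tables(d)
        self.warm = None  # filled with the full-sample estimates

    def rows_for_participants(self, draw: np.ndarray) -> np.ndarray:
        # concatenated aranges of each drawn participant's row block,
        # built with one cumulative sum instead of a per-person loop
        starts = self.bounds[draw]
        lengths = self.bounds[draw + 1] - starts
        ends = np.cumsum(lengths)
        incr = np.ones(ends[-1], dtype=np.int64)
        incr[0] = starts[0]
        incr[ends[:-1]] = starts[1:] - (starts[:-1] + lengths[:-1] - 1)
        return np.cumsum(incr)

    def leaaf_for_rows(self, rows: np.ndarray) -> np.ndarray:
        import itertools
        import math

        from .plr import newton_logistic

        X, y, t = self.X[rows], self.y[rows], self.t[rows]
        beta = newton_logistic(X, y, start=self.warm)
        d = self.d
        contrib = X[:, 2:2 + d] * beta[2:2 + d]
        lp_obs = X @ beta
        n_masks = len(self.masks)
        sums = np.empty((self.n_times, n_masks))
        for m in range(n_masks):
            p = 1.0 / (1.0 + np.exp(-(lp_obs - contrib @ self.masks[m])))
            sums[:, m] = np.bincount(t, weights=p, minlength=self.n_times)
        weights = np.bincount(t, minlength=self.n_times).astype(float)
        occupied = weights > 0
        sums = sums[occupied]
        weights = weights[occupied]
        if (sums[:, 0] <= 0.0).any():
            raise NoEventsError("observed risk sum vanished at a timepoint")
        af = (sums[:, :1] - sums) / sums[:, :1]
        aaf = np.zeros((len(weights), d))
        if self.method == "subset-weights":
            for j, (without, with_j, wj) in enumerate(self.shapley):
                aaf[:, j] = (af[:, with_j] - af[:, without]) @ wj
        else:
            n_orders = math.factorial(d)
            for order in itertools.permutations(range(d)):
                mask = 0
                prev = np.zeros(len(weights))
                for j in order:
                    mask |= 1 << j
                    aaf[:, j] += af[:, mask] - prev
                    prev = af[:, mask]
            aaf /= n_orders
        leaaf = weights @ aaf / weights.sum()
        return np.r_[leaaf, leaaf.sum()]


def bootstrap_leaaf(
    panel: CohortPanel,
    B: int = DEFAULT_B,
    seed: int = 0,
    method: str = "subset-weights",
    max_failure_rate: float = 0.20,
) -> tuple[np.ndarray, dict]:
    """B clustered-bootstrap replicates of (LE-AAF_1..d, total).

    Returns the (B_ok x (d+1)) replicate matrix and diagnostics including
    the count of non-converged replicates (excluded, logged).  More than
    ``max_failure_rate`` failures is a hard error.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    pipe = _ResamplingPipeline(panel, method)
    pipe.warm = newton_logistic(pipe.X, pipe.y)
    rows = []
    failures = 0
    for i in range(B):
        rng = _replicate_seed_rng(seed, i)
        draw = rng.integers(0, pipe.n_persons, size=pipe.n_persons)
        try:
            rows.append(pipe.leaaf_for_rows(pipe.rows_for_participants(draw)))
        except (NoEventsError, SeparationError) as exc:
            failures += 1
            log.warning("bootstrap replicate %d excluded: %s", i, exc)
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed to converge; "
            "the model is too unstable for interval estimation"
        )
    diagnostics = {"B_requested": B, "B_used": len(rows), "n_failed": failures}
    return np.asarray(rows), diagnostics


def jackknife_leaaf(
    panel: CohortPanel,
    method: str = "subset-weights",
    group_cap: int = JACKKNIFE_GROUP_CAP,
    n_groups: int = JACKKNIFE_N_GROUPS,
) -> np.ndarray:
    """Leave-one-participant-out estimates of (LE-AAF_1..d, total).

    With more than ``group_cap`` participants, deletion switches to
    ``n_groups`` round-robin participant blocks (delete-k jackknife), which
    approximates the acceleration constant at a fraction of the refits.
    Deletions whose refit fails are excluded with a log entry.
    """
    pipe = _ResamplingPipeline(panel, method)
    pipe.warm = newton_logistic(pipe.X, pipe.y)
    n = pipe.n_persons
    if n < 3:
        raise ValueError("jackknife requires at least 3 participants")
    all_ids = np.arange(n)
    if n > group_cap:
        groups = [all_ids[g::n_groups] for g in range(min(n_groups, n))]
        log.info("grouped jackknife: %d groups over %d participants", len(groups), n)
    else:
        groups = [np.array([pid]) for pid in all_ids]
    out = []
    for grp in groups:
        keep = np.setdiff1d(all_ids, grp, assume_unique=True)
        try:
            out.append(pipe.leaaf_for_rows(pipe.rows_for_participants(keep)))
        except (NoEventsError, SeparationError) as exc:
            log.warning("jackknife deletion excluded: %s", exc)
    return np.asarray(out)


def bca_interval(
    point: float,
    boot_estimates: np.ndarray,
    jackknife_estimates: np.ndarray,
    alpha: float = 0.05,
    tie_mode: str = "strict",
) -> BCaInterval:
    """BCa interval from bootstrap draws and jackknife estimates.

    z0 is the normal quantile of the share of bootstrap estimates below
    the point estimate (ties count 0 under ``tie_mode='strict'``, 1/2
    under ``'half'``); the acceleration a is the standard jackknife
    skewness ratio; the bounds are type-7 empirical quantiles of the
    bootstrap distribution at the adjusted percentiles.  A degenerate
    bootstrap distribution collapses the interval to the point with a
    warning; an all-one-sided distribution clamps z0 with a warning.
    """
    boot = np.asarray(boot_estimates, dtype=float)
    jack = np.asarray(jackknife_estimates, dtype=float)
    B = len(boot)
    if B < 2:
        raise ValueError("need at least 2 bootstrap estimates")

    if boot.max() == boot.min() and np.isclose(boot[0], point):
        warnings.warn("degenerate bootstrap distribution; interval collapses to the point")
        return BCaInterval(point, point, point, z0=0.0, a=0.0, B=B, alpha=alpha)

    below = np.sum(boot < point)
    if tie_mode == "half":
        ties = np.sum(boot == point)
        if ties:
            log.info("bca: %d ties with the point estimate counted as half", ties)
        below = below + 0.5 * ties
    prop = below / B
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn(
            "all bootstrap estimates on one side of the point estimate; "
            "bias-correction proportion clamped"
        )
        prop = np.clip(prop, 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(prop)

    theta_bar = jack.mean()
    dev = theta_bar - jack
    denom = np.sum(dev ** 2) ** 1.5
    a = 0.0 if denom == 0.0 else np.sum(dev ** 3) / (6.0 * denom)

    z_lo, z_hi = norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)
    a1 = norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
    a2 = norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
    lower = float(np.quantile(boot, a1, method="linear"))
    upper = float(np.quantile(boot, a2, method="linear"))
    return BCaInterval(float(point), lower, upper, z0=float(z0), a=float(a), B=B, alpha=alpha)


def leaaf_with_bca(
    panel: CohortPanel,
    B: int = DEFAULT_B,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "subset-weights",
) -> dict:
    """Point LE-AAFs with per-condition and total BCa intervals."""
    fit = fit_pooled_logistic(panel)
    res = compute_attribution(fit, panel, method=method)
    point = np.r_[res.leaaf, res.total]
    boot, diagnostics = bootstrap_leaaf(panel, B=B, seed=seed, method=method)
    jack = jackknife_leaaf(panel, method=method)
    labels = [*res.condition_names, "total"]
    intervals = {
        lab: bca_interval(point[k], boot[:, k], jack[:, k], alpha=alpha)
        for k, lab in enumerate(labels)
    }
    return {
        "attribution": res,
        "intervals": intervals,
        "bootstrap": boot,
        "jackknife": jack,
        "diagnostics": diagnostics,
    }

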