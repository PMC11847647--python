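"""Average attributable fractions over removal orders, and their
person-year-weighted longitudinal aggregation (LE-AAF).

For a fitted annual-risk model and the person-years observed at time t,
the attributable fraction of a condition subset S is the excess fraction

    AF(S; t) = [sum_i p_i(observed) - sum_i p_i(S removed)] / sum_i p_i(observed),

where p_i is the model probability at person i's observed conditions and
covariates with the conditions in S forced absent.  The sequential AF of a
condition is its incremental AF given the conditions removed before it in
a removal order; averaging the sequential AF over all d! removal orders
gives the average attributable fraction AAF_j(t).  The average over orders
is computed exactly through the subset-weight (Shapley) identity

    AAF_j(t) = sum_{S subset of C\\{j}} |S|! (d-1-|S|)! / d! * [AF(S u {j}) - AF(S)],

which makes the per-condition AAFs sum exactly to the joint AF with all
conditions removed (component-additivity).  The LE-AAF is the person-year
weighted average of AAF_j(t) over the follow-up grid.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_builder import CohortPanel
from .plr import RiskModelFit

__all__ = [
    "AttributionResult",
    "af_subset",
    "sequential_af",
    "average_af",
    "single_factor_af",
    "le_aaf",
    "compute_attribution",
]

MAX_CONDITIONS_SUBSET = 20   # 2^d table
MAX_CONDITIONS_ENUM = 7      # d! orders


@dataclass
class AttributionResult:
    """Per-time AAFs, person-year weights, LE-AAFs and their total."""

    condition_names: tuple[str, ...]
    times: np.ndarray            # integer time grid
    aaf_by_time: np.ndarray      # d x len(times)
    weights: np.ndarray          # person-years per time
    leaaf: np.ndarray            # d
    total: float
    method: str

    def to_frame(self) -> pd.DataFrame:
        """Tidy (condition, t, aaf, weight) table."""
        d, T = self.aaf_by_time.shape
        return pd.DataFrame({
            "condition": np.repeat(self.condition_names, T),
            "t": np.tile(self.times, d),
            "aaf": self.aaf_by_time.ravel(),
            "weight": np.tile(self.weights, d),
        })

    def summary(self) -> dict:
        return {
            "method": self.method,
            "d": len(self.condition_names),
            "T": int(self.times.max()) if len(self.times) else 0,
            "leaaf": {c: float(v) for c, v in zip(self.condition_names, self.leaaf)},
            "total": float(self.total),
        }


def _rows_design(fit: RiskModelFit, rows: pd.DataFrame):
    x = rows[list(fit.condition_names)].to_numpy(dtype=float)
    z = rows[list(fit.covariate_names)].to_numpy(dtype=float)
    t = rows["t"].to_numpy(dtype=float)
    return x, z, t


def _prob_sum_removed(fit: RiskModelFit, rows: pd.DataFrame, masks: np.ndarray) -> np.ndarray:
    """sum_i p_i with condition subsets zeroed, for each 0/1 mask row.

    The linear predictor with subset S removed is the observed predictor
    minus the condition contributions of S, so all subsets share one pass
    over the data.
    """
    x, z, t = _rows_design(fit, rows)
    contrib = x * fit.beta_cond                      # n x d
    lp_obs = fit.beta0 + fit.beta_time * t + contrib.sum(axis=1) + z @ fit.beta_cov
    out = np.empty(len(masks))
    for m, mask in enumerate(masks):
        lp = lp_obs - contrib @ mask
        out[m] = np.sum(1.0 / (1.0 + np.exp(-lp)))
    return out


def af_subset(fit: RiskModelFit, rows: pd.DataFrame, removed) -> float:
    """Attributable fraction of removing condition subset ``removed``.

    ``removed`` is an iterable of condition indices or names.  AF of the
    empty set is 0 by construction; an all-zero observed risk sum makes
    the fraction undefined and raises.
    """
    if len(rows) == 0:
        raise ValueError("empty person-period set")
    idx = _as_indices(fit, removed)
    d = len(fit.condition_names)
    mask = np.zeros(d)
    mask[idx] = 1.0
    sums = _prob_sum_removed(fit, rows, np.vstack([np.zeros(d), mask]))
    if sums[0] <= 0.0:
        raise ZeroDivisionError("observed risk sum is zero; AF undefined")
    return float((sums[0] - sums[1]) / sums[0])


def _as_indices(fit: RiskModelFit, items) -> list[int]:
    out = []
    for it in items:
        out.append(fit.condition_names.index(it) if isinstance(it, str) else int(it))
    if len(set(out)) != len(out):
        raise ValueError("duplicate conditions in subset")
    return out


def _af_table(fit: RiskModelFit, rows: pd.DataFrame) -> np.ndarray:
    """AF(S) for every subset S, indexed by bitmask (length 2^d)."""
    d = len(fit.condition_names)
    if d > MAX_CONDITIONS_SUBSET:
        raise ValueError(f"d = {d} exceeds subset-enumeration cap {MAX_CONDITIONS_SUBSET}")
    masks = ((np.arange(2 ** d)[:, None] >> np.arange(d)) & 1).astype(float)
    sums = _prob_sum_removed(fit, rows, masks)
    if sums[0] <= 0.0:
        raise ZeroDivisionError("observed risk sum is zero; AF undefined")
    return (sums[0] - sums) / sums[0]


@functools.lru_cache(maxsize=8)
def _shapley_tables(d: int):
    """Per-condition subset index pairs and order weights, cached by d."""
    w = np.array([math.factorial(s) * math.factorial(d - 1 - s) / math.factorial(d)
                  for s in range(d)])
    masks = np.arange(2 ** d)
    sizes = np.array([bin(m).count("1") for m in masks])
    tables = []
    for j in range(d):
        bit = 1 << j
        without = masks[(masks & bit) == 0]
        tables.append((without, without | bit, w[sizes[without]]))
    return tables


def _shapley_from_table(af: np.ndarray, d: int) -> np.ndarray:
    """Average sequential contribution of each condition from the AF table."""
    out = np.zeros(d)
    for j, (without, with_j, wj) in enumerate(_shapley_tables(d)):
        out[j] = np.sum(wj * (af[with_j] - af[without]))
    return out


def sequential_af(fit: RiskModelFit, rows: pd.DataFrame, order) -> np.ndarray:
    """Incremental AFs along one removal order (telescoping to AF(all)).

    ``order`` is a permutation of all condition indices/names; element m of
    the result is the contribution of the condition removed m-th, i.e.
    AF(first m removed) - AF(first m-1 removed), reported in the order's
    sequence.
    """
    idx = _as_indices(fit, order)
    d = len(fit.condition_names)
    if sorted(idx) != list(range(d)):
        raise ValueError("order must be a permutation of all conditions")
    contribs = np.empty(d)
    prev = 0.0
    for m in range(1, d + 1):
        cur = af_subset(fit, rows, idx[:m])
        contribs[m - 1] = cur - prev
        prev = cur
    return contribs


def average_af(fit: RiskModelFit, rows: pd.DataFrame, method: str = "subset-weights") -> np.ndarray:
    """AAF_j at one timepoint: mean sequential AF over all removal orders.

    ``method='subset-weights'`` uses the exact Shapley identity over the
    2^d AF table; ``method='enumerate'`` explicitly averages over all d!
    orders (cross-check path, capped at small d).  Both return one value
    per condition in the fit's condition order.
    """
    d = len(fit.condition_names)
    af = _af_table(fit, rows)
    if method == "subset-weights":
        return _shapley_from_table(af, d)
    if method == "enumerate":
        if d > MAX_CONDITIONS_ENUM:
            raise ValueError(f"d = {d} exceeds order-enumeration cap {MAX_CONDITIONS_ENUM}")
        acc = np.zeros(d)
        n_orders = 0
        for order in itertools.permutations(range(d)):
            mask = 0
            prev = 0.0
            for j in order:
                mask |= 1 << j
                acc[j] += af[mask] - prev
                prev = af[mask]
            n_orders += 1
        return acc / n_orders
    raise ValueError(f"unknown method {method!r}")


def single_factor_af(fit: RiskModelFit, rows: pd.DataFrame, j) -> float:
    """Single-factor AF of condition j at one timepoint.

    Prevalence of j times the mean risk difference (j present vs absent)
    among the exposed, divided by the mean observed risk — the textbook
    excess-fraction expression, algebraically equal to ``af_subset({j})``.
    Returns 0 when nobody has the condition.
    """
    (jdx,) = _as_indices(fit, [j])
    x, z, t = _rows_design(fit, rows)
    exposed = x[:, jdx] == 1
    prev = exposed.mean()
    if prev == 0.0:
        return 0.0
    p_obs = 1.0 / (1.0 + np.exp(-fit.linear_predictor(t, x, z)))
    if p_obs.mean() <= 0.0:
        raise ZeroDivisionError("observed risk is zero; AF undefined")
    x0 = x[exposed].copy()
    x0[:, jdx] = 0.0
    p1 = p_obs[exposed]
    p0 = 1.0 / (1.0 + np.exp(-fit.linear_predictor(t[exposed], x0, z[exposed])))
    return float(prev * (p1.mean() - p0.mean()) / p_obs.mean())


def le_aaf(aaf_by_time: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Person-year-weighted time average of AAFs, and the additive total.

    ``aaf_by_time`` is d x T; ``weights`` the person-years per timepoint.
    Returns (LE-AAF per condition, sum over conditions).
    """
    w = np.asarray(weights, dtype=float)
    a = np.atleast_2d(np.asarray(aaf_by_time, dtype=float))
    if a.shape[1] != len(w):
        raise ValueError("weights do not align with the time grid")
    if w.min() < 0:
        raise ValueError("negative person-year weight")
    if w.sum() <= 0:
        raise ValueError("all-zero weights")
    leaaf = a @ w / w.sum()
    return leaaf, float(leaaf.sum())


def compute_attribution(
    fit: RiskModelFit, panel: CohortPanel, method: str = "subset-weights"
) -> AttributionResult:
    """Full longitudinal attribution: AAF_j(t) on the person-year grid,
    person-year weights, LE-AAFs and their additive total.

    All timepoints share one pass over the panel: probabilities under each
    of the 2^d removal subsets are evaluated for every person-year and
    summed within years, giving the per-year AF tables at once.
    """
    d = len(fit.condition_names)
    if d > MAX_CONDITIONS_SUBSET:
        raise ValueError(f"d = {d} exceeds subset-enumeration cap {MAX_CONDITIONS_SUBSET}")
    df = panel.df.sort_values("t", kind="stable")
    t_all = df["t"].to_numpy()
    times = np.unique(t_all)
    starts = np.searchsorted(t_all, times)
    x, z, t = _rows_design(fit, df)
    contrib = x * fit.beta_cond
    lp_obs = fit.beta0 + fit.beta_time * t + contrib.sum(axis=1) + z @ fit.beta_cov
    n_masks = 2 ** d
    bit_masks = ((np.arange(n_masks)[:, None] >> np.arange(d)) & 1).astype(float)
    sums = np.empty((len(times), n_masks))
    for m in range(n_masks):
        p = 1.0 / (1.0 + np.exp(-(lp_obs - contrib @ bit_masks[m])))
        sums[:, m] = np.add.reduceat(p, starts)
    if (sums[:, 0] <= 0.0).any():
        raise ZeroDivisionError("observed risk sum is zero at some timepoint; AF undefined")
    af_tables = (sums[:, :1] - sums) / sums[:, :1]

    weights = np.diff(np.r_[starts, len(df)]).astype(float)
    aaf = np.zeros((d, len(times)))
    if method == "subset-weights":
        for k in range(len(times)):
            aaf[:, k] = _shapley_from_table(af_tables[k], d)
    elif method == "enumerate":
        if d > MAX_CONDITIONS_ENUM:
            raise ValueError(f"d = {d} exceeds order-enumeration cap {MAX_CONDITIONS_ENUM}")
        n_orders = math.factorial(d)
        for k in range(len(times)):
            af = af_tables[k]
            acc = np.zeros(d)
            for order in itertools.permutations(range(d)):
                mask = 0
                prev = 0.0
                for j in order:
                    mask |= 1 << j
                    acc[j] += af[mask] - prev
                    prev = af[mask]
            aaf[:, k] = acc / n_orders
    else:
        raise ValueError(f"unknown method {method!r}")
    leaaf, total = le_aaf(aaf, weights)
    return AttributionResult(
        condition_names=fit.condition_names,
        times=times,
        aaf_by_time=aaf,
        weights=weights,
        leaaf=leaaf,
        total=total,
        method=method,
    )
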