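"""Conventional population-attributable-fraction baselines.

Case-based (Miettinen) PAFs from adjusted odds ratios or unadjusted risk
ratios, for sensitivity comparison against the order-averaged LE-AAFs.
Conventional PAFs treat each exposure in isolation and are not additive:
their sum across co-occurring conditions can exceed the joint
attributable fraction (and even 100%), which the comparison table makes
explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aaf_engine import AttributionResult
from .panel_builder import CohortPanel
from .plr import RiskModelFit

__all__ = [
    "PafEstimate",
    "paf_miettinen",
    "paf_levin",
    "unadjusted_rr",
    "case_exposure_prevalence",
    "paf_table",
    "compare_paf_leaaf",
]


@dataclass(frozen=True)
class PafEstimate:
    condition: str
    measure: str          # "adjusted_or" | "unadjusted_rr"
    prevalence: float     # exposure prevalence among cases
    paf: float


def paf_miettinen(relative_measure: float, case_exposure_prevalence: float) -> float:
    """Miettinen's case-based PAF: p_c * (R - 1) / R.

    ``case_exposure_prevalence`` is the exposure prevalence among incident
    cases; R the relative measure of association (RR, or OR for a rare
    outcome).  Equals 0 at R = 1 and approaches p_c as R grows.
    """
    if relative_measure <= 0:
        raise ValueError("relative measure must be positive")
    if not 0.0 <= case_exposure_prevalence <= 1.0:
        raise ValueError("case exposure prevalence must be in [0, 1]")
    return case_exposure_prevalence * (relative_measure - 1.0) / relative_measure


def paf_levin(relative_measure: float, population_prevalence: float) -> float:
    """Levin's PAF: p (R - 1) / (1 + p (R - 1)), with population prevalence p."""
    if relative_measure <= 0:
        raise ValueError("relative measure must be positive")
    if not 0.0 <= population_prevalence <= 1.0:
        raise ValueError("population prevalence must be in [0, 1]")
    x = population_prevalence * (relative_measure - 1.0)
    return x / (1.0 + x)


def unadjusted_rr(panel: CohortPanel, condition: str) -> float:
    """Crude risk ratio of event proportions in exposed vs unexposed
    person-years for one condition.  Infinite (flagged) when no unexposed
    events occur."""
    df = panel.df
    exposed = df[condition].to_numpy(dtype=bool)
    y = df["outcome"].to_numpy(dtype=float)
    if exposed.all() or not exposed.any():
        raise ValueError(f"condition {condition!r}: need exposed and unexposed person-years")
    risk1 = y[exposed].mean()
    risk0 = y[~exposed].mean()
    if risk0 == 0.0:
        import warnings

        warnings.warn(f"condition {condition!r}: zero unexposed events; RR infinite")
        return float("inf")
    return float(risk1 / risk0)


def case_exposure_prevalence(panel: CohortPanel, condition: str) -> float:
    """Share of incident cases exposed to the condition at their event row."""
    cases = panel.df[panel.df["outcome"] == 1]
    if len(cases) == 0:
        raise ValueError("panel has no events")
    return float(cases[condition].mean())


def paf_table(panel: CohortPanel, fit: RiskModelFit) -> pd.DataFrame:
    """Per-condition PAF_OR (adjusted OR, from the pooled logistic fit that
    also drives the LE-AAFs) and PAF_RR (crude person-year risk ratio),
    both through Miettinen's case-based formula."""
    rows = []
    for j, c in enumerate(panel.condition_names):
        p_c = case_exposure_prevalence(panel, c)
        or_adj = float(np.exp(fit.beta_cond[j]))
        rr = unadjusted_rr(panel, c)
        rows.append({
            "condition": c,
            "case_exposure_prevalence": p_c,
            "adjusted_or": or_adj,
            "unadjusted_rr": rr,
            "paf_or": paf_miettinen(or_adj, p_c),
            "paf_rr": paf_miettinen(rr, p_c) if np.isfinite(rr) else np.nan,
        })
    return pd.DataFrame(rows)


def compare_paf_leaaf(
    paf: pd.DataFrame,
    attribution: AttributionResult,
    intervals: dict | None = None,
) -> pd.DataFrame:
    """Side-by-side LE-AAF vs conventional PAFs, with divergence flags.

    Adds per-condition deltas, a flag for PAFs falling outside the LE-AAF
    BCa interval (when intervals are supplied), and a totals row showing
    the additive LE-AAF total against the simple PAF sums (which can
    exceed the joint attributable fraction).
    """
    leaaf = pd.Series(attribution.leaaf, index=attribution.condition_names, name="leaaf")
    tab = paf.set_index("condition")
    if set(tab.index) != set(leaaf.index):
        raise ValueError(
            f"condition label mismatch: {sorted(set(tab.index) ^ set(leaaf.index))}"
        )
    out = tab.join(leaaf)
    out["delta_paf_or"] = out["paf_or"] - out["leaaf"]
    out["delta_paf_rr"] = out["paf_rr"] - out["leaaf"]
    if intervals is not None:
        lo = pd.Series({c: intervals[c].lower for c in leaaf.index})
        hi = pd.Series({c: intervals[c].upper for c in leaaf.index})
        out["paf_or_outside_bca"] = (out["paf_or"] < lo) | (out["paf_or"] > hi)
        out["paf_rr_outside_bca"] = (out["paf_rr"] < lo) | (out["paf_rr"] > hi)
    totals = pd.DataFrame(
        {
            "leaaf": [attribution.total],
            "paf_or": [out["paf_or"].sum()],
            "paf_rr": [out["paf_rr"].sum()],
        },
        index=pd.Index(["total"], name="condition"),
    )
    out = pd.concat([out, totals])
    out.attrs["paf_sum_exceeds_joint"] = bool(
        out.loc["total", "paf_or"] > attribution.total
        or out.loc["total", "paf_rr"] > attribution.total
    )
    return out
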