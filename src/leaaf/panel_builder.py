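"""Raw longitudinal records -> analysis-ready person-year panel.

Applies the cohort's eligibility and censoring rules: left truncation at
age 68, right censoring at the first of incident event, age above 99,
enrollment gap or missing time-varying covariate, one-year carry-forward
of biennially observed covariates, dichotomization of raw covariates at
fixed cut points, and the minimum-observation and event-free-at-entry
eligibility rules.  Every exclusion is counted with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._published import CONDITIONS, COVARIATES
from .synthetic_cohort import Thresholds

__all__ = [
    "CohortPanel",
    "PanelIntegrityError",
    "expand_person_years",
    "dichotomize_covariates",
    "panel_summary",
]

TIME_VARYING_RAW = ("networth", "bmi", "adl_count")


class PanelIntegrityError(ValueError):
    """Raw records violate a structural invariant (named in the message)."""


@dataclass
class CohortPanel:
    """Validated person-year panel.

    ``df`` has one row per participant-year with columns ``person_id``,
    ``t`` (integer years since individual baseline, contiguous from 0),
    one 0/1 column per condition (absorbing within person), one 0/1 column
    per covariate, and the 0/1 ``outcome`` which is 1 only on a person's
    final row.
    """

    df: pd.DataFrame
    condition_names: tuple[str, ...]
    covariate_names: tuple[str, ...]
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_persons(self) -> int:
        return self.df["person_id"].nunique()

    @property
    def n_person_years(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df["outcome"].sum())

    def validate(self) -> None:
        df = self.df
        required = ["person_id", "t", "outcome", *self.condition_names, *self.covariate_names]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise PanelIntegrityError(f"panel missing columns {missing}")
        for c in (*self.condition_names, *self.covariate_names, "outcome"):
            vals = df[c].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                bad = df.index[~np.isin(vals, (0, 1))][0]
                raise PanelIntegrityError(f"column {c!r} non-binary at row {bad}")
        g = df.groupby("person_id", sort=False)
        if (g.size() < 2).any():
            pid = g.size()[g.size() < 2].index[0]
            raise PanelIntegrityError(f"person {pid!r} has fewer than 2 observations")
        t = df["t"].to_numpy()
        expected = g.cumcount().to_numpy()
        if (t != expected).any():
            pid = df.loc[df.index[t != expected][0], "person_id"]
            raise PanelIntegrityError(f"person {pid!r}: t not contiguous from 0")
        for c in self.condition_names:
            dec = g[c].diff().fillna(0) < 0
            if dec.any():
                pid = df.loc[dec.idxmax(), "person_id"]
                raise PanelIntegrityError(f"person {pid!r}: condition {c!r} not absorbing")
        nonlast_event = df["outcome"].astype(bool) & (g.cumcount(ascending=False) != 0)
        if nonlast_event.any():
            pid = df.loc[nonlast_event.idxmax(), "person_id"]
            raise PanelIntegrityError(f"person {pid!r}: outcome before final row")


def dichotomize_covariates(
    raw: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Map raw covariate values to the nine binary analysis covariates.

    Strict ``>`` for baseline age, net worth and BMI (a value exactly at
    the cut point codes 0); ``>=`` for ADL count and education years.
    Already-binary inputs (columns named as the analysis covariates) pass
    through unchanged, which makes the mapping idempotent.  Missing raw
    values yield missing indicators; the caller censors from the first
    missing row (complete-case rule).
    """
    th = thresholds
    out = pd.DataFrame(index=raw.index)
    rules = {
        "female": ("female", None),
        "educ_12plus": ("educ_years", lambda v: v >= th.educ_years),
        "networth_above_median": ("networth", lambda v: v > th.networth),
        "bmi_over_30": ("bmi", lambda v: v > th.bmi),
        "coupled": ("coupled", None),
        "age_above_median": ("age_at_entry", lambda v: v > th.baseline_age),
        "adl_2plus": ("adl_count", lambda v: v >= th.adl),
        "black": ("black", None),
        "hispanic": ("hispanic", None),
    }
    for name, (src, fn) in rules.items():
        if name in raw.columns:          # already dichotomized
            out[name] = raw[name].astype(float)
        elif src in raw.columns:
            vals = raw[src]
            if fn is None:
                out[name] = vals.astype(float)
            else:
                res = fn(vals.astype(float))
                out[name] = res.astype(float).where(vals.notna())
        else:
            raise PanelIntegrityError(f"no source column for covariate {name!r}")
    return out


def expand_person_years(
    records: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    condition_names: tuple[str, ...] = CONDITIONS,
    covariate_names: tuple[str, ...] = COVARIATES,
    min_age: int = 68,
    max_age: int = 99,
) -> CohortPanel:
    """Apply truncation, censoring and eligibility rules; return the panel.

    Rules, in order, per person:

    1. drop years with age < ``min_age`` (left truncation) or > ``max_age``;
    2. carry biennially observed covariates forward one year;
    3. censor at the first enrollment gap or missing covariate;
    4. censor at the first year not contiguous with the previous retained
       year (an unexplained gap in observation);
    5. keep the first event year as the final row (y = 1), drop later rows;
    6. re-index time so the first retained row is t = 0;
    7. drop persons with fewer than 2 retained rows, or with the event
       already present on their first retained row.

    Exclusion counts by reason are recorded on the returned panel.
    Raises :class:`PanelIntegrityError` for non-absorbing condition flags
    or duplicate (person, year) rows, naming the offending person.
    """
    df = records.copy()
    time_col = "year" if "year" in df.columns else "t"
    if time_col not in df.columns:
        raise PanelIntegrityError("records need a 'year' or 't' column")
    df.sort_values(["person_id", time_col], inplace=True, kind="stable")
    df.reset_index(drop=True, inplace=True)

    if df.duplicated(["person_id", time_col]).any():
        pid = df.loc[df.duplicated(["person_id", time_col]).idxmax(), "person_id"]
        raise PanelIntegrityError(f"person {pid!r}: duplicate ({time_col}) rows")
    g = df.groupby("person_id", sort=False)
    for c in condition_names:
        if c not in df.columns:
            raise PanelIntegrityError(f"records missing condition column {c!r}")
        dec = g[c].diff().fillna(0) < 0
        if dec.any():
            pid = df.loc[dec.idxmax(), "person_id"]
            raise PanelIntegrityError(f"person {pid!r}: condition {c!r} not absorbing")

    exclusions: dict[str, int] = {}
    n_rows0 = len(df)

    # 1. age truncation (skipped when no age information is present,
    #    e.g. when re-expanding an already-built panel)
    if "age" in df.columns:
        in_age = (df["age"] >= min_age) & (df["age"] <= max_age)
        exclusions["rows_outside_age_range"] = int((~in_age).sum())
        df = df[in_age]
    else:
        exclusions["rows_outside_age_range"] = 0

    # 2. carry-forward of biennial covariates (one year at most)
    present = [c for c in TIME_VARYING_RAW if c in df.columns]
    if present:
        df = df.copy()
        df[present] = df.groupby("person_id", sort=False)[present].ffill(limit=1)

    # dichotomize (pass-through if already binary)
    z = dichotomize_covariates(df, thresholds)

    # 3. censor at first gap / missing covariate
    ok = z.notna().all(axis=1).to_numpy()
    if "enrolled" in df.columns:
        ok &= df["enrolled"].to_numpy() == 1
    keep = pd.Series(ok, index=df.index).groupby(df["person_id"], sort=False).cummin()
    exclusions["rows_after_gap_or_missing"] = int((~keep.astype(bool)).sum())
    df, z = df[keep.astype(bool)], z[keep.astype(bool)]

    # 4. contiguity of retained years
    gp = df.groupby("person_id", sort=False)
    contiguous = df[time_col] == gp[time_col].transform("min") + gp.cumcount()
    contiguous = contiguous.groupby(df["person_id"], sort=False).cummin()
    exclusions["rows_after_observation_gap"] = int((~contiguous).sum())
    df, z = df[contiguous], z[contiguous]

    # 5. truncate after first event
    gp = df.groupby("person_id", sort=False)
    prior_events = gp["outcome"].cumsum() - df["outcome"]
    keep = prior_events == 0
    exclusions["rows_after_event"] = int((~keep).sum())
    df, z = df[keep], z[keep]

    # 6./7. person-level eligibility
    gp = df.groupby("person_id", sort=False)
    first_event = gp["outcome"].transform("first") == 1
    n_prevalent = int(df.loc[first_event, "person_id"].nunique())
    df, z = df[~first_event], z[~first_event]
    gp = df.groupby("person_id", sort=False)
    enough = gp["person_id"].transform("size") >= 2
    n_short = int(df.loc[~enough, "person_id"].nunique())
    df, z = df[enough], z[enough]
    exclusions["persons_event_at_entry"] = n_prevalent
    exclusions["persons_fewer_than_2_obs"] = n_short

    panel_df = pd.DataFrame({"person_id": df["person_id"].to_numpy()})
    panel_df["t"] = df.groupby("person_id", sort=False).cumcount().to_numpy()
    for c in condition_names:
        panel_df[c] = df[c].to_numpy().astype(np.int8)
    for c in covariate_names:
        panel_df[c] = z[c].to_numpy().astype(np.int8)
    panel_df["outcome"] = df["outcome"].to_numpy().astype(np.int8)
    exclusions["rows_in"] = n_rows0
    exclusions["rows_retained"] = len(panel_df)

    panel = CohortPanel(
        df=panel_df.reset_index(drop=True),
        condition_names=tuple(condition_names),
        covariate_names=tuple(covariate_names),
        exclusions=exclusions,
    )
    panel.validate()
    return panel


def panel_summary(panel: CohortPanel) -> dict:
    """Descriptive summary: baseline prevalence, strata, person-years.

    Mirrors the cohort-description tables of a claims-linked study:
    per-condition baseline prevalence, the distribution of the number of
    conditions at baseline, the count of distinct observed condition
    combinations at baseline out of the 2^d possible, and person-years
    at risk per year of follow-up.
    """
    if panel.n_person_years == 0:
        raise ValueError("empty panel")
    df = panel.df
    d = len(panel.condition_names)
    base = df[df["t"] == 0]
    cond = base[list(panel.condition_names)]
    combos = cond.drop_duplicates()
    return {
        "n_persons": panel.n_persons,
        "n_person_years": panel.n_person_years,
        "n_events": panel.n_events,
        "baseline_prevalence": {
            c: float(base[c].mean()) for c in panel.condition_names
        },
        "baseline_condition_count_distribution": (
            cond.sum(axis=1).value_counts().sort_index().to_dict()
        ),
        "n_possible_combinations": 2 ** d,
        "n_observed_combinations_baseline": int(len(combos)),
        "person_years_by_t": df["t"].value_counts().sort_index().to_dict(),
    }
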