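"""Published reference estimates used as simulation defaults and arithmetic checks.

The numbers below are point estimates reported by a large US study of
HRS participants linked to Medicare fee-for-service claims (n = 9944,
1998-2016) that estimated longitudinal average attributable fractions
of eight chronic conditions for incident dementia (ADRD).  The original
individual-level data are restricted-access; these published aggregates
serve two purposes here:

* default ``true_coefficients`` for the synthetic-cohort generator, so
  simulated cohorts carry realistic association strengths, and
* inputs to internal-consistency arithmetic (odds ratios recomputed from
  log-odds, component sums of attributable fractions).
"""

from __future__ import annotations

CONDITIONS: tuple[str, ...] = (
    "ami",            # acute myocardial infarction
    "afib",           # atrial fibrillation
    "diabetes",
    "heart_failure",
    "hypertension",
    "ihd",            # ischemic heart disease
    "arthritis",      # rheumatoid or osteoarthritis
    "stia",           # stroke or transient ischemic attack
)

COVARIATES: tuple[str, ...] = (
    "female",
    "educ_12plus",            # 12 or more years of education
    "networth_above_median",  # net worth > $211,000
    "bmi_over_30",
    "coupled",
    "age_above_median",       # baseline age > 76 years
    "adl_2plus",              # two or more ADL limitations
    "black",
    "hispanic",
)

# Pooled logistic regression log-odds (discrete-time hazard of incident ADRD
# on annual person-period data) and standard errors, as published.
PUBLISHED_TIME_COEF: float = 0.0761
PUBLISHED_TIME_SE: float = 0.006

PUBLISHED_CONDITION_COEFS: dict[str, float] = {
    "ami": 0.127,
    "afib": 0.184,
    "diabetes": 0.133,
    "heart_failure": 0.384,
    "hypertension": 0.241,
    "ihd": 0.199,
    "arthritis": 0.246,
    "stia": 0.675,
}
PUBLISHED_CONDITION_SES: dict[str, float] = {
    "ami": 0.077,
    "afib": 0.057,
    "diabetes": 0.050,
    "heart_failure": 0.054,
    "hypertension": 0.079,
    "ihd": 0.057,
    "arthritis": 0.053,
    "stia": 0.051,
}

PUBLISHED_COVARIATE_COEFS: dict[str, float] = {
    "female": 0.050,
    "educ_12plus": -0.118,
    "networth_above_median": -0.209,
    "bmi_over_30": -0.590,
    "coupled": -0.044,
    "age_above_median": 0.792,
    "adl_2plus": 0.565,
    "black": 0.203,
    "hispanic": 0.172,
}
PUBLISHED_COVARIATE_SES: dict[str, float] = {
    "female": 0.053,
    "educ_12plus": 0.054,
    "networth_above_median": 0.054,
    "bmi_over_30": 0.067,
    "coupled": 0.054,
    "age_above_median": 0.052,
    "adl_2plus": 0.059,
    "black": 0.075,
    "hispanic": 0.102,
}

# Published per-condition LE-AAF point estimates (percent of incident ADRD
# cases) with 95% BCa bounds, and the printed component-additive total.
PUBLISHED_LEAAF: dict[str, tuple[float, float, float]] = {
    "ami": (0.8, -0.2, 2.0),
    "afib": (2.9, 0.8, 4.8),
    "diabetes": (4.1, 0.8, 7.4),
    "heart_failure": (12.2, 8.5, 16.1),
    "hypertension": (16.9, 5.3, 26.7),
    "ihd": (10.0, 4.0, 15.8),
    "arthritis": (12.5, 7.0, 17.6),
    "stia": (12.4, 9.9, 14.9),
}
PUBLISHED_LEAAF_TOTAL: tuple[float, float, float] = (71.8, 62.9, 79.1)

# Baseline prevalence of each condition in the published cohort (Table-style
# aggregates), used as the generator's default baseline prevalences.
PUBLISHED_BASELINE_PREVALENCE: dict[str, float] = {
    "ami": 0.032,
    "afib": 0.076,
    "diabetes": 0.228,
    "heart_failure": 0.190,
    "hypertension": 0.630,
    "ihd": 0.380,
    "arthritis": 0.348,
    "stia": 0.084,
}
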