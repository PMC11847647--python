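# Methods

This note records the model, the estimator, the synthetic data-generating
process, and the numerical and design choices behind `leaaf`, at the
level of detail a user needs to judge what the package's tests do and do
not establish.

## Discrete-time hazard model

The unit of analysis is the person-year.  The incident outcome (an ADRD
analog) follows a pooled logistic regression

    logit P(Y_it = 1 | x_it, z_it) = β₀ + β_T t + x_it·β_cond + z_it·β_cov

where t is integer years since the participant's own baseline (0…18),
x_it the d binary, absorbing condition indicators, and z_it nine binary
covariates (female, ≥12 years of education, net worth above the cohort
median, BMI > 30, coupled, baseline age > 76, ≥2 ADL limitations, Black,
Hispanic).  With annual intervals and event probabilities of a few
percent per year, the pooled logistic model is the standard discrete-time
approximation to a proportional-hazards model.  Estimation is
deterministic maximum likelihood (Newton iterations via statsmodels,
gradient tolerance 1e-8); there is no stochastic optimizer anywhere in
the pipeline.  Standard errors are the usual inverse-Hessian Wald errors
and are reported for odds-ratio tables only — repeated person-years
within a participant are correlated, so pipeline uncertainty comes from
the participant-clustered bootstrap instead, and no cluster-robust
adjustment is applied to the likelihood fit.

A panel with zero events (or zero non-events) raises an error rather than
returning a degenerate fit; perfect separation is detected (singular
Hessian, divergent estimates) and raised as a diagnostic rather than
silently reported.

## Attribution

For a subset S of conditions and the person-years observed at time t, the
attributable fraction is the model-based excess fraction

    AF(S; t) = [Σ_i p_i(observed) − Σ_i p_i(S removed)] / Σ_i p_i(observed),

with probabilities evaluated at each person's own covariates and observed
comorbidity pattern, conditions in S forced to absent.  This person-level
form is the exact version of computing risks "per stratum" of the 2^d
presence/absence combinations: when covariates vary within a condition
stratum the person-level sum is what the stratum computation converges
to, and the two coincide on covariate-homogeneous strata (tested).

The average attributable fraction of condition j at t is the mean of its
sequential AF over all d! removal orders, computed exactly via the
subset-weight (Shapley value) identity rather than by enumerating orders:

    AAF_j(t) = Σ_{S ⊆ C\{j}}  |S|! (d−1−|S|)! / d!  ×  [AF(S∪{j};t) − AF(S;t)].

An explicit order-enumeration mode exists as a cross-check (capped at
d = 7) and agrees with the subset-weight path to 1e-10 on randomized
panels.  Averaging over *all* orders is the canonical average-AF
estimand; restricting to orders compatible with each participant's
observed onset sequence is a conceivable variant but is not implemented —
the classical estimator is what the sequential-AF literature averages.

Key properties, all enforced or tested:

* **Component-additivity.** Σ_j AAF_j(t) equals the joint AF with all d
  conditions removed, at every t, to 1e-10 — by construction of the
  Shapley weights, not by normalization.
* **Null factors.** A condition with zero coefficient or zero prevalence
  has AAF exactly 0 at every t.
* **Negative contributions are retained.**  Truncating them at zero would
  destroy additivity.
* Computation is exact over all 2^d subsets; d is capped at 20 (the 2^d
  table) and memory stays modest because subsets share one pass over the
  linear predictor.

The longitudinal aggregate weights each year by its person-years:
LE-AAF_j = Σ_t w_t AAF_j(t) / Σ_t w_t, with w_t the number of person-year
rows at t (the event year counts as an at-risk person-year and carries
the event).  Years with no events still contribute through model-based
probabilities.  The total Σ_j LE-AAF_j equals the person-year-weighted
joint AF.

## Bootstrap and BCa intervals

Resampling is clustered on participants: each of B replicates draws n
participants with replacement, all person-years of a drawn participant
moving together, then refits the pooled logistic model and recomputes all
LE-AAFs.  Default B = 3000 for headline intervals; the test-suite and the
acceptance script run B = 200 at their reduced scales.  Per-replicate
seeding uses `SeedSequence(seed, spawn_key=(i,))`, so enlarging B leaves
earlier replicates unchanged.  Replicates whose refit fails (no events
after resampling, separation) are excluded and counted; more than 20%
failures aborts with diagnostics.

The BCa interval for each estimate uses

* bias: z₀ = Φ⁻¹(#{θ*_b < θ̂}/B), ties counted as 0 by default (a
  half-tie mode exists); an all-one-sided bootstrap clamps the proportion
  to [1/(B+1), B/(B+1)] with a warning;
* acceleration: a = Σ(θ̄−θ₍ᵢ₎)³ / (6[Σ(θ̄−θ₍ᵢ₎)²]^{3/2}) over jackknife
  estimates θ₍ᵢ₎, computed at the participant level to match the
  clustered resampling.  Above 500 participants the jackknife deletes 200
  round-robin participant blocks instead of single participants (a
  delete-k approximation; the exact mode remains available);
* bounds: type-7 (linear-interpolation) empirical quantiles of the
  bootstrap distribution at the adjusted percentiles
  α_k = Φ(z₀ + (z₀+z_k)/(1−a(z₀+z_k))).

With z₀ = 0 and a = 0 the interval reduces exactly to the percentile
interval (tested); the formulas are pinned against an independent
brute-force implementation to 1e-10.

The many refits inside the bootstrap and jackknife loops run through an
array-only Newton/IRLS engine warm-started at the full-sample estimates —
the same estimator as the public fit path, equivalent to it within 1e-8
on identical replicates (tested) — because per-replicate DataFrame and
model-object construction would otherwise dominate the runtime of the
coverage studies.

## Conventional PAF baselines

For the sensitivity comparison the package computes Miettinen's
case-based PAF, p_c (R−1)/R, with p_c the exposure prevalence among
incident cases at their event row, using either the adjusted odds ratio
from the same pooled logistic fit that drives the LE-AAFs (PAF_OR — so
the comparison isolates the attribution method, not the risk model) or
the crude person-year risk ratio (PAF_RR).  Levin's
population-prevalence formula is available as an alternative.  The
comparison table reports per-condition deltas, flags PAFs outside the
LE-AAF BCa interval, and shows the method sums — conventional PAFs of
co-occurring conditions routinely sum past the additive joint total,
which is the point of the comparison.

## Synthetic cohort generator

The generator emulates the structure of an HRS-style survey linked to
annual claims, without any claims-code machinery:

* **Entry and follow-up.**  Entry ages are a truncated normal
  (mean 72.8, SD 6.5, clipped to 68–99, rounded); follow-up runs on the
  integer grid t = 0…18 and ends at the first of outcome event, age 99,
  study end, enrollment gap, or dropout.  An annual condition-independent
  dropout hazard (default 0.10) stands in for death and disenrollment
  jointly; death is *not* modeled as a semi-competing risk, so, as in the
  real-data setting, condition-attributable mortality would bias LE-AAFs
  toward zero and the generator cannot exhibit that bias.
* **Conditions.**  Baseline prevalences default to the published cohort's
  values (hypertension 63%, down to AMI 3.2%); onsets are absorbing
  annual Bernoulli events whose hazards are scaled by a configurable
  ordered-pair synergy matrix (e.g. hypertension multiplies the
  heart-failure onset hazard by 1.8), sketching a cardiovascular onset
  cascade.  The synergy defaults are qualitative choices — the real onset
  dependence structure is not identified by published aggregates.  AMI is
  configured to never occur in isolation at baseline, matching the
  published combination tables.
* **Covariates.**  Fixed binaries are drawn at published prevalences;
  net worth (lognormal), BMI (normal) and ADL count (Poisson) are drawn
  as continuous/count analogs so the dichotomization stage does real
  work, re-drawn by a random-walk update only on even years since entry
  and carried forward one year (the biennial-survey pattern), with a
  slowly rising ADL rate standing in for aging.
* **Outcome.**  Drawn each person-year from the logistic hazard applied
  to the *dichotomized* covariate state, so the pooled logistic model is
  correctly specified for the generated data — recovery tests therefore
  check estimator correctness, not robustness to misspecification.  The
  default condition, covariate and time coefficients are the published
  point estimates; the intercept, which the published table does not
  contain, was calibrated once by a coarse grid on the generator to the
  published cumulative incidence (20.4% of participants over follow-up)
  and frozen at −5.1 (the default configuration yields 20.0% at
  n = 20 000).

What passing tests on this generator show: the pipeline recovers known
coefficients at the correct asymptotic rate, the attribution equals its
estimand on large samples, and BCa intervals attain near-nominal coverage
under correct specification.  What they cannot show: behavior under
informative censoring by death, claims-coding misclassification,
survey-design effects, or model misspecification — none of which the
generator produces.

## Panel construction rules

Raw records pass through, in order: left truncation below age 68 and
above 99; one-year carry-forward of biennially observed covariates;
censoring at the first enrollment gap or missing covariate (complete-case
from that row on); censoring at any remaining discontinuity in observed
years; truncation after the first event year (kept as the final row,
y = 1); re-indexing of time from the first retained row; exclusion of
participants with fewer than two retained rows or with the event at their
first retained row.  Every dropped row and excluded person is counted by
reason.  Dichotomization uses strict `>` for age (76), net worth
($211 000) and BMI (30), and `>=` for ADL (2) and education years (12) —
the boundary conventions of the source cohort's variable definitions.
Thresholds are fixed configuration values by default so runs are
comparable across synthetic cohorts; conditions newly coded in the event
year remain set on the final row.

## Study sizes in the test suite

The acceptance-style studies are scaled to desk hardware and their sizes
are frozen in the tests: coefficient recovery uses 20 cohorts of 2000
participants; estimand convergence compares 24 cohorts each at
n = 1000/5000/10000 against a 200 000-participant reference
super-population (per-condition mean absolute deviation is dominated by
the sampling noise of the hypertension AAF — the least stable component,
as its wide published interval suggests — so smaller replicate counts
leave the 5000-vs-10000 ordering inside Monte-Carlo noise); interval
coverage uses 100 cohorts of 1000 participants with B = 200 on a
three-condition configuration.  The acceptance script's end-to-end run
uses n = 4000 and B = 200.

## Known limitations

* No semi-competing risk of death; no survey weights; no multiple
  imputation (complete-case censoring only); main-effects hazard model
  only (no interactions or splines).
* The AAF estimand is model-based: all counterfactual probabilities come
  from one pooled logistic fit, and causal interpretation of attributable
  fractions requires the usual no-confounding assumptions.
* Wald CIs in odds-ratio tables use the conventional 1.96 multiplier and
  ignore within-person correlation; use the bootstrap intervals for
  anything downstream.
* The generator's onset-synergy defaults are plausible, not calibrated to
  restricted individual-level data.
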