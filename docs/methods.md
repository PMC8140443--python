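# Methods

This note documents the models, conventions, and numerical choices behind
`carecycle`, and what the synthetic-data tests do and do not establish
about behavior on real data.

## Continuum specification

A continuum is an ordered list of clinical phases, each holding ordered
elements of care; phase and element order define the clockwise axis order
of the circular visualization and the row order of all output tables.
Specs are plain YAML (`spec_version: 1`; see
`src/carecycle/data/msk_default.yaml` for the commented reference file) and
are validated structurally: unique element ids, resolvable composite
members (composites of composites are rejected so one topological pass —
atomics first, composites second — is always sufficient), non-inverted
windows, finite lab thresholds. Validation reports machine-readable
findings and never raises; loading a spec that fails validation raises.

Element rules are disjunctions: an element is present iff *any* criterion
matches. Criteria:

- **Codes** — prefix match within a code system (ICD9 / ICD10 /
  procedure), after dot-stripping and upper-casing. Prefix lists are
  literal; no terminology expansion (a stated non-goal).
- **Labs** — per-analyte aggregation (`max`, `min`, `any`) then comparison
  (`ge`/`le`) against a threshold. The default diabetes rule uses max
  HbA1c ≥ 6.5 %. Only rows in the criterion's units are considered; rows
  in other units are skipped with a logged warning rather than silently
  converted.
- **Medications** — drug-class prefix match; records carrying a `route`
  column have topical routes excluded for systemic-only criteria (the
  antibiotics element is "any systemic antimicrobial", unrestricted in
  time; an episode restriction is a possible future option).
- **Procedures** — any procedure, a code-prefix subset, or only rows with
  the explicit `is_amputation` flag (amputation coding varies enough
  across systems that an explicit flag keeps behavior deterministic; a
  code-prefix fallback can be configured in the rule).
- **Composites** — true iff at least `min_count` member elements are true
  ("two or more of osteomyelitis, septic arthritis, infectious myositis").

**Windows.** Dated criteria may be restricted to an inclusive day-offset
window around the *index infection date*, the earliest diagnosis matching
any of the spec's qualifying infection elements. "The first 3 months" is
fixed as offsets (0, 90): day arithmetic is deterministic where
calendar-month arithmetic is locale-ambiguous. Patients with no qualifying
infection diagnosis fail cohort inclusion and are dropped, with a logged
count, before the matrix is derived.

Anatomic-site proximity ("at or near the site of the infection") is not
modeled as geometry: events may carry an optional body-site label, matched
exactly when both sides carry one and ignored otherwise. No published site
taxonomy exists for this, and exact-label matching is the only testable,
honest reading.

## Estimation

One logistic model per element, fit by Newton-Raphson maximum likelihood
(statsmodels `Logit`; convergence tolerance 1e-8, at most 100 iterations):

    logit P(Y_j=1) = β0 + Σ_g β_g·1[stratum=g] + β_age·age + β_sex·1[male]

- **Reference stratum.** Lowest *crude* odds (TRUE/FALSE count) of the
  index element, ties broken lexicographically. Crude odds are
  deterministic before any model is fit; selection via adjusted odds is
  available behind the `reference=` parameter but is not the default.
- **Intervals and tests.** Wald CIs `exp(β ± z·SE)` and two-sided Wald
  p-values, matching the conventional "OR (95 % CI)" presentation; no
  profile likelihood, no likelihood-ratio tests, no multiple-testing
  correction (α = 0.05 per comparison). Significance is declared exactly
  when the CI excludes 1.00.
- **Covariates.** Age enters linearly in years (the minimal reading of
  "adjusted for age and sex"); sex as a male-vs-female indicator. Analysis
  is complete-case: rows with missing age or a sex outside
  {female, male} are dropped per model with a logged count.
- **Degenerate cells.** A stratum in which the element has zero events or
  all events has no finite MLE; its rows are excluded from that element's
  fit and its result flagged `degenerate` (OR/CI/p all NaN). Post-fit
  guards (|β| > 20 or SE > 100, or non-convergence) likewise flag rather
  than report diverging numbers. There is no penalized (Firth-type)
  fallback in v1: flagged honesty was preferred over silently switching
  estimands. Consequence: in very small strata with rare elements the
  reported MLE carries the textbook finite-sample bias of order
  1/(event count), documented by the recovery study below.

Descriptives mirror the conventional cohort table: per-stratum n, percent,
and age mean/median/SD (one decimal), one-way ANOVA for age across strata,
and a Pearson chi-square for sex by stratum; both are omitted with a
warning when only one stratum is present.

## Visualization

Each non-reference stratum is one polar panel: axes at 360°/n spacing,
first element at 12 o'clock, clockwise in cycle order (the convention is
fixed here and recorded in the figure caption; no standard exists). The
radial coordinate is ln(OR), so OR = 1 is the zero ring, drawn dashed and
identical across panels; the radial range is symmetric about zero and
padded to the nearest power-of-two OR ring (ticks at 0.25, 0.5, 1, 2, 4, 8,
extended in powers of two when an estimate exceeds them), shared by all
panels of one figure so panels are directly comparable. Significant
elements get a `*` suffix on their axis label. Degenerate estimates break
the polygon (a gap) instead of plotting at radius 0, which would fabricate
a null effect; per-vertex CI whiskers are available behind
`FigureRequest.ci_whiskers` (off by default — statistical-error display on
cyclical maps has no settled convention). SVG output is deterministic
(fixed hash salt, no timestamp metadata) and each polygon carries a stable
`gid`, so tests can verify emitted coordinates against the layout geometry
within 0.5 px. The default palette is the colorblind-safe Okabe–Ito set.

## Synthetic cohorts

The generator emulates a single-center hospital cohort of adults with
musculoskeletal infections. Demographics follow the published cohort's
margins: five race/ethnicity strata with proportions
0.402/0.350/0.177/0.045/0.026, per-stratum truncated-normal ages
(means 52.3/56.3/50.9/54.6/53.4, SDs 15.8/14.3/14.6/16.3/13.7 years,
rejection-sampled above 18), and 31.7 % women in every stratum (the source
cohort showed no sex-by-stratum association). Each element is Bernoulli
with a logistic model in stratum, age, and sex; the intercept is calibrated
by bisection (tolerance 1e-9 on the intercept) so the reference stratum's
expected prevalence hits its target.

The `emulation` scenario sets the stratum log-ORs to the natural logs of
a published set of adjusted point estimates — an *emulation* of the
published disparity pattern for demos and recovery tests, not a
reproduction of the study, whose source data are not public. Reference
prevalences are the generator's own choices of plausible values for such a
cohort (diabetes 0.40, peripheral vascular disease 0.08, osteomyelitis
0.60, multiple infection types 0.15, sepsis 0.30, systemic antibiotics
0.85, 90-day surgical procedure 0.55, 90-day amputation 0.12), as are the
small covariate effects (e.g. diabetes +0.03 log-odds per year of age).
The `null` scenario keeps demographics and prevalences but zeroes every
stratum effect.

Dependence: elements are conditionally independent given covariates, with
two exceptions. The surgical-procedure/amputation pair is drawn from one
shared uniform (comonotone coupling): both marginal logistic models hold
exactly, and amputation ⇒ surgical procedure holds whenever the surgical
probability dominates pointwise, which the shipped configurations
guarantee. An optional shared normal frailty (`frailty_sd`) on the linear
predictor induces positive dependence among all elements; it is off by
default because no joint model of the real elements is published.

True element states are materialized as raw coded events that satisfy the
default rules exactly and deterministically (e.g. diabetes via a randomly
chosen mechanism — code, HbA1c ≥ 6.5 lab, or antidiabetic prescription;
infection diagnoses chosen so the per-patient set of infection types
reproduces both the osteomyelitis and the two-or-more-infections booleans;
surgical events dated 0–90 days after the index infection date, plus
decoy out-of-window procedures and sub-threshold HbA1c results for
negative patients). Emission is exact, not noisy: the phenotyper must
reproduce the truth table for 100 % of patients, which is the end-to-end
oracle. Identical seeds give byte-identical CSVs (single `numpy`
`default_rng` stream, fixed draw order).

What passing tests therefore show: the pipeline is internally consistent,
the estimator recovers known effects under a correctly specified model,
and the figures faithfully encode the estimates. What they do not show:
robustness to miscoding, missingness, unit heterogeneity, or dependence
structures of real EHR data, none of which the v1 generator models.

## Recovery study and its known limitation

`recovery_report` runs simulate → phenotype → estimate over replicates and
summarizes, per non-reference stratum × element, the mean/SD of the
estimated log-OR, bias with its Monte-Carlo SE, CI coverage of the truth,
significance rate, and degenerate-fit rate. The reference stratum is fixed
to the generator's configured reference so truth is well defined in every
replicate (crude-odds reference *selection* is exercised separately). The
acceptance-scale study uses n = 2000 and 200 replicates per scenario
(≈1 minute on one CPU); pooled coverage sits near 95 % and the pooled null
significance rate near 5 %.

Known limitation: in the smallest strata (2.6 % and 4.5 % of the cohort,
i.e. ~50–90 patients) with rare elements (~5 events), the unpenalized MLE's
finite-sample bias (≤ 0.19 on the log-OR scale in our runs) is detectable
at 200 replicates — the per-pair mean can sit more than 3 Monte-Carlo SEs
from truth even though the pipeline is exact upstream. This is a property
of the estimator at those sample sizes, reproduced by a direct
statsmodels-only simulation of the same design, and is the documented cost
of the no-penalization decision above.

## Cohort interchange formats

Five CSV tables (UTF-8, header row, ISO-8601 dates), joined on
`patient_id`:

| table | required columns |
|---|---|
| patients | patient_id, age_years, sex, stratum |
| diagnoses | patient_id, code_system, code, date |
| labs | patient_id, analyte, value, units, date |
| medications | patient_id, drug_class, date (+ optional route) |
| procedures | patient_id, code, date, is_amputation (+ optional body_site) |

Codes are normalized on load (dots stripped, upper-cased), event rows for
unknown patients are dropped with a logged count, duplicate patient ids and
malformed dates are errors naming the offending column/row, and loading is
row-order insensitive (canonical sort). Outputs: element matrix CSV (0/1
columns in cycle order), long-form estimates CSV (ORs and CI bounds at six
decimals), and an estimates JSON carrying full model metadata (covariates,
alpha, reference, n per model, degeneracy flags) for programmatic reuse.
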