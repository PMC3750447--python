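# Methods

`rxpatterns` implements a retrospective new-user, active-comparator analysis
of pharmacy-claims data for two glucose-lowering index drugs — a twice-daily
GLP-1 receptor agonist ("exenatide") and a basal insulin ("glargine") — from
cohort selection through first-treatment-modification classification, 1:1
propensity-score matching, and time-to-modification survival comparison. A
synthetic-claims generator with per-patient ground truth stands in for
proprietary insurer databases and defines the conditions under which the
pipeline is validated.

All calendars are integer days from a global origin; a patient's index day
(first in-window fill of either index drug) is day 0 of follow-up. There is
no month or leap-year logic: the design operates in day counts (a 365-day
baseline window, a 545-day follow-up horizon, a 90-day permissible gap).

## Treatment-modification rules

For each patient the classifier resolves exactly one of four mutually
exclusive outcomes within 545 days of index, dated in days since index:

**Discontinuation.** Each index claim's run-out is `fill_day + days_supply`.
A claim *opens a gap* when no index fill occurs in `(fill_day, run_out + 90]`
— a fill inside `(fill_day, run_out]` is an early refill and a fill inside
`(run_out, run_out + 90]` a timely one; either closes the gap. A gap with no
non-index glucose-lowering fill inside `(run_out, run_out + 90]` is a
discontinuation, dated at the run-out, so time-to-event equals time on
therapy.

**Switching.** If instead a non-index glucose-lowering class has its first
fill F inside the gap window and a further fill of the same class occurs no
later than F + 90, the patient switched, dated at F. The replacement class
need not be new to the patient (a baseline drug continued alone after the
index drug stops is, by these definitions, the therapy switched to).

**Intensification.** A fill A of a glucose-lowering class *not used in the
baseline window* whose supply interval `[A, A + supply)` overlaps an index
claim's supply interval, with the index drug refilled within 90 days of that
index claim's run-out and class A refilled within 90 days of A's own
run-out, is an intensification dated at A. For the basal-insulin arm only,
a second route exists: the estimated daily dose (units dispensed divided by
days to the next dispense; undefined for the final fill) rising by ≥100%
from one claim to the next, dated at the second fill of the offending pair.
The earlier of the two routes wins; on a tie the add-on is reported (it
names the added class). The claim-to-claim ratio and the conservative 2.0×
threshold protect early refillers, whose estimated dose is diluted or
concentrated by irregular refill spacing, from misclassification.

**Censoring.** Absent any event, the patient is administratively censored at
day 545 (treatment durability = 545+ days).

Resolution: every detector proposes its earliest candidate; the smallest
event day wins, with the deterministic tie-break intensification > switch >
discontinuation (an intensification implies continued index use — the most
specific evidence). Numerical/edge conventions, chosen where the definitions
underdetermine behaviour:

- **No supply carryover.** Each claim's run-out derives from its own fill
  day; early refills never stack. This is conservative against stockpiling
  artifacts and keeps every rule a function of individual claims.
- **Same-day fills** of one drug are merged (units summed, longest supply
  kept) before any rule runs.
- **Horizon evaluability.** A gap whose 90-day window would extend past day
  545 cannot be fully observed and never yields a discontinuation; such
  patients are censored (no right-edge bias). Claims beyond day 545, when
  present, are used to *confirm* refill windows but never to *date* events.
- **Fall-through.** A gap containing a non-index fill that is never refilled
  (and no index refill) satisfies neither definition; scanning continues and
  a patient censored in that state carries the audit flag
  `gap_with_unconfirmed_nonindex`.
- **Novelty is judged at drug-class level** against the set of classes
  filled in the 365 days before index; continuation of a baseline class is
  never an intensification.
- A non-index fill on the index day itself is combination initiation, not an
  addition, and is not an intensification candidate (event days are strictly
  positive).
- Gap length (90), horizon (545), baseline window (365), and the dose
  threshold (2.0) are `ClassifyParams` fields with those defaults.

An independent day-scanning implementation of the same definitions (in
`tests/oracles.py`) re-derives every patient's outcome by literal
day-by-day application of the rules; the engine is required to agree with it
exactly on an exhaustive grid of small synthetic patients and on randomized
fuzz cases.

## Cohort selection

Index event: earliest in-window fill of either index drug; if both drugs are
first filled on the same day the arm is undecidable and the package raises
an explicit error rather than guessing. Patients must be ≥18 at index, be
continuously enrolled with pharmacy benefit from 365 days before to 545 days
after index without a commercial-to-Medicare transition, carry no diagnosis
of type 1 or gestational diabetes, chronic kidney disease, Cushing syndrome,
acromegaly, or bariatric surgery within the study window, have fewer than
two systemic glucocorticoid fills in the baseline window, and have no
baseline fill of pramlintide, sitagliptin, exenatide, or any insulin (the
washout that makes them new users). Exclusions are evaluated exhaustively
and order-independently; every patient with an index event lands either in
the cohort or in the exclusion log with all failed rules.

The pre-index window is `[index − 365, index − 1]`: the index fill itself is
follow-up, not baseline exposure. The comorbidity index is consumed as a
supplied integer covariate (in the synthetic tables, a count of `cci_point`
marker claims) rather than computed from diagnosis-code maps, which keeps
its role in matching while avoiding code-list curation out of scope here.

## Propensity matching and balance

The basal-insulin arm is modelled as treated (under channelled assignment it
is the smaller arm). Scores come from maximum-likelihood logistic regression
(IRLS via statsmodels GLM) on a fixed design: scaled age, sex, micro- and
macrovascular disease, comorbidity score, hospitalisation, log baseline
cost, claim and class counts, region/plan/specialty indicators, and baseline
drug-class flags. Perfect separation is detected per covariate and reported
by name. Matching is greedy nearest-neighbour without replacement on the
logit of the score, treated patients processed in descending score order
(ties by patient id), with a caliper of 0.2 SD of the logit score — the
conventional default, configurable — so the pair list is a deterministic
function of the data. Balance is reported as absolute standardized
differences ×100 (continuous: mean difference over the pooled-SD;
binary: the same with p(1−p) variances), alongside pre-match p-values
(chi-square for indicators, Welch t-test otherwise). Matching quality is
asserted as properties — post-match standardized differences below the
conventional threshold of 10 and strictly improved relative to pre-match —
because greedy matching output has no closed-form reference.

## Survival analysis

Time-to-modification is compared with the Kaplan-Meier product-limit
estimator, the two-group log-rank test, and a Cox proportional-hazards model
with the arm indicator as the single covariate (matching carries the
confounder adjustment; a matched-pair-stratified partial likelihood is
available by flag). The Cox fit is a Newton-Raphson maximum partial
likelihood with Breslow tie handling by default — day-granularity data tie
heavily — and Efron available by flag; convergence requires a score norm
below 1e-8 within 50 iterations, and a monotone likelihood (arms fully
separated in event order) is detected and reported rather than returning a
divergent estimate. The score test at β = 0 is exposed and must equal the
log-rank chi-square on tie-free data (the classical identity, used as a
cross-check); lifelines serves as an independent implementation check in the
test suite. Per-type analyses are cause-specific: competing modification
types censor at their own event day. Subdistribution (cumulative-incidence)
hazards are deliberately out of scope. Mean days-to-event are computed among
patients experiencing that event type only; censored times never enter
means.

## The synthetic-claims generator

The generator emulates the statistical structure the analysis assumes, with
every patient labelled by ground truth:

- **Confounded assignment.** Baseline covariates are drawn at realistic
  managed-care prevalences (mean age ≈ 56, comorbidity index ≈ 1.6, baseline
  glucose-lowering classes at oral-agent prevalences of roughly 71%/53%/52%
  for biguanides/sulfonylureas/thiazolidinediones). The arm is Bernoulli
  with logit linear in the propensity design; default weights channel older,
  sicker, hospitalised patients toward basal insulin and endocrinology
  patients toward the GLP-1 agonist, giving ≈ one-third insulin initiators.
- **Competing risks.** Each patient draws independent exponential latent
  times for discontinuation, switching, and intensification at arm-specific
  daily hazards; the minimum wins, censored at day 545. Default hazards are
  calibrated so the *realised* (claim-grid, post-relabelling) 18-month
  modification fractions land near 69% (GLP-1 arm: ≈ 38.6 / 14.9 / 15.6
  discontinuation/switch/intensification) and 76% (insulin arm: ≈ 40.7 /
  9.7 / 25.6) — the range reported for commercial-claims cohorts of these
  drugs. Constant hazards are a deliberate simplification: they reproduce
  18-month proportions, not the early-hazard concentration of real cohorts,
  so mean days-to-event run higher than observational reports.
- **Claim-grid realisation.** Refill chains step by `days_supply` (30 or 90,
  4:1 by default) plus a slack draw (truncated Poisson, mean 2, cap 14 days;
  the noiseless variant sets slack to zero). Ground truth is finalised on
  the claim grid with the classifier's own conventions: a discontinuation's
  truth day is the run-out of the last fill; a switch's the first fill of
  the replacement class (3–45 days after the gap opens, then refilled); an
  intensification's the add-on fill day inside covered index supply, or the
  escalated fill for the dose route. Latent events whose realisation cannot
  be observed inside the horizon (e.g. a gap opening after day 455) are
  relabelled persistent, so emitted truth is exactly what a correct
  classifier can recover — the round-trip identity that makes recall a
  meaningful validation target rather than a noise measurement.
- **Dose titration.** Basal-insulin units per fill encode a daily dose
  starting near 25 IU/day with mild upward titration (≤1.2× per refill,
  capped at 60 IU/day); a dose-route intensification applies a single 3×
  jump. With slack capped at 14 days, the estimated-dose ratio of a true
  jump is provably ≥ 2.05 and of ordinary titration ≤ 1.76, so the 2.0
  threshold separates them under refill noise by construction.
- **Background therapy** (baseline classes) continues post-index until the
  truth event day — discontinuers stop everything, because a background drug
  continued into the gap would, under the definitions, turn the course into
  a switch and make the ground-truth taxonomy ill-posed.
- **Exclusion triggers** (diagnosis flags, double glucocorticoid fills,
  washout-drug fills, enrollment gaps, benefit lapses, insurer transitions,
  minors) are injected into configured fractions of patients to exercise
  the selection funnel. Washout-drug triggers use non-index classes only: a
  pre-index fill of an index drug inside the index window would itself
  become the index event. The exclusion rules for index drugs are unit
  tested with hand-built claims instead.

What the generator does *not* emulate: real diagnosis/drug code systems,
duration-dependent or seasonal hazards, dose-dependent behaviour, partial
adherence (fills not taken), or informative censoring. Passing round-trip
validation therefore demonstrates that the rule engine implements the
definitions correctly, not that the definitions capture real-world
behaviour.

Byte-level reproducibility: a `(config, seed)` pair fully determines every
output file; the claim emitter uses a seed offset (`seed + 1000003`) so
population generation and emission are independently reproducible.

## Problem sizes and test design

Validation sizes were chosen as the smallest that make each check sharp:
oracle-equivalence grids of a few thousand constructed patients plus
seeded fuzz; ground-truth recovery at n = 2,000 per configuration; log-rank
null calibration with 2,000 simulations of n = 200 (rejection rate asserted
within [0.03, 0.07] at α = 0.05); Cox coverage with 20 replicates of
3,774 patients per arm at hazard ratios {0.71, 1.0, 1.33, 1.72} (≥90% CI
coverage); propensity-coefficient recovery within 3 SE at n = 10,000 across
five seeds; and the end-to-end pipeline at n = 6,000 in the acceptance
script. The matched-set size (≈1,700 pairs at n = 6,000) scales the
confidence intervals accordingly.

## Known limitations

- Greedy matching is order-dependent by design (deterministic, but not
  optimal matching); optimal/full matching and weighting estimators are out
  of scope.
- The per-type hazard ratios are cause-specific, not subdistribution
  hazards; they answer "rate among those still unmodified", not "cumulative
  probability" questions.
- The classifier reports first events only; second and later modifications
  are out of scope.
- Adherence metrics (proportion of days covered, medication possession
  ratio) are not computed.
- With real claims extracts truncated exactly at day 545, switch and
  intensification confirmations near the horizon are partially unobservable;
  the package then errs toward censoring (the non-committal outcome).
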