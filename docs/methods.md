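# Methods

This note records the models, rules, and design choices behind `copdce`:
what the pipeline computes, what the synthetic-claims generator does and
does not emulate, and where genuinely open design questions were settled.

## Data model

Claims live in four linked tables (patients, enrollment spans, medical
claims with up to five ordered ICD-9-CM diagnosis slots, pharmacy claims
with drug class and days supply). Dates are integer day indices against an
arbitrary epoch; the calendar intake window is a configurable
`[intake_start, intake_end]` pair (defaults 400–1130, a ~3-year window
that leaves room for a one-year look-back). Age is derived as
`epoch_year + index_date // 365 - birth_year` (default `epoch_year`
2006); the generator constructs birth years by the same convention, so
ages round-trip exactly. Diagnosis matching is prefix-based and
period-insensitive; drug exposure is modeled at the class level (BFC, FSC,
other ICS/LABA combinations, and the supporting respiratory and OCS /
antibiotic classes), not at the NDC level.

## Cohort construction

The index date is the first BFC or FSC fill inside the intake window;
patients whose first fills of both drugs share that date are dual
initiators and excluded. Eligibility is conjunctive: new-user rule (no
ICS/LABA *combination* fill in [index−365, index−1]; ICS or LABA
monotherapy does not disqualify, since the emulated population shows
nonzero prior monotherapy use), age ≥ 40 at index, day-level continuous
medical+pharmacy enrollment over [index−365, index+365] (an
allowable-gap parameter defaults to 0), the COPD diagnosis pathway, no
pre-index cancer diagnosis (configurable stem set, default ICD-9
140–208), and < 180 total days of pre-index OCS supply. The attrition
table removes sequentially in a fixed documented order; eligibility itself
is order-independent. The pre-index window is [index−365, index−1]: the
index day belongs to follow-up, so index-day fills never count as prior
exposure. The "two other medical claims" pathway requires distinct service
dates by default (configurable), and pre-index covariates are computed
strictly from pre-index claims — shifting all post-index claims leaves
every covariate unchanged (tested).

Pre-index exacerbation counts reuse the same candidate/attribution/merge
machinery as the outcome, restricted to pre-index claims. The index
prescriber's specialty is proxied by the most recent pre-index medical
claim's provider specialty; `index_month` is the index date's 30-day
bucket within the year (a seasonality proxy under day-index dates).

## Exacerbation adjudication

Candidates: inpatient stays with *primary* COPD diagnosis (onset =
admission date); ED visits with COPD in *any* position (onset = service
date); and office/outpatient visits with COPD in any position paired with
an OCS or antibiotic fill 0–10 days after the visit (onset = visit date —
the visit anchors the encounter). Attribution then drops (i) ED visits
whose service date falls inside any inpatient candidate's
admission–discharge interval (transfer linkage does not exist in claims),
(ii) outpatient candidates whose *fill* lies within 14 days (absolute
gap; "within 14 days of" is symmetric) of a severe candidate's onset, and
(iii) duplicate fills for the same visit. Surviving candidates within 14
days of each other merge into one event. Merging is anchored at the
cluster's first onset — a candidate joins iff it is ≤ 14 days after the
anchor — because chained merging lets clusters grow without bound; a
chained variant exists behind `chained=True`. A merged event keeps the
anchor onset and the most severe member's type (inpatient > ED >
outpatient-Rx), so by-type rates partition the overall rate.

Follow-up variants: `fixed_12mo` (person-time exactly 1.0 year),
`censor_at_switch` (end at the first post-index fill of an ICS/LABA
combination class different from the index drug; same-class refills never
censor; events strictly before the switch date count, person-time =
(switch − index)/365), `all_available` (end of the continuous enrollment
run containing the index, capped by a study-end date), and `severe_only`
(inpatient/ED events only, fixed window). Length of stay is
`max(1, discharge − admission)` (same-day admission and discharge count as
one day); a "long stay" is LOS > 5. PDC is `min(1, Σ days_supply / 365)`
over post-index fills of the index drug — days supply is summed literally
and overlapping fills are not shifted forward, favoring fidelity to the
stated formula over the stockpiling convention.

## Propensity scores, matching, balance

The propensity score is the probability of receiving BFC from a
`RandomForestClassifier` over the pre-specified and optional covariates
(categoricals one-hot encoded). Out-of-bag probabilities are used to avoid
in-bag overfitting and are clipped to [1/(2N), 1−1/(2N)]. Defaults:
500 trees, `min_samples_leaf` 25 — the larger leaf and tree count matter
because out-of-bag *sampling* noise in the score attenuates how much
confounding the match removes, while smooth estimation error (a function
of the covariates) does not harm balance.

Matching is greedy nearest-neighbor 1:1 without replacement on the logit
of the score, processing BFC patients in a seeded random order, with a
caliper of 0.2 SD of the logit scores by default; distance ties between
the nearest lower and higher score (within 1e−12 relative) go to the
lower patient id. The paper trail for balance is a per-variable table
with pre/post means, pooled-variance t-tests (continuous), chi-square
tests without continuity correction (categorical; balance SMD for a
multi-level variable is the largest level-wise SMD), and standardized
mean differences; a variable is balanced when p > 0.05, and a
zero-variance variable is reported balanced with p = 1. A single match is
performed and reported — matching is not iterated until balance.
Variables unbalanced after matching become covariates in *all* outcome
models, together with the analogous pre-index variable for each outcome
(e.g., pre-index exacerbation count for the exacerbation rate model).

## Outcome models

The primary model is a negative-binomial (NB2) GLM with log link for
event counts with a log person-time offset; dispersion is estimated by
maximum likelihood jointly with the coefficients (a fixed-α GLM and a
Poisson limit are available; the Poisson fallback engages if the NB
likelihood degenerates). The rate ratio is the exponentiated arm
coefficient with a Wald 95% CI on the log scale; adjusted per-arm rates
use marginal standardization (average predicted rate with every patient
assigned to each arm in turn) rather than prediction at covariate means.
Time-to-first-event uses Cox proportional hazards (Efron ties, via
lifelines) with Kaplan–Meier curves; binary outcomes use logistic
regression; the index-fill distribution (1/2/3/4+) uses proportional-odds
ordinal logistic regression (the proportional-odds assumption is not
tested, and this is recorded in the fit metadata); PDC uses normal linear
regression. Matched-pair correlation is ignored in the standard errors —
patients are treated as independent, the conventional approach for
propensity-matched claims analyses, and conservative here because matched
pairs are positively correlated. No multiple-testing adjustment is made.
All analyses are intent-to-treat; the censor-at-switch variant is the
per-protocol flavor.

The sample-size routine for two NB rates uses the log-rate-ratio Wald
variance with per-arm contribution 1/(μt) + k:
n = ⌈(z₁₋α/₂+z₁₋β)²[(1/(μ₀t)+k)+(1/(μ₁t)+k)]/ln²(μ₁/μ₀)⌉. Under the
study defaults (μ₀ = 0.5/person-year, 20% reduction, α = 0.05, power
0.90, k = 1.2, t = 1) it evaluates to 1456.05 → 1457 per group, and to
950 in the Poisson limit k = 0. The "dispersion effect" is interpreted
throughout as the NB2 dispersion (variance μ + kμ²).

## Synthetic claims generator

The generator's defaults define the study conditions and are calibrated
to the emulated managed-care COPD population: age ~ integer-truncated
normal(64, 11.5) on [40, 95); 53% female; 35% prior asthma; 23% prior
pneumonia; BFC share 0.37 (intercept solved numerically each run);
FSC-arm exacerbation rate 0.86/person-year with true rate ratio 1.0 by
default and gamma-frailty NB2 dispersion 1.2; event types 7%
hospitalization / 15% ED / 78% outpatient-Rx; 18% annual pneumonia
probability (placed 45/5/50 across inpatient/ED/outpatient); index-fill
process with 33% single-fill patients and a shifted-geometric refill count
with mean 3.9 (capped at 13), 30-day supplies at 30-day intervals, which
implies the generator's exact PDC mean (≈ 0.32) by enumeration; 15%
switch probability; and a 0 dropout hazard (fixed 12-month design), with
enrollment extending ~1 year beyond follow-up on average.

A latent severity factor z ~ N(0,1) is the backbone of the pre-index
history: prior exacerbation counts are Poisson with a unit-mean lognormal
frailty in z (variance 0.4, matching the emulated population's prior-count
dispersion), and every standalone pre-index fill class is Poisson with a
class-specific lognormal frailty in the same z (variances 0.5–6,
reproducing the heavy overdispersion and mutual correlation of claims fill
counts). Asthma patients fill asthma-typical classes (SABA, ICS, LTRA)
more often, giving asthma a medication signature. Treatment assignment is
a logistic model in severity, age, sex, asthma, prior exacerbations, and
prior pneumonia; the default coefficients sit at the modest end of the
emulated population's pre-matching arm differences (age about −0.9 y,
asthma about +3 pp, severity channeling shifting every prior-use covariate
at once). The outcome log-rate depends on age, sex, asthma, prior
exacerbation count, and prior pneumonia, with the intercept normalized in
sample so the FSC-arm marginal rate equals its configured value exactly.
Severity affects outcomes only through the measured history, so matching
plus the residual-imbalance covariate policy can remove the confounding —
by design the *unadjusted* rate ratio under a true null is biased away
from 1 (the generator records the margin it must exceed,
`crude_rr_margin` = 1.02).

Ground-truth stability is engineered, not hoped for: intended onsets are
re-spaced ≥ 15 days apart (uniform draws plus rank offsets), inpatient
stays are 1–14 days so they end before the next event, outpatient fill
offsets are drawn from [0, min(10, gap-to-next-severe − 15)], and
pre-index events stay in [index−350, index−15]. Consequently no
attribution or merge rule ever fires on intended events, and the
adjudicated stream equals the intended one exactly. Stray post-index
OCS/antibiotic fills (concomitant medication use) are safe by
construction: a stray fill pairing with an intended visit is deduplicated
per visit, and one pairing with a planted decoy visit necessarily lies
within 14 days of that decoy's severe onset and is absorbed. The noise
toggles plant same-day ED+admission pairs (removed by the ED-collapse
rule), decoy office-visit+fill bundles near severe events (absorbed by the
14-day rule), and duplicate fills (deduplicated) — so adjudication must
reproduce ground truth exactly with noise on as well. Decoy ineligible
patients (default 8%, cycling through the six exclusion reasons) violate
exactly one criterion each, so recovered exclusion reasons can be compared
to planted ones. Eligible patients are guaranteed two routine pre-index
COPD office visits on distinct dates (the "two other claims" pathway) and
their pre-index OCS supply is capped far below the 180-day threshold.

Problem sizes used by the test suite are the package's own choices: the
matched-recovery studies run 50 replicates of ~5,600 patients (≈ 2,000
matched pairs) for the null (true RR 1.0) and effect (true RR 0.8)
scenarios with 150-tree forests; balance is assessed on 20 seeds of 8,000
patients with 500-tree forests; calibration uses one 50,000-patient run
compared against the generator's exact implied marginals within 3
Monte-Carlo standard errors.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real claims: coding error and diagnosis
miscoding (every COPD/pneumonia code is truthful; the known ~80% positive
predictive value of claims pneumonia coding is out of scope), unmeasured
confounding (severity is fully expressed in measured history, so matching
can succeed; in real data it cannot be verified), calendar seasonality and
secular trends, costs and payer structure, telephone prescriptions and
inpatient-administered drugs (absent from claims in reality as well), and
post-12-month outcome events — the all-available-follow-up variant
therefore exercises windowing and person-time logic, not late-event
dynamics (its event *rate* dilutes mechanically with added event-free
time). Intended-event counts are capped at the number of ≥15-day slots in
the window (23), a negligible truncation at the default rates.

## Numerical choices and degenerate inputs

NB fits use BFGS with a Poisson fallback on degeneracy; Wald intervals
exponentiate with overflow guarded to infinity (perfect separation in a
logistic fit is flagged in metadata rather than raised). The random-forest
scores are deterministic given the seed; matching processes BFC patients
in a seeded permutation; every pipeline stage is a pure function of
(config, seed), and the run manifest records seeds and a config hash so
identical configs produce identical bundles. Degenerate cases: an
all-zero-count arm flags the rate ratio; a single-category ordinal outcome
returns a flagged, non-converged estimate; zero-variance balance variables
report p = 1; an empty match result is allowed.

## Known limitations

Greedy matching on a noisy forest score removes most but not all
systematic imbalance (~25–35% of an initial standardized difference
survives in these conditions); with genuinely confounded covariates that
are weakly correlated with the score, occasional post-match p-values below
0.05 are expected across seeds, which is why unbalanced variables are
forwarded into the outcome models rather than assumed away. The ordinal
model does not test proportional odds. Cluster-robust standard errors for
matched pairs exist behind the model layer but are off by default,
mirroring conventional practice.
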