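# Methods

`rxpersist` implements a claims-database analysis of persistence and
adherence to a newly initiated drug class — here sodium-glucose
co-transporter 2 inhibitors (SGLT2i, ATC prefix `A10P`) started as
monotherapy by type-2-diabetes patients — together with a synthetic claims
generator that provides a known ground truth for validating every stage.
This note records the models, conventions, parameter choices and known
limitations.

## Data model and date conventions

Four flat tables (enrollment, prescriptions, diagnoses, outpatient-visit
claims) emulate a Japanese employment-based insurance extract. Fields that
such databases store at month resolution (birthday, enrollment window,
visit dates) are six-digit `YYYYMM` strings and are imputed to **day 15**
of the month; eight-digit dates parse literally. All window arithmetic is
in integer days over half-open `[start, end)` intervals. Days of supply is
constrained to 1–90 days (the permitted dispensing range in Japan), and
enrollment must end before a beneficiary's 75th birthday, when coverage
moves to the late-elderly system.

## Cohort construction

A *new user* has a first SGLT2i fill (the index date) preceded by a
180-day washout with no antidiabetic fill (any `A10` code) and enrollment
spanning `[index − 180, index + 365)`. Only the first SGLT2i fill is ever
considered as an index event, so patients who stop and restart cannot
re-enter the cohort. Candidates then pass an ordered, labelled exclusion
cascade — missing prescription date (data-quality guard, normally zero),
a single SGLT2i fill in follow-up, a second antidiabetic agent dispensed
on the index date, a fixed-dose-combination SGLT2i product at index, and
fewer than two pre-index outpatient visits — with every stage recorded in
a flow-count table whose conservation is enforced (`n_remaining` at each
stage equals the previous remainder minus that stage's exclusions). The
*set* of excluded patients is order-invariant; the per-stage counts follow
the order above. "Combination at index" is read literally as a same-day
non-SGLT2i antidiabetic fill; no look-ahead window is applied. Fractional
age at index uses the day-15-imputed birth date divided by 365.25.

## Persistence and adherence

**Discontinuation** is gap-based: scanning consecutive SGLT2i fill dates,
the first pair whose date-to-date gap strictly exceeds the permissible gap
(90 days primary, 30 days sensitivity; a gap of exactly the limit is
tolerated) dates an event at `min(previous fill + its supply, day 365)`.
A trailing gap — no further fill with more than the permissible gap left
before day 365 — is treated the same way; the internal count summaries of
the source setting (restart counts, person-year incidence and mean
follow-up) are mutually consistent only under this reading. The first fill
of any other antidiabetic agent after index ends monotherapy persistence
at that fill's date ("switch"). The earliest event wins; a tie is
attributed to the gap. Event-free patients are censored persistent at day
365. **Restart** is evaluated only after gap events (a switcher is still
on antidiabetic therapy; a flag reverses this) and requires an SGLT2i fill
strictly after the event day and before day 365.

**Adherence** is the proportion of days covered: the union of half-open
supply intervals clipped to the fixed 365-day window, overlapping supply
counted once, with no stockpiling shift and no regard for gap events.
`PDC >= 0.80` defines adherent. Because 0.8 × 365 = 292 exactly, the
threshold is exact in integer days.

Per-patient persistence under the 90-day policy dominates the 30-day
policy whenever days of supply is constant within patient (the generator's
regime). With supply varying across fills a literal reading of the
event-day rule admits rare counterexamples (an early overlapping refill of
a long supply followed by a long gap), which is why the monotonicity
guarantee is stated over the simulated cohorts rather than over arbitrary
fill sequences.

## Covariates

Everything except calendar year, age and sex is ascertained in
`[index − 180, index)`, with suspected-diagnosis flags excluded.
Comorbidity flags use ICD-10 prefixes — hypertension I10, dyslipidemia
E78, depression F32/F33, obesity E66, hyperuricemia E790, diabetic
nephropathy E112/E142/N083/N189. (Published tabulations for this setting
pair hypertension with E78 and dyslipidemia with I10; that pairing is
lexically transposed relative to ICD-10 semantics, so the default map uses
the conventional assignment and remains config-overridable.) Concomitant
drug burden counts distinct classes among RAS agents C09, beta blockers
C07, calcium-channel blockers C08, diuretics C03 and lipid-lowering agents
C10, compound products counting toward each matching class. The Charlson
comorbidity index uses the Quan-2005 ICD-10 category mapping with the
original 17-category weights and severity hierarchies (complicated
diabetes over uncomplicated, severe liver over mild, metastatic over
non-metastatic); bare three-character diabetes codes score as
uncomplicated. Visit counts keep same-day duplicate claims (each claim is
one visit); the mean inter-visit interval is `(last − first)/(n_distinct −
1)` over distinct dates and is defined as 0.0 in the degenerate case where
month-imputation collapses all visits onto one date.

## Statistical layer

Kaplan–Meier persistence uses the product-limit estimator (lifelines)
with censoring only at day 365; with no interior censoring it coincides
with the empirical survival function, which the tests assert. Incidence is
events per 1000 person-years with person-time from per-patient persistence
days. Odds ratios come from maximum-likelihood logistic fits
(statsmodels): *crude* = one single-covariate model per variable (equal to
the 2×2 cross-product ratio for a binary covariate), *adjusted* = all
covariates jointly; both report Wald 95% CIs (the common choice in claims
studies; profile-likelihood is not offered). Separation or non-convergence
yields a per-covariate failure note, never a crash. Multicollinearity is
screened with variance inflation factors (flag at VIF > 10, configurable;
constant columns reported as degenerate). The additional analyses are
ordinary least squares of PDC and of persistence days on age and on the
mean visit interval. Significance is two-sided at 0.05.

## Synthetic generator

The generator emulates the study conditions: observation window 2017-10
to 2020-09, index dates spanning calendar years 2018–2019, age ~
N(51.9, 9.1) truncated to 20.5–73.9, 73.4% male, comorbidity prevalences
{hypertension 0.611, dyslipidemia 0.651, depression 0.085, obesity 0.057,
hyperuricemia 0.214, nephropathy 0.078}, concomitant-class prevalences
{C09 0.448, C07 0.129, C08 0.299, C03 0.094, C10 0.483}, days-of-supply
mix {14: 0.20, 30: 0.73, 60: 0.05, 90: 0.02} (median 30), and ~6.2
pre-index visits per patient at month resolution.

**Outcome model.** Non-persistence over the year is drawn per patient from
a logistic model, `logit P = logit(p0) + Σ β_k (x_k − center_k)`, with
`p0 = 1 − (1 − h)^365` from the baseline per-day hazard `h` and planted
log-odds `β` on centred covariates (defaults equal to the study's adjusted
estimates: hypertension −0.33, dyslipidemia −0.31, hyperuricemia −0.28,
age −0.033 per year). Given non-persistence, the stop day is a truncated
geometric with hazard `h` over the span in which a trailing 90-day gap
remains observable, and the patient either abandons refills (gap mode;
restarting later with probability 0.454) or starts a second antidiabetic
agent (switch mode, probability 0.08). Planting effects on the binary
outcome scale keeps the planted log-odds identifiable by the downstream
logistic analysis — under a pure proportional-hazards planting the
one-year log-odds would differ from the planted coefficient by ~0.07 at
these event fractions, which no correct analysis could recover — while
the per-day hazard still drives event timing for the survival stage.
`h = 0.00147`/day was derived analytically so that cohort persistence
lands near the observed 61% after the single-prescription exclusion
removes early discontinuers.

**Refills** are on time or early (half-normal jitter, SD 3 days, floored
at supply − 5 so a refill never precedes the prior fill), exercising the
overlap rule; a rare missed refill (p = 0.005 per fill) adds a 10–55-day
delay that can breach a 30-day gap but — with intervals capped at 90 days
— never the primary 90-day gap. Exclusion branches (prior antidiabetic
use, short enrollment, same-day combination, fixed-dose combination,
single fill, under two visits) are planted at fixed fractions so every
funnel stage is exercised.

**What the generator does not emulate:** correlated comorbidity,
seasonality, dose changes, switching between SGLT2i products, inpatient
episodes, mortality or disenrollment during follow-up, and fee-schedule
detail. Passing tests therefore demonstrate correctness of the measurement
pipeline under a known truth, not fidelity of any particular rate to real
claims data.

## Problem sizes and numerical choices

The validation suite uses a shared population of 5,000 simulated patients
(≈2,600 cohort members) for oracle-equivalence, monotonicity and
invariant checks; planted-effect recovery uses 100 replicate populations
of 5,000 patients and asserts ≥90% empirical coverage of the planted
adjusted odds ratio; the acceptance script runs a 20,000-patient
population (≈10,000 cohort members). Day coverage is computed exactly in
integer days; percentages render half-up at one decimal; all randomness
flows through a single seeded NumPy generator, making every population and
pipeline run bit-reproducible.

## Known limitations

Restart classification follows the literal fill-after-event-day rule, so
under the 30-day policy an early overlapping refill inside a flagged gap
does not count as a restart. The crude odds ratios published for this
study design are not always reproducible as cross-product ratios of the
printed contingency cells; this package defines crude as the univariate
logistic fit and leaves any unstated weighting undocumented. HbA1c, BMI,
diabetes duration and self-reported adherence scores are out of scope (not
present in the emulated source).
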