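# Methods

This note documents the model implemented by `acosim`: its assumptions, the
parameters that matter, the design choices made where the design was genuinely
open, and what the synthetic inputs do and do not represent.

## Time conventions

The patient state-transition model advances in **15-day cycles**, chosen so that
30-day readmissions are resolvable.  A simulation year is **24 cycles
(360 days)**; every annualization in the package (visit rates, survival-curve
knots, intervention effect windows) uses this convention consistently, so that
"one year" is always exactly 24 cycles and annual quantities compose exactly
from per-cycle quantities.  Survival-curve knots at "1 year" and "5 years" are
therefore placed at 360 and 1,800 days.

## Patient agents

### Characteristics and the synthetic population

Each patient carries four demographic variables (age group 1–5 over the bands
65–69, 70–74, 75–79, 80–84, 85+; race; gender; income band) and three chronic
conditions (diabetes, hypertension, CHF), sampled by a conditional chain:
demographics, then diabetes given demographics, then hypertension given
diabetes and demographics, then CHF given all.  Chronic conditions are
incurable: flags never revert.

The default fixture (`synthetic-v1`) is **explicitly synthetic**.  Its
demographic table is the product of four documented marginals (independence
across demographic variables is a simplification), and its comorbidity
conditionals are additive in documented age/race/comorbidity shifts, giving
overall prevalences of roughly 24% diabetes, 60% hypertension and 13% CHF —
plausible for Medicare beneficiaries but **not calibrated to any survey
microdata**.  Consequences for interpretation:

* absolute outcome levels (admission rates, mortality, dollar totals) depend on
  this fixture and are not claims about the US Medicare population;
* comparative results (ACO vs controlled network, trends across payment
  parameters) are the meaningful outputs, and the test suite asserts them as
  properties — sign tests, rank trends, conservation identities — rather than
  point values.

Income is sampled and carried but has no effect on transitions by default (no
credible effect size was available to encode); the conditional tables are fully
user-replaceable for anyone wishing to add one.  Patients age one year at each
year boundary, updating their age group.

### State transitions

States: CHF-free, CHF on-site (diagnosed, in the community), CHF-related
hospitalization, dead (absorbing; the agent is removed).  Per cycle, one
categorical draw moves the patient:

* **CHF-free** — background mortality from a stylized life table (per-cycle
  probabilities by age group and gender); CHF onset at a risk-adjusted per-cycle
  probability (baseline 4.19 × 10⁻⁴, equivalent to ~1%/year for the youngest
  group, multiplied by age-group factors 1.0–3.5, ×1.5 for diabetes, ×1.8 for
  hypertension).  A configurable share (default 0.5) of onsets is diagnosed in
  the inpatient setting and enters through a hospitalization.
* **CHF on-site** — hospitalization at the per-cycle probability by age group
  (0.01663 for 65–74, 0.02360 for 75–84, 0.03489 for 85+), reduced by the
  intervention effect; mortality from the survival-curve hazard (below).
* **Hospitalization** — a one-cycle state: the patient is discharged back to
  CHF on-site at the next cycle unless they die.  A 30-day readmission is a new
  admission within two cycles of discharge.

Diabetes and hypertension incidence are side-processes (per-cycle draws for
patients lacking the condition; hypertension incidence varies by race); they
affect CHF onset risk through the multipliers above.

### CHF mortality

CHF patients' mortality comes from all-cause survival curves keyed to the
diagnosis setting: S(30 d, 1 y, 5 y) = 0.98 / 0.87 / 0.49 for outpatient-
diagnosed and 0.84 / 0.66 / 0.33 for inpatient-diagnosed patients.  Each curve
is converted to per-cycle probabilities by **piecewise-exponential
interpolation**: within a knot interval the hazard is constant,
λᵢ = −ln(Sᵢ₊₁/Sᵢ)/(tᵢ₊₁−tᵢ), and the per-cycle probability is 1−exp(−15λᵢ).
Composition over cycles reproduces the knots exactly (to floating-point
precision); beyond the last knot the final hazard continues.  Because these
curves are all-cause for CHF patients, they **replace** background mortality by
default (an additive mode exists for users who prefer curves interpreted as
cause-specific).  Prevalent (initially CHF) patients start their
time-since-onset clock at simulation entry, since their true onset date is
unknown.

### Utilization

Regular outpatient visits are a Poisson process at 9 visits/year (per-cycle
mean 9/24 = 0.375); patients spending a cycle in hospital generate none.  When
a patient's PCP conducts the intervention, one deterministic follow-up visit
occurs in the cycle after each discharge.  Only CHF-related utilization is
modeled; non-CHF hospitalizations are out of scope.

## The intervention and its effects

The intervention is comprehensive discharge planning with post-discharge
follow-up.  At full effect it reduces the CHF hospitalization probability by
**20%** and CHF mortality by **13%** (relative reductions).  Full effect
requires both the admitting hospital and the patient's PCP to conduct it; a
single intervening party achieves a configurable partial fraction φ (default
0.5) of both reductions; neither, none.

Effects are **status-based**: during any cycle, a patient's risk reductions are
determined by the current behaviors of their home hospital and their PCP.
Since behavior is an annual decision, an adopted intervention's effect lasts
exactly the behavior year.  An intervening provider enrolls its entire CHF
panel, paying the per-patient-year intervention cost for each ($648/patient-
year for hospitals — $108/month pooled cost over a 6-month program amortized
across the 1-year effect window, i.e. $54/month; $69/patient-year for PCPs —
the opportunity cost of one standard visit slot).

## Provider agents and the TPB decision

Each network has 3 hospital and 15 PCP agents.  Controlled-network agents
always provide usual care.  ACO agents decide annually via the Theory of
Planned Behavior; the three stylized types weight profit vs quality in the
attitude as β = (0.8, 0.2) (profit-oriented), (0.2, 0.8) (quality-oriented) and
(0.5, 0.5) (neutral).

Where the behavioral theory leaves functional forms open, the package makes
these choices (all pluggable through configuration):

* **Profit utility** `U_p`: logistic in per-own-CHF-patient profit with a $500
  scale — losses map below 0.5, gains above, saturating smoothly.
* **Quality utility** `U_q`: the admission rate (per CHF patient-year) and
  mortality rate are averaged into an adverse-event index mapped linearly from
  configurable reference bounds (default [0, 1], inverted) — lower rates, higher
  utility.
* **Subjective norm** `U_sn`: the proportion of received messages supporting
  each behavior; 0.5 for both when no messages arrived.  Each agent sends one
  message per cycle (24/year) to a uniformly random other ACO provider,
  supporting whichever behavior its latest attitude favors.
* **Perceived behavioral control**: `PBC¹ = ni/ti` over the year's discharge
  interactions (both parties log every ACO discharge; `ni` counts those whose
  counterpart was intervening).  With no interactions the previous year's value
  carries forward (initially 0.5).  `PBC⁰ ≡ 1`: not intervening needs no
  collaboration.
* **Intention**: an equal-weight convex combination of attitude, norm and
  control (weights configurable).
* **Choice**: softmax over the two intentions with irrationality τ; the default
  τ = 0 is the rational arg-max with ties broken toward usual care.

### Expected profit and quality

The expectation estimator is deliberately simple and myopic.  For behavior
k = 0, expected profit is the prior year's realized service profit per own CHF
patient (admission margins for hospitals, visit margins for PCPs — excluding
intervention costs and shared-saving receipts).  For k = 1 the agent:

* subtracts the per-patient-year intervention cost;
* adds the shared-saving share it would receive **if the network-wide
  intervention succeeds**: the avoided hospitalization spending implied by the
  full risk reduction applied to the observed admission rate, times SSR, times
  the agent's equal within-type share (SRH/3 for a hospital,
  (1−SRH)/15 for a PCP);
* (hospitals) adds the margin effect of avoided admissions, since Medicare CHF
  admissions carry a negative margin (−$1,186 each).

The naive "full-attribution" saving forecast — rather than the game-theoretic
marginal contribution of one agent's adoption — is a deliberate design choice:
because the shared saving is distributed equally within provider type
regardless of individual behavior, a strictly rational marginal calculation
dilutes each agent's incentive by the roster size and payment parameters would
barely influence behavior.  Real providers deciding whether to join a
collaborative program reason about the program's headline returns; the naive
framing reproduces the intended sensitivity of adoption to SSR and SRH.

Expected quality under k = 1 applies the known 20%/13% reductions to the prior
year's own-panel rates.

### Cold start

All ACO agents provide usual care in year 1, with uninformative priors
(A = SN = 0.5, PBC¹ = 0.5).  Adoption therefore emerges endogenously: attitudes
update after year 1, messages then propagate pro-intervention sentiment, and
interaction-based control rises as counterparts adopt.  In practice adoption
begins in year 2 at the earliest and can cascade or stall depending on the
payment parameters — the cascade (or its absence) is part of what the model is
for.

## Payer and payment

Fee-for-service flows per event (USD 2011): a CHF admission costs the payer
$14,822 (hospital service) + $2,668 (inpatient physician fee, 18% of the
hospital reimbursement, paid to unmodeled inpatient physicians); the hospital's
net margin per admission is −$1,186 (Table values are authoritative; the
package does not re-derive the margin).  An outpatient visit costs the payer
$85, of which the PCP nets $34 after a 60% operating-cost share.

At each year end the CHF-related payer cost per CHF patient (admissions plus
CHF patients' visits) is computed for both networks.  "CHF patient" for the
settlement means any patient with CHF at any point during the year, including
those who died.  The saving per CHF patient is the controlled-minus-ACO
difference **floored at zero**; SSR of the total saving is distributed (SRH to
hospitals, equally; the rest to PCPs, equally) and the payer retains
SSP = (1−SSR) × saving.  The reported ACO payment per CHF patient includes the
distributed shared saving; the settlement itself is computed on service costs
only.  The floor introduces a small-sample positive bias in mean savings (the
expectation of a floored noisy difference is positive even under the null);
this shrinks with cohort size and is why network-equivalence tests compare
rates, not savings.

## Run configuration and outputs

Defaults: 10,000 patients split between the networks by independent fair coin
(an exact stratified split is available for variance reduction), 5 years,
3 hospitals + 15 PCPs per network, 500 replications (library default; the
experiment drivers default to 50 and the bundled tests and acceptance script
use 1,000–4,000-patient cohorts with 10–100 replications so the full suite runs
in minutes on one CPU — the model's behavior at these sizes is qualitatively
identical, with wider confidence intervals).

Because the annual hospitalization "rate" is ambiguous between admissions per
CHF patient-year and the share of CHF patients with ≥1 admission, **both** are
computed and reported (`admissions_per_chf_py`, `admission_share`).
Replication summaries report the mean and a normal-approximation 95% CI
(mean ± 1.96 sd/√n); a percentile bootstrap is available.  Dead patients are
not replaced.  Runs are deterministic given (config, seed), with independent
named RNG streams for population, disease and behavior.

## Numerical and degenerate-input choices

* Transition vectors are exact probabilities summing to 1; hazards are small
  enough under all shipped parameterizations that no renormalization is needed
  (validation rejects out-of-range inputs).
* Cash flows are kept at full floating precision; only schedule-derived
  integers (physician fee, PCP visit net) are rounded to whole dollars.
* If a network has no CHF patients in a year (possible only in toy-sized
  cohorts), the settlement is skipped and per-patient quantities are reported
  as missing rather than dividing by zero.
* Softmax ties at τ = 0 resolve to usual care; the softmax subtracts the
  maximum intention before exponentiating for numerical stability.
* Survival-curve validation requires knots on cycle boundaries, a start at
  (0, 1.0), and monotone non-increase.

## Known limitations

* The population fixture is synthetic; absolute levels are illustrative.
* Intervention receipt is modeled at the provider-panel level (status-based);
  patient-level receipt tracking (e.g. only post-discharge enrollment) would
  lower effective coverage and costs together.
* The TPB weights, utility scales and message schedule are not estimated from
  provider surveys; they are documented defaults intended for scenario
  exploration, and conclusions should be tested for robustness across them.
* Quality plays no role in the settlement (no quality-gated savings as in the
  CMS Shared Savings Program), and only CHF-related utilization is costed.
* The shared-saving benchmark is a contemporaneous controlled network, not a
  historical or risk-adjusted benchmark.
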