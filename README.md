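# acosim

An agent-based simulator of accountable care organization (ACO) demonstrations
for congestive heart failure (CHF) care.  It is aimed at health-policy and
health-services researchers who want to explore, before running a costly pilot,
how a shared-saving payment design interacts with provider incentives and
chronic-disease dynamics.

CHF is the leading cause of hospitalization among Medicare patients, and
comprehensive discharge planning with post-discharge follow-up is known to
reduce CHF readmissions and mortality — but only if hospitals and primary-care
physicians (PCPs) choose to invest in it.  The simulator couples three agent
types:

* **Patient agents** — Medicare beneficiaries (65+) characterized by age, race,
  gender, income, diabetes, hypertension and CHF status, progressing through a
  discrete-time state model (CHF-free → CHF on-site → CHF-related
  hospitalization → death) on 15-day cycles.  CHF mortality follows
  piecewise-exponential hazards fitted to survival curves that differ by
  diagnosis setting (outpatient vs inpatient); outpatient visits are a Poisson
  process (9/year).
* **Provider agents** — 3 hospitals and 15 PCP clinics per network.  Each year
  an ACO provider decides whether to conduct the CHF intervention using the
  Theory of Planned Behavior: intention `I^k` toward behavior `k ∈ {0, 1}`
  combines attitude `A^k = β₁·U_p(EP^k) + β₂·U_q(EQ^k)` (expected profit and
  quality, weighted by the provider's priorities β), subjective norm
  `SN^k = U_sn(nm^k)` (supportive peer messages), and perceived behavioral
  control `PBC¹ = ni/ti` (the fraction of discharge interactions whose
  counterpart was observed intervening; `PBC⁰ ≡ 1`).  Behavior is drawn from a
  softmax `P¹ = exp(I¹/τ) / (exp(I⁰/τ) + exp(I¹/τ))`; the default `τ → 0` is
  the rational arg-max.  The full risk reduction (20% on CHF hospitalization,
  13% on CHF mortality) requires both the admitting hospital and the patient's
  PCP to intervene; one party alone achieves a partial effect.
* **A payer agent** — reimburses fee-for-service (hospitalization $14,822 +
  $2,668 physician fee; visit $85) in both networks.  Each year the cost per
  CHF patient of the ACO network is compared with a controlled (usual-care)
  network serving a statistically identical population; a fraction **SSR** of
  any saving is shared with ACO providers, split by **SRH** between hospitals
  and PCPs and equally within type.  The remainder is the shared saving to
  payer (**SSP**).

Experiment drivers reproduce the study designs: a baseline comparison
(SSR = 0.5, SRH = 0.7, mixed provider types), SSR × SRH sweeps under three
provider-mix scenarios, and a one-at-a-time ±20% sensitivity analysis of SSP.

No external data are required: a documented synthetic population fixture
(`acosim.population.make_default_population_fixture`) generates cohorts from a
conditional-probability chain (demographics → diabetes → hypertension → CHF).

## Worked example

Run the replicated baseline study at a reduced scale (4,000 patients, 5 years,
50 replications):

```python
import acosim

cfg = acosim.SimulationConfig(n_patients=4000)
summary = acosim.run_replications(cfg, n_reps=50, seed=1)

for outcome in ("ctrl_admissions_per_chf_py", "aco_admissions_per_chf_py",
                "ctrl_mortality", "aco_mortality",
                "ctrl_payment_per_chf", "ssp_per_chf", "percent_saving"):
    lo, hi = summary.ci(outcome)
    print(f"{outcome:28s} {summary.mean(outcome):9.3f}  (95% CI {lo:.3f}-{hi:.3f})")
```

prints

```
ctrl_admissions_per_chf_py       0.545  (95% CI 0.539-0.551)
aco_admissions_per_chf_py        0.489  (95% CI 0.484-0.493)
ctrl_mortality                   0.160  (95% CI 0.157-0.163)
aco_mortality                    0.153  (95% CI 0.150-0.156)
ctrl_payment_per_chf         10153.688  (95% CI 10050.785-10256.591)
ssp_per_chf                    564.301  (95% CI 513.617-614.985)
percent_saving                   5.297  (95% CI 4.850-5.745)
```

Reading the output: controlled-network CHF patients average 0.545 CHF-related
admissions per patient-year and 16.0% annual mortality under usual care.  Once
shared-saving incentives trigger intervention adoption in the ACO network, its
admission rate falls to 0.489 and mortality to 15.3%, and after distributing
the providers' share the payer retains $564 per CHF patient per year — a 5.3%
saving against the $10,154 fee-for-service payment in the controlled network.
Absolute levels depend on the synthetic population fixture; the comparative
(ACO vs controlled) structure is the meaningful output.

The same studies are available from the shell:

```bash
acosim run --config my_config.yaml --seed 1 --reps 50 --out results/
acosim experiment baseline --reps 50 --seed 1 --out results/
acosim experiment sweep --scenario profit --reps 50 --seed 1 --out results/
acosim experiment sensitivity --reps 50 --seed 1 --out results/
acosim population sample --n 10000 --seed 1 --out cohort.csv
```

## Documentation

`docs/methods.md` describes the model in full: the transition model and its
parameters, the TPB decision machinery and its default utility transforms, the
payment settlement, what the synthetic population fixture does and does not
emulate, and the package's numerical and design choices.
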