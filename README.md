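# ktxclaims

Claims-based phenotyping and competing-risk survival analysis for kidney-transplant
cohorts, with a synthetic national-claims simulator that carries its own ground truth.

## The problem

National health-insurance claims databases (such as the French SNDS) record every
reimbursed hospital stay, community-pharmacy delivery and dialysis session, but no
clinical outcomes: whether a kidney graft failed, which maintenance immunosuppressant a
patient was on, or whether a hospital-infused biologic like belatacept was ever given
must all be *reconstructed from billing signals*. `ktxclaims` implements that
reconstruction as a tested, reusable pipeline for pharmacoepidemiologists studying
post-transplant immunosuppression:

* **cohort building** — index transplantation = admission date of the first hospital stay
  carrying a kidney-transplant procedure code (defaults `JAE003`, `HNEA002`); exclusions
  for age < 18, undocumented sex, database absence in the prior year, and data
  inconsistencies, with a patient-flow report that partitions the screened population;
* **drug-exposure episodes** — each pharmacy delivery covers 30 days; per-class coverage
  intervals merge across gaps ≤ 31 days; multi-class overlaps of ≥ 30 days that form a
  recognized regimen (CNI + antimetabolite, CNI + mTORi, …) are combinations, shorter
  overlaps are transition slack;
* **switch / add-on detection** — a regimen is deemed stopped on the date of first
  delivery of a relay class; if prior coverage continues ≥ 30 days alongside, the event
  is an add-on instead;
* **belatacept proxy** — belatacept is infused in hospital and invisible in community
  claims, so users are identified by ≥ 3 chemotherapy-delivery stays with a transplant
  diagnosis within 90 days, a companion mTORi/antimetabolite delivery within 90 days of
  the index hospitalization, and no CNI delivery during the fourth month after it;
* **graft-loss proxy** — earliest of: a > 3-month gap after immunosuppressive coverage
  ends, a retransplantation stay, or a sustained dialysis resumption (run spanning
  ≥ 91 days, inter-session gaps ≤ 31 days);
* **survival estimation** — event-free survival by the Kaplan–Meier product-limit
  estimator `S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)` with Greenwood variance and log(−log)
  95% bands; graft survival as `1 − F_graft(t)` where `F_k(t) = Σ_{t_i ≤ t} S(t_i−)
  d_{k,i}/n_i` is the Aalen–Johansen cumulative incidence with death as the competing
  risk, with the standard counting-process variance. The identity
  `Σ_k F_k(t) + S(t) = 1` holds at every event time to 1e-10.

Because real claims extracts are legally restricted, the package ships a first-class
**synthetic-claims generator** (`ktxclaims.simulate`): constant cause-specific hazards
for graft loss and death (closed-form oracles), 30-day delivery cadence, infusion-stay
streams for belatacept patients, dialysis resumption after graft loss, and a per-patient
`GroundTruth` (true regimen timeline, switch dates, event times) against which every
phenotyping rule is validated exactly on noise-free data.

## Worked example

```python
import ktxclaims as k

bundle, truth = k.generate(k.SimConfig(n_patients=2000, seed=42))
report = k.run_pipeline(bundle, seed=42)
print(report.text_summary())
```

```
Screened: 2000  eligible: 1966  excluded: {'under_18': 10, 'missing_sex': 10,
                                           'absent_prior_year': 8, 'inconsistent': 6}

Outcome table (5-year probabilities):
stratum    n  event_free_survival  event_free_lo  event_free_hi  graft_survival  graft_lo  graft_hi
    all 1014             0.752465       0.724708       0.777866        0.857002  0.834690  0.877739
  18-29   55             0.636364       0.494996       0.747880        0.727273  0.606262  0.836537
  ...

Patients with >=1 relay treatment: 442 (never switched: 0.775)
```

The `all` row is restricted to patients with an index date before 2015 so that five full
years of follow-up are possible. Event-free survival 0.752 matches the all-cause
exponential `exp(−5(λ_g+λ_d)) = 0.749` for the generator's default hazards
(λ_g = 0.03455, λ_d = 0.023306 per year), and graft survival 0.857 matches the
competing-risk closed form `1 − λ_g/(λ_g+λ_d)·(1 − e^{−5(λ_g+λ_d)}) = 0.850` within
Monte-Carlo error — the pipeline recovered both through claims phenotyping alone, not
from the simulator's truth.

The same stages are available from a shell:

```bash
ktxclaims simulate --n-patients 2000 --seed 42 --out data/
ktxclaims run --in data/ --out reports/
```

## Layout

```
src/ktxclaims/
  config.py     code lists, drug-class taxonomy, window parameters (YAML-serializable)
  model.py      four-table claims bundle, CSV dialect, validation
  simulate.py   synthetic claims generator + ground truth, competing-risk sampler
  cohort.py     index events, eligibility, baseline comorbidity/history flags
  exposure.py   coverage timelines, combinations, switches, belatacept algorithm
  outcomes.py   graft-loss proxy, outcome assembly (censored/graft loss/death)
  survival.py   Kaplan-Meier and Aalen-Johansen estimators with 95% bands
  report.py     era-bucketed treatment tables, yearly prevalence, switch matrix
  cli.py        `ktxclaims` command-line verbs
docs/methods.md  modelling assumptions, parameter defaults, limitations
```
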