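# Methods

This note documents the modelling assumptions, parameter conventions and design
choices behind `ktxclaims`, and what the synthetic-data validation does and does
not demonstrate about real claims data.

## Data model and temporal conventions

The pipeline consumes four flat tables (patients, hospital stays, pharmacy
deliveries, dialysis sessions) in a fixed CSV dialect: UTF-8, comma-separated,
ISO-8601 dates, `|`-separated code sets. Internally, all per-patient time is
expressed as integer day offsets from the index date (the admission date of the
first transplant-coded stay), and every interval is half-open `[start, end)`.
Calendar months are ragged, so month-based clinical rules are fixed once in
configuration: a "month" is 30 days, "three months" is 91 days, and the "fourth
month" after an anchor is days 91–120 inclusive, encoded `[91, 121)`. Day-to-year
conversion uses 365.25.

Comorbidity code lists match by *prefix* (a configured `E66` covers `E660`,
`E669`, …), mirroring hierarchical diagnosis families; drug classification is an
exact ATC-code lookup with unknown codes mapped to `other`. Both the code lists
and every window parameter are plain configuration (`CodeConfig`), not logic.

## Exposure episodes

A delivery covers `coverage_days = 30` days. Claims data do not state pack
coverage; 30 days matches the dominant dispensing rhythm for maintenance
immunosuppressants and is configurable. Per-class covers are unioned and merged
across gaps of at most `merge_gap_days = 31`, so one skipped refill does not
break an episode while a two-month silence does. Every coverage interval starts
at a delivery date, which makes interval starts usable as first-exposure dates.

Combinations partition covered time into maximal periods of constant
therapeutic-group sets (CNI, antimetabolite, mTORi, belatacept, corticosteroid).
A multi-group period is a combination only if the simultaneous overlap lasts
≥ 30 days and its non-steroid set is a recognized maintenance regimen;
shorter multi-group periods are treated as transition slack and folded into the
neighbouring period. Corticosteroids never participate in recognition, and an
isolated sub-30-day multi-group island with no contiguous neighbour is left as
its own (unrecognized) period.

Switches: when a class first becomes covered more than 30 days after the
patient's earliest coverage, the classes covered at that date whose current
interval ends within 30 days are "stopping"; if any stops, the event is a switch
dated at the new class's first delivery, otherwise an add-on. A residual of
exactly 30 days counts as continuing (the ≥ 30-day rule is inclusive). When the
belatacept call is positive, the belatacept class is anchored at its infusion
start rather than its first community delivery, so the 2020 retrocession (the
drug becoming pharmacy-visible mid-stream) is not misread as a therapy change.

The belatacept proxy algorithm anchors all windows at the index
hospitalization, defined as the earliest stay of the earliest qualifying
three-stay window. The companion-delivery window is implemented as
`[anchor, anchor + 90]` inclusive; whether the clause should instead require a
strictly later delivery is undecidable from the rule's phrasing, and the chosen
reading is the laxer one. "No CNI delivery" is evaluated against community
deliveries only, the only CNI channel visible in claims.

## Outcomes

Graft loss is dated by the earliest of: (a) end of all-class immunosuppressive
coverage followed by > 91 days without any delivery (dated at the coverage end,
so the rule composes with the 30-day coverage assumption); (b) a
retransplantation stay (admission date); (c) a dialysis run spanning ≥ 91 days
with inter-session gaps ≤ 31 days (dated at the first session). Gaps truncated
by death or the end of the study do not qualify. Ties between proxies on the
same day resolve in the listed order.

One outcome record per cohort member codes the first of graft loss (1), death
(2), or censoring (0). A same-day graft-loss/death tie is coded as death:
death is the competing risk of interest and terminal-hospitalization artifacts
would otherwise inflate graft failure. Loss to follow-up — undefined in
administrative claims — is operationalized as > 365 days of all-claim silence
ending before the study end, censored at the last claim. The retransplant-only
variant of graft survival (ignoring proxies a and c) can be obtained by passing
only retransplant candidates to the detector; the default estimand is the
proxy-based one.

## Survival estimation

The product-limit estimator uses Greenwood's variance; the default 95% band
applies the log(−log S) transform (plain Greenwood is available as an option),
which keeps intervals inside [0, 1] and is the common convention when only
"95% CI" is specified. The Aalen–Johansen estimator processes ties across
causes at the same time against the same pre-time risk set; its variance is the
standard counting-process (Marubini–Valsecchi) estimator, expanded into
cumulative sums for O(m) evaluation, with a complementary-log-log band on the
CIF scale. The complement-of-KM alternative for graft-survival intervals is
deliberately not used. Both estimators are validated against brute-force
risk-set recomputation at 1e-10 and cross-checked against lifelines.

## The synthetic-claims generator

The generator emulates the claim streams of a national transplant cohort with
known ground truth:

* **Demographics.** Age-class weights (6.8 / 12.4 / 19.1 / 24.9 / 24.7 / 12.1 %
  for 18-29 … ≥ 70) and a 62.7% male split, giving a mean age near 53 years;
  index dates uniform over 2009–2020.
* **Events.** Constant cause-specific hazards, default λ_graft = 0.034550 and
  λ_death = 0.023306 per year, calibrated so the true 5-year death-free
  probability is 0.890 and the true 5-year graft-failure-free probability under
  competing risks is 0.850. Exponential hazards are a simplification chosen
  because they give closed-form oracles for every estimator; real post-transplant
  hazards are higher in year one. Administrative censoring at
  min(12 years, study end). Death hazards may be age-class-specific.
* **Treatment.** Initial regimens drawn from a configurable mix dominated by
  tacrolimus + mycophenolic acid + corticosteroid; 3.9% of patients receive
  belatacept (infusion stays every 30 days carrying a chemotherapy-delivery flag
  and a transplant diagnosis, antimetabolite and steroid deliveries, no CNI;
  community belatacept deliveries additionally appear from July 2020, emulating
  retrocession). Pharmacy deliveries arrive every 30 days per active class.
  Switching is a Poisson process at 0.067/year; relays replace the anchor
  molecule (CNI/mTORi/belatacept) with a previously unused pharmacy-visible
  molecule while companions continue.
* **Context claims.** One pre-index delivery guarantees database presence;
  comorbidity-coded stays appear in the lookback year at the configured
  prevalences; non-pre-emptive patients (86.8%) carry pre-index dialysis
  sessions; graft loss triggers dialysis sessions every 7 days thereafter.
* **Determinism.** One RNG substream per patient keyed by `(seed, patient
  index)`, so enlarging the cohort never reshuffles earlier patients.

Three generator choices exist purely to make zero-noise recovery exact, and are
knowingly mild distortions of the event process:

1. a graft loss sampled within 92 days of the censoring horizon is emitted as
   censored (the > 91-day gap/dialysis-run proxies cannot be observed in the
   remaining window);
2. a patient whose follow-up ends before day 61 cannot accumulate the three
   infusion stays the belatacept algorithm requires, and draws a
   pharmacy-visible regimen instead (~0.03% of draws);
3. true switches are restricted to ≥ 150 days post index and to molecules new
   to the patient, so each true switch corresponds 1:1 to a first-delivery
   arrival and the 90-day initial-regimen window stays unambiguous.

Noise knobs (missed deliveries, delivery delays, decoy chemotherapy stays) are
off by default and exercised by robustness tests without fixed expectations.

**What passing tests show — and don't.** Exact zero-noise recovery demonstrates
that the phenotyping rules are implemented faithfully and are mutually
consistent with the generator's claim grammar. It does not validate the proxies
against clinical reality: real claims have irregular refill behaviour,
in-hospital dispensing invisible to community claims, coding errors and
induction therapy, none of which the generator reproduces. Robustness under the
noise knobs is reported, not asserted.

## Problem sizes

The test suite validates estimators on random fixtures of up to 5,000 records,
the belatacept algorithm against exhaustive triple enumeration on streams of up
to 20 stays, and end-to-end ground-truth recovery on a 10,000-patient
simulation; the acceptance script estimates the two headline quantities on
16,139 simulated subjects, matching the cohort size whose five-year follow-up
the outcome table reports. These sizes give Monte-Carlo standard errors of
about 0.0025–0.003 on the 5-year probabilities.

## Known limitations

* The ICD-10/ATC/procedure code lists shipped as defaults are plausible
  placeholders, not a validated extract dictionary; every list is configuration.
* "Database absence", "data inconsistencies" and "loss to follow-up" have no
  canonical claims definitions; the operationalizations above are documented
  sensitivity knobs.
* The pipeline estimates descriptive survival only; no regression modelling
  (Cox, Fine–Gray) is included.
* Dose, trough levels, induction agents and hospital-dispensed drugs other than
  belatacept are out of scope — they are not observable in the claims model the
  package targets.
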