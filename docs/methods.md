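# Methods

## The estimation problem

Prehospital major-trauma triage is a binary test applied by ambulance crews
to acutely injured patients: convey to a Major Trauma Centre (MTC) with a
pre-alert call, or not. Its accuracy is judged against a reference standard
of "true" major trauma. Because prevalence is low (~3%), a simple random
sample large enough to estimate sensitivity precisely is impractical; the
case-cohort design instead analyses a random sub-cohort (drawn irrespective
of outcome) together with *all* reference-standard positive cases found in
the trauma registry and linked deterministically to their ambulance records
by patient report form number.

All estimation is unweighted, mirroring standard practice for this design
in diagnostic research: sensitivity uses all cases, specificity uses the
reference-negative records (dominated by the sub-cohort), and prevalence is
estimated from the random sub-cohort alone. No Prentice/Barlow-style
weighted estimators are provided. The key pitfall of the design — that the
case-enriched 2×2 table's column margins do not reflect population
prevalence — is handled explicitly: `DiagnosticAccuracyResults.ppv()` emits
a `CaseCohortPPVWarning`, and the supported route to predictive values is
Bayes on the odds scale, `post-test odds = pre-test odds × LR`, using the
sub-cohort prevalence. On a simple random sample the two routes coincide
exactly (a property the test suite checks algebraically).

## Accuracy metrics and intervals

* Sensitivity/specificity: exact binomial proportions with Wilson score
  intervals by default; Wald available (`ci_method="wald"`). Wilson was
  chosen for its better small-count behaviour in age-stratified analyses.
* Likelihood ratios: `LR+ = Se/(1−Sp)`, `LR− = (1−Se)/Sp`, with
  log-transform (Simel) intervals,
  `SE(ln LR+) = sqrt(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN))` and the
  analogous expression (TP↔FN, FP↔TN) for LR−. Published tables produced
  by other software may show different LR− intervals; point estimates are
  method-independent.
* Degenerate tables: an empty reference margin raises
  `UndefinedMetricError` naming the margin; `Sp = 1` reports `LR+ = +∞`
  flagged, with a one-sided interval from continuity-corrected counts.
* Presentation rounding is round-half-up at the printed precision
  (so 6.125 → 6.13), applied only at output; full precision is kept
  internally.
* Age strata default to children (<16) then 10-year adult bands ending in
  an open 90+ band; bands are configurable and must partition the age axis.

## The rule engine

Tools are declarative YAML checklists. Grouped tools have up to four steps —
physiology and anatomical injury (mandatory, steps 1–2), mechanism of
injury and special circumstances (discretionary, steps 3–4); ungrouped
tools are a single flat checklist. Within a step, criteria combine by OR;
`cumulative(k)` is the OR of steps 1..k, which makes sensitivity
non-decreasing and specificity non-increasing in depth by construction —
the engine reports both the mandatory-steps-only result and every
cumulative depth, because services differ in whether discretionary steps
are applied.

Criterion semantics:

* non-sustained physiology compares the **first recorded value**;
* *sustained* criteria require a run of **≥2 consecutive recorded values**
  meeting the threshold, in recording order (timestamps are retained in the
  evidence trail but do not reorder the series);
* comparators are applied exactly as written — strict vs inclusive
  thresholds are distinct and no measured value is rounded;
* a missing required variable raises `MissingDataError`, never a silent
  negative; the default policy is whole-record exclusion via the
  complete-case filter, which logs removals per field;
* every satisfied criterion reports the exact measurement(s) that satisfied
  it, so any positive triage result is auditable.

The four packaged tool files are *structural* fixtures: three grouped
four-step tools and one ungrouped checklist populated with conventional
field-triage variables (SBP <90, GCS ≤13, RR <10 or >29, penetrating
injury, open fracture, falls >1 m, age ≥65, anticoagulation). Authentic
service checklists live in operational documents and must be supplied by
the user; the fixtures exist so the engine, and analyses built on it, are
fully testable.

## Reference standards

The primary consensus standard is positive when any of four domains holds:
(1) receipt of a critical intervention; (2) a significant individual
injury; (3) a multiple-injury burden; (4) patient characteristics implying
capacity to benefit from specialist care. The operational criterion lists
behind these domains are consensus products not reprinted here, so each
domain is a configurable predicate list with documented defaults: urgent
interventions = {intubation, thoracostomy, blood product transfusion,
emergency surgery, interventional radiology}; significant injury = any
AIS ≥3 injury or an open extremity fracture; multiple injuries = AIS ≥3 in
≥2 body regions; capacity to benefit = age ≥65 with an AIS ≥3 injury
(requiring ≥1 coded injury — whether this domain can fire without a coded
injury is clinically unsettled, so it is configurable).

Secondary standards: ISS ≥16; the critical-interventions domain alone; and
the consensus standard re-evaluated with open-fracture rules removed. Two
implications hold by construction and are property-tested: critical
interventions ⇒ consensus positive, and no-open-fracture positive ⇒
consensus positive.

ISS is the sum of squares of the highest AIS severity in each of the three
most severely injured of the six classic body regions (head, face, thorax,
abdomen, extremities, external); any AIS-6 injury sets ISS = 75 by
convention. The implementation is verified against a brute-force
maximisation over all ≤3-region subsets on exhaustive small injury sets.

## The synthetic generator

The generator emulates the study population of a four-network English
case-cohort triage study, stratified by latent reference-standard status:

* **Prevalence** 3.1% of incidents positive.
* **Ages**: child/adult/elderly mixture with per-status weights
  (positives 3.2/51.2/45.6%, negatives 6.6/35.8/57.6%); uniform within the
  child (0–16) and adult (16–65) bands, truncated normal in the elderly
  band (negatives μ=84 σ=12, positives μ=78 σ=10, on [65,103]), tuned so
  the negative-stratum median age is ≈73 and the positive ≈61 years.
* **Mechanisms**: the 11-category distribution per status (ground-level
  falls 70.9% of negatives, 35.4% of positives; penetrating mechanisms
  derive the blunt/penetrating mode).
* **Vitals**: 1–4 serial measurements; first values from per-status
  truncated normals matched to observed medians/IQRs (e.g. SBP 137 vs
  142 mmHg; RR 20 vs 18), GCS from explicit categoricals (median 15 in both
  strata, heavier low tail in positives); later values follow a bounded
  random walk (SBP sd 8, RR 2, SpO2 1.5 per step) so sustained criteria
  have genuine serial structure.
* **Injuries**: per-status Bernoulli region involvement (positives: head
  53%, extremities 50%, thorax 40%, …) with a severity categorical
  calibrated once so the positive-stratum ISS has median 18 (IQR ≈12–27);
  ~10% of positives qualify only through an open extremity fracture.
  Negatives carry only AIS ≤2, closed injuries.
* **Provider behaviour**: pre-alert decisions are Bernoulli with
  `P = expit(α_status + slope·(age−60))`. The slopes (−0.032/year for
  sensitivity, −0.020/year for the false-positive rate) encode the observed
  spectrum effect — sensitivity falling from ~0.8 in children to ~0.23 over
  90, specificity rising with age. The intercepts are solved numerically at
  generation time on the realised age vector, so the *expected* whole-sample
  sensitivity and specificity equal the configured targets exactly and
  deviations are pure binomial noise. The destination (MTC vs non-MTC)
  secondary index test is the pre-alert decision OR'd with extra
  conveyances (20%/17% by status), so it dominates pre-alert in sensitivity
  and is dominated in specificity.
* **Missingness** only where the design needs it: 3% of report form IDs
  (driving the deterministic-linkage match rate) and 2% of GCS series
  (driving the complete-case filter), keeping complete-case rates >90%.

The generator is *coherent with the default classifier*: positives always
satisfy at least one consensus domain and negatives never do, so the
classify stage recovers the latent truth exactly. This is intentional —
it isolates estimator behaviour from reference-standard misclassification.
What the generator does **not** emulate: within-patient correlation of
repeat incidents, per-service population differences (services share one
population by default), reference-standard misclassification, probabilistic
record matching, seasonal/COVID-era shifts, and free-text abstraction
error. Passing tests therefore demonstrate correct estimation under the
stated sampling design, not robustness to those real-data complications.

Determinism: one master seed; the population and sub-cohort draws use fixed
offsets from it. Identical configs give byte-identical cohorts, analysis
sets and report bundles (SVG output is salted with the seed for
reproducible hashing).

## Problem sizes

The shipped analyses use n=20,000 parent cohorts for distributional and
cumulative-step checks and n=50,000 for parameter recovery (with a
2,000-record sub-cohort typical); these sizes make binomial Monte-Carlo
intervals around the generator targets tight enough to be informative while
keeping a full run in seconds on one CPU.

## Known limitations and open points

* Published sources disagree slightly internally: the pooled decision
  counts imply sensitivity 46.5%/specificity 94.7% while the abstract-style
  summary prints 46.7%/94.5%, and the prevalence denominator appears both
  as 1,722 and 1,798. The counts-consistent values are used for regression
  checks; the prevalence worked example uses 54/1,722 = 3.1%.
* LR− interval methods differ across software; only point estimates are
  treated as method-independent.
* Incident, not patient, is the unit of analysis; recurrent attenders are
  not modelled.
* The packaged tool specs are placeholders (above); per-service theoretical
  accuracy from these fixtures characterises the engine, not any real
  service's tool.
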