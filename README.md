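# trauma-triage

Tools for evaluating the diagnostic accuracy of prehospital major-trauma
triage in regional trauma networks.

English ambulance services use step-wise checklist triage tools to decide
which injured patients should be taken — with a pre-alert call — to a Major
Trauma Centre (MTC). Whether those decisions are *right* is a diagnostic
accuracy question: the index test is the crew's conveyance decision (or the
theoretical result of the triage tool itself), and the reference standard is
whether the patient truly had major trauma benefiting from expedited MTC
care. Because major trauma is rare (~3% of acutely injured ambulance
patients), accuracy studies use a **case-cohort design**: a random
sub-cohort sampled irrespective of outcome, plus every reference-standard
positive case identified in the national trauma registry and linked back to
its ambulance record.

This package is aimed at triage researchers and trauma-network audit teams.
It provides:

- **`DiagnosticAccuracyModel` / `DiagnosticAccuracyResults`** — the central
  estimator. From aligned index/reference flags or a 2×2 table it computes
  sensitivity `Se = TP/(TP+FN)`, specificity `Sp = TN/(FP+TN)`, likelihood
  ratios `LR+ = Se/(1−Sp)`, `LR− = (1−Se)/Sp` (Wilson or Wald intervals for
  proportions; Simel log-method intervals for LRs), and Bayesian post-test
  probabilities via pre-test odds × LR = post-test odds. Under case-cohort
  sampling it deliberately warns if you ask for a predictive value straight
  off the enriched table.
- **A declarative triage-rule engine** — tools are YAML checklists of
  criteria over vitals, age, mechanism, injury patterns and special
  circumstances, organised into mandatory (physiology, anatomy) and
  discretionary (mechanism, special circumstances) steps, evaluated
  cumulatively. First-recorded-value and sustained (≥2 consecutive
  readings) physiology semantics are built in.
- **Reference-standard classification** — the four-domain consensus
  definition of major trauma (critical interventions, significant injuries,
  multiple injuries, capacity to benefit) plus secondary standards:
  ISS ≥ 16 (ISS = sum of squares of the highest AIS severity in the three
  most severely injured of six body regions), critical interventions alone,
  and the consensus standard without open fractures.
- **A synthetic case-cohort generator** — an elderly-skewed, blunt-trauma,
  ground-level-fall dominated population with configurable provider triage
  behaviour, for validating estimators and tool configurations end to end.
- **A pipeline CLI** (`trauma-triage`) with `simulate`, `triage`,
  `classify`, `estimate`, `prevalence`, `run` and `report` subcommands.

## Worked example

Pooled observed triage decisions (conveyed to MTC with pre-alert) against
the consensus reference standard, from published counts:

```python
>>> from trauma_triage import DiagnosticAccuracyModel, posttest_probability
>>> res = DiagnosticAccuracyModel.from_counts(tp=446, fp=95, tn=1703, fn=513).fit()
>>> print(res.summary())
Diagnostic accuracy — overall
==========================================================
design: case_cohort            ci method: wilson
n = 2757   tp=446 fp=95 tn=1703 fn=513
----------------------------------------------------------
metric          estimate     95% LCL     95% UCL
sensitivity        0.465       0.434       0.497
specificity        0.947       0.936       0.957
LR+                8.802       7.155      10.828
LR-                0.565       0.532       0.600
==========================================================
>>> round(posttest_probability(0.031, res.lr_pos), 2)   # after a positive decision
0.22
>>> round(1 - posttest_probability(0.031, res.lr_neg), 2)  # no major trauma after a negative
0.98
```

Reading: crews identify fewer than half of major-trauma patients
(sensitivity ≈ 0.47) but rarely over-triage (specificity ≈ 0.95). At a 3.1%
pre-test prevalence, a positive decision raises the probability of major
trauma to 22%; a negative decision leaves a 98% probability of no major
trauma.

A full synthetic study run:

```bash
trauma-triage run --n 20000 --subcohort-size 2000 --seed 7 --out study_run
```

writes the analysis set, sample characteristics, observed-decision accuracy
(overall, per service, per age band), cumulative step-depth accuracy per
tool, a 4-reference-standards × 2-index-tests sensitivity-analysis matrix,
ROC plots and a hash-stamped manifest; rerunning with the same seed
reproduces the bundle byte for byte.

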