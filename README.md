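# icutriage

Rule-based ICU admission triage with the statistics needed to evaluate it.

Intensive-care beds are scarce, and admission triage is usually left to
unaided clinical judgment, which is hard to reproduce and can hide bias.
`icutriage` implements a deterministic bedside decision rule that maps a
four-question admission questionnaire onto the Society of Critical Care
Medicine's (SCCM) priority classes 1–4, together with everything a
methodologist needs to study such a rule: inter-rater reliability statistics
(quadratic-weighted Cohen's κ, percent agreement, average-measures ICC),
construct/criterion validity analyses (appropriateness proportions, outcome
rates by priority with χ² tests for trend), and a seeded simulator of a
vignettes-×-raters agreement study and an admission-request cohort.

It is intended for critical-care researchers and biostatisticians evaluating
triage instruments, not for unsupervised clinical use.

## The decision rule

Four closed questions per admission request:

1. **Request type** — active intervention (vasopressors, ventilation, urgent
   dialysis) vs monitoring.
2. **Comorbidity** — none, compensated, decompensated, or advanced disease
   (life expectancy of months).
3. **Functionality** — Katz ADL: independent, partially dependent, severely
   dependent (≤ 2 ADLs).
4. **Intuitive prognosis** — survivor without severe disabilities, survivor
   with severe disabilities, nonsurvivor.

Priority **4** (generally not appropriate): decompensated comorbidity with
severe dependency; advanced disease with partial or severe dependency;
advanced disease with preserved functionality but a prognosis of death.
Priority **3**: compensated comorbidity with severe dependency; decompensated
comorbidity with partial dependency; advanced disease with preserved
functionality and a prognosis of survival. Everyone else is priority **1**
(intervention request) or **2** (monitoring request). The rule is total and
deterministic: the 72 possible answer combinations partition 18/18/16/20
across priorities 1/2/3/4 (`triage table` prints the full table).

## Worked example

Classify a request and replicate a full synthetic study:

```bash
$ printf 'id,request_type,comorbidity,functionality,prognosis\nv1,MONITORING,ADVANCED,INDEPENDENT,NONSURVIVOR\n' > a.csv
$ triage classify --in a.csv --out p.csv && tail -1 p.csv
v1,MONITORING,ADVANCED,INDEPENDENT,NONSURVIVOR,4
```

The patient has advanced disease with preserved functionality and an
intuitive prognosis of death, so the rule assigns priority 4.

```bash
$ triage replicate --seed 17 --out-dir demo --format csv
wrote demo/study_report.json (config hash cd9bc2c2eb36a54c)
```

With the default configuration (40 vignettes distributed 7/13/10/10 over
priorities, 9 raters at question fidelity 0.9, intuition noise 0.4, and a
603-request cohort of 265/155/102/61 prioritized records plus 20 with missing
priority), the report at seed 17 contains, among others:

* reliability — rule-based track: overall pairwise κ 0.84 (bootstrap 95% CI
  0.74–0.91), median percent agreement 0.78 (IQR 0.75–0.80), average ICC 0.98;
  intuitive track: overall κ 0.66. The rule-based track is more reliable
  because classification error only enters through the four answers, while
  intuitive priorities carry a direct ordinal confusion.
* construct validity — median κ against the reference standard 0.91;
  last-ICU-bed admission falls monotonically across priorities 1→4
  (87.3%, 62.4%, 35.6%, 20.0%; trend p ≈ 2×10⁻¹⁹).
* criterion validity — e.g. hospital mortality 32.8%, 24.5%, 42.2%, 65.6%
  across priorities 1–4 (trend p ≈ 2×10⁻⁵), with the exact event/total counts
  archived next to each percentage.

Every percentage in the report is recomputable from the emitted count tables,
and rerunning with the same seed reproduces the report byte for byte.

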