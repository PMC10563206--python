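# haisurv — knowledge-based surveillance of healthcare-associated infections

Healthcare-associated infections (HAIs) — infections acquired during a
hospital stay rather than present or incubating at admission — must be
detected and reported case by case, yet screening thousands of inpatients
daily by chart review is infeasible. `haisurv` implements a semi-automated,
knowledge-based surveillance pipeline for infection-control teams and
clinical-informatics researchers: explicit clinical rules screen every
inpatient day and raise detailed, auditable warnings that physicians then
confirm or reject.

## The model

Each inpatient surveillance day is an 8-tuple case
**(DE, PS, PN, IR, VS, CL, OP, MO)** — demographics, hospitalization
status, progress-note flags, imaging-report flags, vital signs, clinical
laboratory, operations, medical orders. Factors are typed (integer, real,
date, or binary with 0 = unsuspected / 1 = suspected) and drawn from a
declarative registry.

Knowledge rules live in decision tables: each row is a conjunction of
conditions over factors plus an action (rule id, infection probability
Pr). A rule *fires* when every condition holds; per diagnosis only the
highest-probability firing survives. Fired rules are post-processed into
warnings:

* **onset** — onset ≤ 48 h after admission ⇒ community-acquired (not an
  HAI alert);
* **threshold** — Pr below the per-diagnosis threshold ⇒ not sent;
* **repeat-infection timeframe (RTI)** — a same-patient, same-site alert
  within 14 days of a previous alert ⇒ suppressed as a recurrence.

Monthly physician feedback updates each rule's confidence via

    Pr(i) = Pr(i−1) + α · (Acc(i) − Pr(i)) / Pr(i−1),   α = 0.75

where Acc(i) is the fraction of the rule's alerts confirmed that month.
The relation is implicit in Pr(i) and is solved exactly:
Pr(i) = (Pr(i−1)² + α·Acc(i)) / (Pr(i−1) + α).

Evaluation scores episodes against gold labels with

    ACC = (TP+TN)/(P+N),  SEN = TP/(TP+FN),  SPE = TN/(TN+FP)

stratified by month, diagnosis, site, and rule-base scenario
(guideline-derived rules only vs guideline + expert rules).

The package ships a 12-site / 40-diagnosis infection catalog, a factor
registry, a keyword lexicon with sentence-level negation cues, and three
exemplar decision tables (pleural cavity infection and urinary tract
infection from guideline criteria, lower respiratory tract infection from
expert practice). Because real surveillance cohorts are confidential, a
synthetic EHR generator builds multi-source record sets (admissions,
vitals, labs, microbiology, notes, operations, orders) whose injected
infections each satisfy one packaged rule — giving the pipeline a known
ground truth.

## Worked example

`examples/02_run_surveillance.py` generates 200 episodes at 5% HAI
prevalence with no noise, extracts daily cases, runs the engine, and
scores against the generator's labels:

```
cohort: 200 episodes, 6 with an injected HAI
extracted 1363 case-days
warnings by status: {'alerted': 6, 'suppressed_rti': 1}
TP=6 FP=0 FN=0 TN=194
ACC=1.000 SEN=1.000 SPE=1.000
```

Six injected infections produce six alerts (one repeat firing is
suppressed by the 14-day window), no clean episode alerts, so
sensitivity and specificity are both 1.0 — the expected outcome when
every injected infection satisfies a packaged rule and no supporting
factor is dropped. The other examples inspect the catalog and rules
(`01`), show the confidence update converging to a rule's observed
confirmation rate (`03`), and compare guideline-only against
guideline-plus-expert scenarios in a stratified report (`04`).

A thin CLI wires the same stages together on disk:

```bash
haisurv simulate --seed 5 --n 200 --out run/
haisurv extract  --raw run/raw --out run/cases.jsonl
haisurv infer    --cases run/cases.jsonl --out run/warnings.csv
haisurv evaluate --warnings run/warnings.csv --gold run/gold_labels.csv --out run/report.csv
```

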