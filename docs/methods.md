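# Methods

## Scope and pipeline

`haisurv` is a rule-based screening pipeline for healthcare-associated
infections (HAIs). It deliberately contains no statistical learning: the
detector is a set of human-readable conjunctive rules, because the
system's purpose is auditable decision support — every alert cites the
rule that produced it, and every non-alert carries an explicit status.

The stages, in order: factor extraction (multi-source records → daily
8-tuple cases), forward matching (all-conditions-true firing), per-
diagnosis selection (highest probability, ties to the lowest rule id),
onset classification, per-diagnosis threshold gating, and
repeat-infection-timeframe (RTI) suppression. RTI runs last so that a
warning excluded earlier (community-acquired, below threshold) never
consumes the suppression window; onset runs before thresholding so
community-acquired firings are labelled as such rather than silently
thresholded away.

## Case representation and extraction conventions

One case per patient-episode per calendar day, so the engine can be run
as a daily review. Conventions that fix otherwise-ambiguous semantics:

* day windows are half-open `[00:00, 24:00)`; the daily maximum
  temperature takes the highest plausible reading (30–45 °C) in that
  window;
* the admission day is hospital day 1; hospital days count calendar
  days, not 24-hour periods (admitted 23:50 → day 2 ten minutes later);
* labs resolve latest-wins within "on or before the surveillance day";
* text-derived binary factors are never missing (absent evidence → 0);
  unmeasured numeric factors are *missing*, and any condition on a
  missing factor evaluates false — a rule cannot fire on unknown data.
  This is conservative against false alarms and costs sensitivity; it
  is the main reason factor dropout degrades recall in the experiments.
* keyword flags use all notes to date within the episode (configurable
  to same-day-only): clinical documentation accumulates evidence, and a
  sign recorded yesterday still supports today's inference.

Keyword matching is substring matching on case-folded,
whitespace-normalized text with a small sentence-level negation-cue list
("no ", "denies", "without", ...). This is an extension beyond bare
substring search — without it, any note documenting the *absence* of a
symptom would raise the flag and sensitivity tests would be misleading —
but it is deliberately not NLP: no parsing, no section detection, no
word embeddings.

## Rule dialect

Decision tables are plain CSV with a header declaring the ruleset,
target diagnosis, source (`guideline` or `expert`) and one
`factor operator` binding per CONDITION column; each data row is one
rule, blank cells are don't-cares, and an all-blank row is a parse error
(an empty conjunction would fire on every case). `in_range` operands
`low..high` denote `[low, high)`. Rule ids are opaque strings, unique
per rule base.

The three packaged tables encode the constraints stated in the source
clinical-guideline prose (pleural cavity infection's five-element
vocabulary including the pleural-effusion leukocyte cutoff of
1000 ×10⁶/L; urinary tract infection's seven elements with a
hospital-days gate; an expert lower-respiratory table using hospital
day, age and the presence of a PCT order). Cell values the prose does
not fix — temperature ranges, day cutoffs, probabilities — were authored
here and are marked `authored` in the provenance sidecar; initial
confidences default to 0.5, with 0.9–0.95 for etiologically confirmed
(culture-backed) rules.

## Boundary semantics

Fixed and tested, not configurable per call:

* onset: hospital-acquired iff strictly more than `onset_cutoff_hours`
  (default 48) elapse between admission and 00:00 of the firing day;
  onset at exactly 48 h counts as community-acquired. The 48-hour rule
  is stated ambiguously in practice; strictly-greater matches the common
  international convention and is the package's documented choice.
* thresholds: rejection is strict `<`; an unconfigured diagnosis has
  threshold 0 and always passes.
* RTI: suppression when the gap to the last *alerted* same-patient
  same-site warning is strictly less than `rti_days` (default 14).
  Keying on site (not diagnosis) follows the recurrence rationale — a
  new diagnosis at an already-alerted site within the window is still
  the same clinical episode; diagnosis keying is available via config.
* Optionally, warnings matching an already-confirmed infection of the
  same episode and site are suppressed regardless of the window
  (re-alert etiquette); this is off unless confirmed labels are passed.

## Confidence feedback

The monthly update `Pr(i) = Pr(i−1) + α(Acc(i) − Pr(i))/Pr(i−1)` is
implicit — the new confidence appears on both sides. The package solves
it exactly: `Pr(i) = (Pr(i−1)² + α·Acc(i))/(Pr(i−1) + α)`. The closed
form is self-normalizing to (0, 1], strictly increasing in Acc with
slope α/(Pr(i−1)+α), has Acc = Pr(i−1) as its unique fixed point, and
under constant Acc contracts toward Acc. A literal explicit reading
(replacing the right-hand Pr(i) with Pr(i−1)) is offered behind
`form="explicit"`; it can leave the unit interval (0.5 + 0.75·(1−0.5)/0.5
= 1.25) and is clamped to [0.01, 1]. α defaults to 0.75.

The accuracy denominator is the rule's *alerted* warnings in the
calendar month; months with no alerts carry the confidence forward
without a history entry. Thresholds are static unless changed by the
operator — they do not co-update with confidences.

## Evaluation

The scoring unit is the episode. Warning-to-gold matching granularity is
explicit (`any` / `site` / `diagnosis`, default `site`) because "the
system found this infection" is ambiguous when a warning names the wrong
site. Undefined metrics (zero denominators) are reported as missing,
never 0, and stratum averages are unweighted means over defined values.
Per-diagnosis and per-site strata score all episodes for that one label,
so true negatives dominate and specificity is structurally high there —
a property of the stratification, not of the detector.

## Synthetic cohorts

No real cohort ships with the package; the generator defines the test
conditions. Defaults: 500 episodes admitted over one quarter, 3% HAI
prevalence, mean stay 7 days (1 + Poisson), one episode per patient,
ages 18–90, diagnosis mixture LRI 0.60 / UTI 0.25 / PCI 0.15 — a
long-tail over the diagnoses that have packaged rules, with lower
respiratory tract infection heaviest as in real HAI registries. Infected
episodes get an onset on hospital day ≥ 4 (guaranteeing > 48 h after any
admission clock time and satisfying any hospital-days gate), and one
record-level realization per condition of one randomly chosen rule for
the diagnosis: a temperature reading inside the rule's range at onset, a
lab row 1.5× above a `gt` cutoff, culture rows, notes containing a
lexicon keyword. Lab-value and lab-flag conditions on the same test
share one row so latest-wins extraction cannot split them.

Factor dropout `q` removes each record-producing realization
independently with probability `q` (structural factors — age, onset-day
placement — cannot be "omitted" from an admissions row). The dropout
draw is made whether or not it removes anything, so cohorts differing
only in `q` share the same underlying population. Note noise plants a
lexicon keyword in a clean episode's notes at the given rate; because
every packaged rule also requires non-textual evidence, note noise
stresses the keyword extractor without creating false alarms.

What passing tests therefore show: the pipeline is internally coherent —
injected, rule-consistent infections are recovered perfectly at q = 0
and degrade monotonically with dropout. What they do not show:
performance on real data, where factors are noisy and incomplete in
correlated ways, notes are free-form (and in the original setting,
Chinese), baseline patients can be febrile without infection, and rules
compete with overlapping evidence. The generator models none of that;
real-world sensitivity/specificity cannot be inferred from these
cohorts.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale cohorts (200–2000 episodes,
seeds fixed) — large enough for the binomial/chi-square sanity checks on
the generator, small enough to iterate quickly; the cohort spec accepts
n ≈ 10⁵ for stress runs. The engine-vs-oracle check uses 200 randomized
cases against the full packaged base with an independently written naive
evaluator. The confidence closed form is verified on a 100×100 (Pr, Acc)
grid with residual ≤ 1e-12 against the implicit relation, and against a
root-bracketing solver in unit tests (a naive fixed-point iteration of
the relation diverges when Pr(i−1) < α, so it is not a usable oracle).

## Known limitations

* The packaged rule base is an exemplar (12 rules, 3 diagnoses), not a
  complete surveillance rule set; the dialect and validation support a
  full base.
* Only three infection sites are exercised end-to-end by the generator
  (those with packaged rules).
* No streaming/real-time operation, no HL7/FHIR ingestion, no
  database-backed storage, no dashboard rendering of warnings.
* Negation handling is cue-based and sentence-scoped; scope ambiguity,
  hedging and family history are not modelled.
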