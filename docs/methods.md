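# Methods

## Detection model

Each in-hospital creatinine result is evaluated in arrival order as a
potential index value; community (pre-admission) results never act as
index values but are eligible baseline material. The baseline is
recomputed at every result from the full prior history — it is not
frozen at episode onset — so a drifting baseline behaves exactly as a
live system rescanning the record would.

Window semantics are half-open and exclude the index result itself:
the short window is `(t − 7 d, t)` and takes the **lowest** value (the
NHS England convention; `most_recent` is available as a configuration
variant); the long window is `(t − 365 d, t − 7 d]` and takes the
median, with an even count resolved as the arithmetic mean of the two
middle values. A result exactly 7 days old therefore belongs to the
long window. Excluding the index from its own baseline prevents
self-referential ratios of 1.0 masking real rises.

Staging applies, in order: stage 3 (ratio ≥ 3.0 or absolute value
≥ 353.6 µmol/L), stage 2 (ratio ≥ 2.0), stage 1 (ratio ≥ 1.5 or a rise
≥ 26.5 µmol/L over the minimum creatinine of the trailing 48 h). All
five constants are `StagingConfig` fields with the KDIGO guideline
values as defaults, in µmol/L. When no baseline exists the ratio
criteria are skipped but both absolute criteria still apply — a
previously unknown patient arriving at 360 µmol/L alerts at stage 3.
The 48-h rise window accepts creatinine from either setting; in
practice nearly all trailing-48-h results are in-hospital draws.

### Lifecycle

Recovery is defined as a *full stage-0 assessment* — ratio below 1.5
**and** 48-h rise below 26.5 — not merely a falling ratio. This is the
strictest reading of "below the stage-1 threshold" and prevents an
episode closing while an absolute-rise criterion would still alert.
De-escalation within an episode (e.g. stage 2 → stage-1 range) raises
nothing and does not lower the episode's high-water mark, so a
re-rise to the same stage stays silent; only true progression alerts.
Acknowledgment is idempotent and history-preserving: alerts are
removed from nothing, only their status changes.

### Medication warnings

"A patient with AKI" means an **open episode** — consistent with the
recovery semantics, a drug ordered after recovery does not warn. The
post-onset window is closed at both ends, `onset ≤ t ≤ onset + 48 h`
(boundary orders warn); setting `med_warning_window_hours` to `null`
switches to warning on any risk order during an open episode, for
sites that prefer that reading. The stage recorded on a warning is the
highest stage alerted in the episode at order time. Warnings never
block the order and are recorded even when overridden.

The shipped formulary is a synthetic default with representative
agents per class (loop/thiazide diuretics; aminoglycosides and
vancomycin; common ACE inhibitors and angiotensin receptor blockers;
common NSAIDs; a handful of renally-cleared-only drugs). Site
deployments should replace it; lookup is total, with unknown names
mapping to class `other` and no flags, so a sparse formulary degrades
safely toward silence rather than false warnings.

## Dashboard

The summary is a pure function of the events at or before `as_of`;
appending later events can never change an earlier summary (tested as
an invariant). Fluid and urine summaries use half-open 8-hour bins —
nursing-shift granularity, configurable — anchored at the admission of
the covering encounter. A drug flagged both nephrotoxic and renally
cleared appears in both medication panels deliberately: both facts
matter to the assessing clinician. The electrolyte panel defaults to
sodium, potassium and bicarbonate. Microbiology results are passed
through as free text without parsing.

## Order-set engine

Order-item wording lives in an editable JSON template; the engine
enforces structure only: exactly one fluid-strategy branch per
recommendation (bolus / maintenance / diuresis, selected by the volume
status), monitoring safety parameters whenever a bolus is recommended
(with extra items when the patient is judged at risk of volume
overload), one review/hold suggestion per active risk medication, and
consult guidance from a configurable criteria list. Bolus parameters
are placeholders the prescriber completes — the engine recommends
structure, not doses.

## Silent-mode aggregation

Percentages are rounded half-away-from-zero to one decimal, which
reproduces the arithmetic of count/total frequency tables exactly;
zero-total partitions render "—" rather than dividing by zero. An
alert contributes to the with-medications row iff its active risk
medication list is non-empty, and contributes each *distinct*
medication class at most once to the per-class breakdown. Unit-type
attribution uses the encounter covering the alert or warning time.

## Synthetic cohort generator

The generator emulates a month of admissions to general medical and
surgical units. Per patient: a personal creatinine baseline drawn
lognormal(ln 80, 0.25) µmol/L; an admission uniform over a 30-day
window with a 4–10-day stay; routine creatinine draws every 12–24 h
plus three community results 30–300 days pre-admission (exercising the
year-median baseline path on the first in-hospital draw); shift-level
fluid charting and vitals; and per-class risk-medication exposure
(diuretic 25%, antibiotic 20%, ACEi/ARB 20%, NSAID 15%), with
occasional renally-cleared-only and non-formulary orders.

With probability `aki_incidence` (default 0.15) an episode is planted:
after 2–3 normal draws the trajectory steps into the planted stage's
ratio band, dwells for a duration drawn from the recovery hazard
(capped at 3 days so the pre-onset baseline stays inside the 7-day
window), optionally escalates one stage (progression, default 15%),
then steps back to baseline. Planted ratios are placed at least 5%
inside the KDIGO band edges so that multiplicative lognormal
measurement noise at the default 2% CV cannot move a planted episode
across a stage boundary; when a planted ratio on a high-baseline
patient crosses the 353.6 µmol/L absolute threshold, the recorded
truth stage is promoted to 3, keeping the truth consistent with the
stream by construction. Identical seeds yield byte-identical cohorts.

Defaults were chosen so a default run produces alert volumes of the
same order as a month-long multi-unit silent audit (tens of alerts per
400 admissions) without asserting any particular count; the planted
stage mix defaults to (0.667, 0.173, 0.160).

What the generator does **not** emulate: physiological creatinine
kinetics (rises are steps, not GFR-driven ramps), correlated
multi-analyte derangement, inter-hospital transfers, dialysis, or any
real casemix. Passing tests therefore demonstrate the *engine's*
correctness against its stated rules and planted ground truth — not
clinical sensitivity or specificity on real patients, which depend on
real sampling patterns and baselines.

## Verification design

Every engine is checked against an independently written oracle:
staging against a flat-scan threshold evaluator over a dense
(baseline, index) grid; the streaming lifecycle against a whole-history
replay that re-derives per-result stages with bisect-based window
slicing and segments the stage sequence into episodes; the warning
engine against brute-force (order, episode) pair enumeration; and the
report aggregation against direct recounts of the raw lists. Problem
sizes in the acceptance script (1,000 patients for oracle equivalence,
300 for planted-truth recovery, 1,500 at 70% incidence for stage-mix
recovery, giving ≈1,000 episodes and ±5% binomial bounds) keep the
whole run in a few seconds while leaving the statistical checks
well-powered. The stage-mix check compares each episode's *first*
alert stage to the configured mix, since progression intentionally
raises additional higher-stage alerts without changing the planted
draw.

## Known limitations

* No urine-output or renal-replacement stage-3 criteria (by design).
* mg/dL inputs are supported only by whole-file conversion at read
  time, not per-row units.
* The formulary and order-set content files are synthetic defaults,
  not an institutional document.
* Episode attribution assumes non-overlapping encounters per patient.
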