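# aki-cds

A testable engine for electronic clinical decision support in
hospital-acquired **acute kidney injury (AKI)**: creatinine-based
detection and KDIGO staging, an alert lifecycle state machine,
interruptive nephrotoxic-medication order warnings, a clinical-summary
dashboard aggregator, volume-status-branched order-set recommendations,
and a silent-mode cohort evaluator — all exercisable on synthetic
patient event streams, with no access to a real EMR required.

It is written for health-informatics developers and researchers who
want to prototype, audit, or regression-test AKI e-alerting logic
outside a production EMR.

## The model

AKI is staged from serum creatinine (SCr, µmol/L). For each in-hospital
index result the engine selects a baseline the way the NHS England
detection algorithm does:

* **7-day window** — if any creatinine exists in the 7 days before the
  index result, the baseline is the *lowest* value in that window;
* **one-year median** — otherwise, the median of all values from the
  preceding year;
* otherwise no ratio can be formed (absolute criteria still apply).

Staging follows the KDIGO creatinine criteria:

| stage | criterion |
|---|---|
| 1 | SCr ≥ 1.5 × baseline, **or** rise ≥ 26.5 µmol/L within 48 h |
| 2 | SCr ≥ 2.0 × baseline |
| 3 | SCr ≥ 3.0 × baseline, **or** SCr ≥ 353.6 µmol/L |

Urine-output criteria are deliberately excluded: urine-output charting
varies too much between wards to drive automated alerts.

The alert lifecycle: the first qualifying result opens an **episode**
and raises an alert; within an episode new alerts fire only on
progression to a higher stage; a result assessed stage 0 closes the
episode (recovery); a later qualifying result opens the next episode
and alerts again. Alerts are acknowledgeable but never deleted. A
medication that may worsen kidney function (diuretics, nephrotoxic
antibiotics, ACE inhibitors / angiotensin receptor blockers, NSAIDs)
ordered within 48 h of episode onset triggers an interruptive — but
overridable — warning carrying the current alerted stage.

## Worked example

```bash
python examples/detect_and_stage.py
```

```
alert stage 1  episode 1  raised 2025-03-10 08:00  baseline 100 (short_window)  ratio 1.60
alert stage 2  episode 1  raised 2025-03-10 20:00  baseline 100 (short_window)  ratio 2.10
alert stage 1  episode 2  raised 2025-03-11 20:00  baseline 100 (short_window)  ratio 1.70
2 episodes; final state in_episode=True
```

A patient with a 100 µmol/L baseline rises to 160 (ratio 1.6 → stage 1),
progresses to 210 (ratio 2.1 → a second alert at stage 2), recovers at
105 (episode closed, silently), and relapses at 170 — which opens
episode 2 and alerts again. The de-escalation from 210 to 105 itself
raises nothing: only progression alerts within an episode.

The other examples each demonstrate one capability — medication
warnings, the silent-phase frequency report, the dashboard, the order
set, and the synthetic-cohort generator:

```bash
python examples/silent_phase_report.py   # simulate a month, audit alert volumes
python examples/medication_warnings.py
python examples/dashboard_summary.py
python examples/order_recommendations.py
python examples/simulate_cohort.py
```

The same functionality is exposed as a thin CLI:

```bash
aki-cds simulate --seed 1 --n-patients 100 --out cohort.csv --truth-out truth.json
aki-cds detect cohort.csv --out alerts.jsonl
aki-cds silent-report cohort.csv
aki-cds recommend --volume-status hypovolemic --overload-risk
```

## Layout

* `src/aki_cds/records.py`, `io.py` — domain types; CSV/JSONL event
  streams (JSON Schemas in `src/aki_cds/data/schemas/`)
* `src/aki_cds/detection.py` — baselines, staging, alert lifecycle
* `src/aki_cds/medsafety.py` — formulary and medication warnings
* `src/aki_cds/dashboard.py` — clinical summary aggregation
* `src/aki_cds/orders.py` — order-set recommendation engine
* `src/aki_cds/cohort.py` — silent-mode batch evaluation and reports
* `src/aki_cds/simulate.py`, `scenarios.py` — synthetic cohorts and the
  functional scenario suite
* `docs/methods.md` — modelling choices, generator design, limitations
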