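"""Detect and stage an AKI episode from a short creatinine history.

A patient with a community baseline of 100 µmol/L rises to 160 (stage 1
by the 1.5× ratio), progresses to 210 (stage 2), recovers to 105, and
relapses to 170 — producing three alerts across two episodes.
"""

from datetime import timedelta

from aki_cds import (
    Analyte, Encounter, LabResult, Patient, Setting, UnitType, detect, utc,
)

t = utc(2025, 3, 10, 8)
p = Patient("demo")
p.encounters.append(Encounter("E1", t - timedelta(hours=6), t + timedelta(days=7),
                              UnitType.MEDICAL, "Med-3"))
for hours, value, setting in [
    (-48, 100, Setting.COMMUNITY),   # pre-admission baseline material
    (0, 160, Setting.HOSPITAL),      # ratio 1.6 -> stage 1, episode 1
    (12, 210, Setting.HOSPITAL),     # ratio 2.1 -> progression to stage 2
    (24, 105, Setting.HOSPITAL),     # stage 0 -> recovery closes episode 1
    (36, 170, Setting.HOSPITAL),     # ratio 1.7 -> stage 1 again, episode 2
]:
    p.labs.append(LabResult("demo", Analyte.CREATININE, t + timedelta(hours=hours),
                            value, setting=setting))
p.sort_events()

result = detect(p)
for a in result.alerts:
    print(f"alert stage {a.stage}  episode {a.episode_index}  raised {a.raised_at:%Y-%m-%d %H:%M}"
          f"  baseline {a.assessment.baseline.value} ({a.assessment.baseline.method.value})"
          f"  ratio {a.assessment.ratio:.2f}")
print(f"{len(result.episodes)} episodes; final state in_episode={result.final_state.in_episode}")
# Each line is one e-alert: the stage it announces, which AKI episode it
# belongs to, and the baseline/ratio arithmetic that triggered it.
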