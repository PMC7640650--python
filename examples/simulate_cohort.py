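"""Generate a seeded synthetic cohort, write it to disk, and verify the
detector recovers every planted episode exactly (no measurement noise).
"""

from pathlib import Path

from aki_cds import SimulationConfig, detect, generate_cohort, write_event_stream

config = SimulationConfig(n_patients=100, seed=9, aki_incidence=0.3,
                          measurement_noise_cv=0.0)
cohort, truth = generate_cohort(config)

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
write_event_stream(cohort, out / "synthetic_cohort.csv")

planted = {(e.patient_id, e.onset_at): e for e in truth.episodes}
exact = 0
for p in cohort:
    for ep in detect(p).episodes:
        e = planted.get((p.patient_id, ep.onset_at))
        if e and ep.max_stage == e.peak_stage:
            exact += 1
print(f"planted episodes: {len(truth.episodes)}; recovered exactly: {exact}")
print(f"event stream written to {out}/synthetic_cohort.csv")
# With zero noise every planted episode must be recovered with the
# exact onset time and peak stage — the generator's construction margin
# keeps planted ratios strictly inside the KDIGO stage bands.
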