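"""Build the AKI clinical summary for one simulated patient and write
it as JSON and a self-contained HTML page.
"""

from pathlib import Path

from aki_cds import (
    SimulationConfig, build_dashboard, dashboard_to_html, dashboard_to_json,
    detect, generate_cohort,
)

cohort, truth = generate_cohort(SimulationConfig(n_patients=50, seed=3, aki_incidence=0.5))
pid = truth.episodes[0].patient_id  # a patient with a planted episode
patient = cohort.get(pid)
summary = build_dashboard(patient, detect(patient).alerts)

print(f"patient {pid}: {len(summary.alert_history)} alert(s), "
      f"{len(summary.creatinine_trend)} creatinine points, "
      f"{len(summary.meds_may_worsen_aki)} risk med(s), "
      f"{len(summary.fluid_balance_by_interval)} fluid intervals")
last_iv, net = summary.fluid_balance_by_interval[-1]
print(f"last 8-h shift net fluid balance: {net:+.0f} mL")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
(out / "dashboard_demo.json").write_text(dashboard_to_json(summary))
(out / "dashboard_demo.html").write_text(dashboard_to_html(summary))
print(f"wrote {out}/dashboard_demo.json and .html")
# The summary is a pure function of events up to as_of: alert history,
# lab trends, the two medication panels, shift-level fluid balance and
# urine output, vitals, infection markers and visit history.
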