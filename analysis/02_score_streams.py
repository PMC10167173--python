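"""Step 2 — score the cohort under both scenarios.

Reads the cohort written by step 1, computes the periodic early-warning
score at every nurse observation and the continuous 0-5 instability score at
every monitored minute (after median smoothing), and tabulates how often
each scenario alerts.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from wardalert.cohort import read_cohort
from wardalert.pipeline import PipelineConfig, score_cohort

COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not (COHORT_DIR / "vitals.csv").exists():
        raise SystemExit("cohort not found — run analysis/01_simulate_cohort.py first")
    cohort = read_cohort(COHORT_DIR / "vitals.csv", COHORT_DIR / "observations.csv",
                         COHORT_DIR / "events.csv")
    series = score_cohort(cohort, PipelineConfig())

    summary = {}
    for scenario in ("periodic", "continuous"):
        entries = sum(len(series[a.admission_id][scenario].entries) for a in cohort)
        alerts = sum(len(series[a.admission_id][scenario].alert_minutes()) for a in cohort)
        alerting_adm = sum(
            len(series[a.admission_id][scenario].alert_minutes()) > 0 for a in cohort)
        summary[scenario] = {"score_entries": entries, "alerting_entries": alerts,
                             "admissions_with_any_alert": alerting_adm}
        print(f"{scenario}: {entries} scored entries, {alerts} at/above threshold, "
              f"{alerting_adm}/{len(cohort)} admissions ever alert")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "score_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote {(RESULTS / 'score_summary.json').relative_to(ROOT)}")


if __name__ == "__main__":
    main()
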