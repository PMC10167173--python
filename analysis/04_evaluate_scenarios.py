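"""Step 4 — full evaluation report.

Runs the complete pipeline (eligibility filter, scoring, episode model,
metrics with confidence intervals, lead times, detection curves, and the
alert-burden analysis) on the step-1 cohort and prints the headline
comparison between the periodic and continuous scenarios.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import dataclasses

from wardalert.pipeline import PipelineConfig, run_pipeline

COHORT_DIR = ROOT / "scratch" / "cohort"
OUT_DIR = ROOT / "results" / "evaluation"


def main() -> None:
    if not (COHORT_DIR / "vitals.csv").exists():
        raise SystemExit("cohort not found — run analysis/01_simulate_cohort.py first")
    cfg = PipelineConfig(vitals_path=str(COHORT_DIR / "vitals.csv"),
                         observations_path=str(COHORT_DIR / "observations.csv"),
                         events_path=str(COHORT_DIR / "events.csv"),
                         out_dir=str(OUT_DIR), seed=11)
    report = run_pipeline(cfg)

    for sc in ("periodic", "continuous"):
        m = report["scenarios"][sc]["metrics"]
        lead = report["scenarios"][sc]["lead_times"]
        if "undefined" in m:
            print(f"{sc}: {m['undefined']}")
            continue
        print(f"{sc}: sensitivity {m['sensitivity_pct']}% "
              f"(CI {m['sensitivity_ci_pct'][0]}-{m['sensitivity_ci_pct'][1]}%), "
              f"PPV {m['ppv']}, NNE {m['nne']}, "
              f"{m['warnings_per_patient_day']} warnings/patient-day, "
              f"median lead {lead['median_h'] if lead['median_h'] is None else round(lead['median_h'], 1)} h")
    burden = report["alert_burden"]["burden_120h"]
    if "undefined" not in burden:
        print(f"alert burden (first 120 h): escalation median "
              f"{burden['eoc_median_pct']:.2f}% vs non-escalation "
              f"{burden['non_eoc_median_pct']:.2f}% "
              f"(Mann-Whitney U={burden['mann_whitney']['u']:.0f}, "
              f"p={burden['mann_whitney']['p']:.2g})")
    bins = report["alert_burden"]["prelude_bins"]
    print("prelude alerting medians: " + ", ".join(
        f"{b['bin']}={b['median_pct']:.1f}%" for b in bins if b["median_pct"] is not None))
    print(f"report written to {OUT_DIR.relative_to(ROOT) / 'report.json'}")


if __name__ == "__main__":
    main()
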