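"""Step 3 — build warning episodes and classify them.

Chains each scenario's alerts into 4-hour warning periods (extended from
each in-period alert, truncated at escalations), tiles the remaining
monitored time into negative segments of at most 8 h, and classifies every
episode against the effective escalations.  Writes the per-scenario
contingency counts.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from wardalert.cohort import read_cohort
from wardalert.episodes import ContingencyTable, evaluate_admission
from wardalert.pipeline import PipelineConfig, score_cohort

COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not (COHORT_DIR / "vitals.csv").exists():
        raise SystemExit("cohort not found — run analysis/01_simulate_cohort.py first")
    cohort = read_cohort(COHORT_DIR / "vitals.csv", COHORT_DIR / "observations.csv",
                         COHORT_DIR / "events.csv")
    series = score_cohort(cohort, PipelineConfig())

    rows = []
    for scenario in ("periodic", "continuous"):
        total = ContingencyTable(0, 0, 0, 0, 0.0)
        for a in cohort:
            ep = evaluate_admission(a, series[a.admission_id][scenario].alert_minutes(),
                                    scenario)
            total = total + ep.table
        rows.append({"scenario": scenario, "tp": total.tp, "fp": total.fp,
                     "tn": total.tn, "fn": total.fn, "n_eoc": total.n_eoc,
                     "patient_days": round(total.patient_days, 1)})
        print(f"{scenario}: TP={total.tp} FP={total.fp} TN={total.tn} FN={total.fn} "
              f"(escalations={total.n_eoc}, conservation TP+FN==EOC: "
              f"{total.tp + total.fn == total.n_eoc})")
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "contingency.csv", index=False)
    print(f"wrote {(RESULTS / 'contingency.csv').relative_to(ROOT)}")


if __name__ == "__main__":
    main()
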