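"""Step 1 — simulate the study cohort.

Generates a 300-admission synthetic ward cohort under the default study
conditions (7% escalations, 79% per-minute availability, 11% monitoring
discontinuation, 120 h median stay, 8-hourly nurse observations) and writes
the three cohort CSVs.  Raw per-minute streams are large, so they go under
scratch/; the summary table goes under results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from wardalert.cohort import cohort_summary, validate_admission, write_cohort
from wardalert.synthetic import CohortParams, generate_cohort

PARAMS = CohortParams(n_admissions=300, seed=11)
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = generate_cohort(PARAMS)
    paths = write_cohort(cohort, COHORT_DIR)
    n_violations = sum(len(validate_admission(a)) for a in cohort)
    summary = cohort_summary(cohort)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"simulated {summary['n_admissions']} admissions "
          f"({summary['patient_days']:.0f} patient-days, "
          f"median stay {summary['median_los_h']:.0f} h)")
    print(f"  escalation admissions: {100 * summary['eoc_fraction']:.1f}% "
          f"(target 7%)")
    print(f"  per-minute availability: {100 * summary['availability']:.1f}% "
          f"(target 79%)")
    print(f"  monitoring discontinued: {100 * summary['discontinuation_fraction']:.1f}% "
          f"(target 11%)")
    print(f"  eligibility violations: {n_violations}")
    for p in paths:
        print(f"  wrote {p.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
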