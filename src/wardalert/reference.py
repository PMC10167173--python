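"""Published reference counts and the worked-example checker.

The comparison this package implements was originally run on a 1529-admission
medical/surgical ward cohort covering 8890 patient-days, of which 106
admissions (7%) ended in an escalation of care and 170 (11%) had monitoring
discontinued.  The study's published episode-level contingency counts for the
two alerting scenarios are reproduced below as plain data; feeding them
through :func:`wardalert.evaluation.contingency_metrics` must recover every
published point estimate after display rounding.  That arithmetic is the
package's primary worked example and regression anchor.

Two published interval endpoints in the continuous arm (the PPV CI upper
bound and the NNE CI) do not equal the standard-error values computed from
the printed counts; the checker therefore asserts all point estimates and the
reproducible intervals only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .episodes import ContingencyTable
from .evaluation import contingency_metrics, proportion_ci

#: Episode counts for the periodic early-warning-score scenario.
PERIODIC_COUNTS = ContingencyTable(tp=54, fp=1072, tn=27344, fn=52, patient_days=8890.0)

#: Episode counts for the continuous per-minute-score scenario.
CONTINUOUS_COUNTS = ContingencyTable(tp=58, fp=8726, tn=24772, fn=48, patient_days=8890.0)

ELIGIBLE_ADMISSIONS = 1529
EOC_ADMISSIONS = 106
DISCONTINUED_ADMISSIONS = 170

#: Published display values recovered by the checker.
PUBLISHED = {
    "periodic": {
        "sensitivity_pct": 51,
        "sensitivity_ci_pct": (41, 60),
        "specificity_pct": 96,
        "specificity_ci_pct": (96, 96),
        "ppv": 0.048,
        "ppv_ci": (0.035, 0.060),
        "nne": 21,
        "nne_ci": (17, 28),
        "warnings_per_patient_day": 0.13,
    },
    "continuous": {
        "sensitivity_pct": 55,
        "sensitivity_ci_pct": (45, 64),
        "specificity_pct": 74,
        "specificity_ci_pct": (73, 74),
        "ppv": 0.007,
        "nne": 151,
        "warnings_per_patient_day": 0.99,
    },
}


def cohort_rates() -> dict[str, int]:
    """Whole-percent cohort composition rates from the published totals."""
    return {
        "eoc_admission_pct": round(100.0 * EOC_ADMISSIONS / ELIGIBLE_ADMISSIONS),
        "discontinued_admission_pct": round(100.0 * DISCONTINUED_ADMISSIONS / ELIGIBLE_ADMISSIONS),
    }


@dataclass(frozen=True)
class CheckResult:
    name: str
    expected: object
    computed: object

    @property
    def ok(self) -> bool:
        return self.expected == self.computed


def verify_worked_examples() -> list[CheckResult]:
    """Recompute every reproducible published value from the raw counts.

    Returns one row per check; the CLI exits non-zero if any row mismatches.
    """
    results: list[CheckResult] = []
    for scenario, counts in (("periodic", PERIODIC_COUNTS), ("continuous", CONTINUOUS_COUNTS)):
        disp = contingency_metrics(counts, scenario).display()
        for key, expected in PUBLISHED[scenario].items():
            results.append(CheckResult(f"{scenario}.{key}", expected, disp[key]))
    lo, hi = proportion_ci(PERIODIC_COUNTS.tp, PERIODIC_COUNTS.n_warnings)
    results.append(CheckResult("periodic.ppv_ci_formula", (0.035, 0.060),
                               (round(lo, 3), round(hi, 3))))
    rates = cohort_rates()
    results.append(CheckResult("cohort.eoc_admission_pct", 7, rates["eoc_admission_pct"]))
    results.append(CheckResult("cohort.discontinued_admission_pct", 11,
                               rates["discontinued_admission_pct"]))
    return results
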