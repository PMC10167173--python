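"""Step 5 — worked-example check against the published study arithmetic.

Feeds the published episode-level contingency counts (1529 eligible
admissions, 8890 patient-days) through the package's metric functions and
verifies that every reproducible printed value is recovered after display
rounding.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from wardalert.reference import verify_worked_examples

RESULTS = ROOT / "results"


def main() -> None:
    checks = verify_worked_examples()
    df = pd.DataFrame([{"check": c.name, "expected": str(c.expected),
                        "computed": str(c.computed), "ok": c.ok} for c in checks])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "reference_checks.csv", index=False)
    n_ok = int(df["ok"].sum())
    for c in checks:
        print(f"{'ok  ' if c.ok else 'FAIL'} {c.name}: expected {c.expected}, "
              f"computed {c.computed}")
    print(f"{n_ok}/{len(checks)} checks passed; "
          f"wrote {(RESULTS / 'reference_checks.csv').relative_to(ROOT)}")
    if n_ok != len(checks):
        raise SystemExit(1)


if __name__ == "__main__":
    main()
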