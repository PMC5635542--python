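"""Apply the inclusion rules and summarise the analysis cohort.

Reads results/cohort.csv, removes prevalent cases, carriers with under a
year of follow-up and pre-1997 enrollments, then writes the per-series
baseline table (results/baseline.csv) and the exclusion audit
(results/exclusions.csv).

Run:  python analysis/02_cohort_baseline.py   (after 01_simulate_cohorts.py)
"""

from pathlib import Path

import pandas as pd

from plsd.cohort import apply_inclusion_criteria, read_cohort
from plsd.reporting import baseline_table

OUT = Path("results")


def main() -> None:
    records = read_cohort(OUT / "cohort.csv")
    cohort, report = apply_inclusion_criteria(records)
    print(f"input {report.n_input}, included {report.n_included}, "
          f"excluded {report.n_excluded} {report.counts}")

    base = baseline_table(cohort)
    base.to_csv(OUT / "baseline.csv", float_format="%.2f")
    print(base.round(2).to_string())

    pd.DataFrame(sorted(report.excluded.items()), columns=["id", "reason"]).to_csv(
        OUT / "exclusions.csv", index=False
    )
    print(f"wrote {OUT / 'baseline.csv'} and {OUT / 'exclusions.csv'}")


if __name__ == "__main__":
    main()
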