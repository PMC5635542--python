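"""Crude survival after first cancer and time-from-inclusion to CRC.

Kaplan-Meier overall survival from first CRC / extra-colonic cancer per
series at 5 and 10 years with a Mantel-Cox series comparison, plus the
proportion of carriers diagnosed with CRC by 5 and 10 years after
inclusion.  Writes results/survival_summary.csv.

Run:  python analysis/05_survival.py   (after 01)
"""

import warnings
from pathlib import Path

from plsd.cohort import apply_inclusion_criteria, first_event_age, read_cohort
from plsd.reporting import _survival_summary
from plsd.survival import km_event_from_inclusion, logrank_test, survival_at

OUT = Path("results")


def main() -> None:
    cohort, _ = apply_inclusion_criteria(read_cohort(OUT / "cohort.csv"))
    summary, notes = _survival_summary(cohort)
    summary.to_csv(OUT / "survival_summary.csv", index=False)
    for n in notes:
        print(f"note: {n}")
    print(summary.to_string(index=False))

    # Mantel-Cox comparison of post-CRC survival between the series
    groups = {}
    for series in sorted({r.series for r in cohort}):
        durs, flags = [], []
        for rec in (r for r in cohort if r.series == series):
            has, age = first_event_age(rec, "crc")
            if has:
                durs.append(rec.age_last_observation - age)
                flags.append(rec.died)
        groups[series] = (durs, flags)
    (da, ea), (db, eb) = groups.values()
    res = logrank_test(da, ea, db, eb)
    print(
        f"post-CRC survival, series comparison: chi2(1) = {res.statistic:.3f}, "
        f"p = {res.p_value:.3f} (O/E {res.observed[0]:.0f}/{res.expected[0]:.1f} vs "
        f"{res.observed[1]:.0f}/{res.expected[1]:.1f})"
    )

    for series in groups:
        group = [r for r in cohort if r.series == series]
        curve = km_event_from_inclusion(group, "crc")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p5 = 1 - survival_at(curve, 5.0)[0]
            p10 = 1 - survival_at(curve, 10.0)[0]
        print(
            f"{series}: CRC diagnosed in {100 * p5:.0f}% by 5 years and "
            f"{100 * p10:.0f}% by 10 years after inclusion"
        )
    print(f"wrote {OUT / 'survival_summary.csv'}")


if __name__ == "__main__":
    main()
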