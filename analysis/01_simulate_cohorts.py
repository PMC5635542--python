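"""Generate the synthetic two-series surveillance study.

Builds a Finnish-style series (3-yearly recommended colonoscopy) and a
non-Finnish-style series (2-yearly), each with the enrollment-age,
follow-up and hazard structure the downstream analyses assume, and writes
the pooled cohort to results/cohort.csv.

Run:  python analysis/01_simulate_cohorts.py [seed]
"""

import sys
from pathlib import Path

from plsd.cohort import write_cohort
from plsd.simulate import SimulationConfig, simulate_cohort, simulate_survival_after_cancer

OUT = Path("results")


def main(seed: int = 42) -> None:
    OUT.mkdir(exist_ok=True)
    series = []
    for label, interval, n, sub in (("finnish", 36, 505, 0), ("other", 24, 439, 1)):
        cfg = SimulationConfig(
            n_patients=n,
            seed=seed * 10 + sub,
            series=label,
            recommended_interval_months=interval,
        )
        records = simulate_survival_after_cancer(cfg, simulate_cohort(cfg))
        series.append(records)
        n_crc = sum(any(e.is_crc for e in r.events) for r in records)
        n_dead = sum(r.died for r in records)
        print(f"{label}: {len(records)} carriers, {n_crc} CRC cases, {n_dead} deaths")
    cohort = series[0] + series[1]
    write_cohort(cohort, OUT / "cohort.csv")
    print(f"wrote {len(cohort)} records to {OUT / 'cohort.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
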