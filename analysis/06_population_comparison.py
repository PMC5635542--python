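"""Does population CRC incidence explain the between-series difference?

Compares the Finland-vs-other ratio of age-standardized population CRC
rates with the ratio of carrier cumulative CRC risks at age 70, using the
packaged reference rates.  Writes results/population_comparison.csv.

Run:  python analysis/06_population_comparison.py
"""

from pathlib import Path

import pandas as pd

from plsd.reporting import PopulationComparison
from plsd.tables import load_population_rates

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rates = load_population_rates()
    cmp = PopulationComparison(
        population_rate_a=float(rates.loc["finland", "asr_crc_per_100k"]),
        population_rate_b=float(rates.loc["other", "asr_crc_per_100k"]),
        cohort_q_a=float(rates.loc["finland", "cohort_crc_cum_incidence_70_pct"]),
        cohort_q_b=float(rates.loc["other", "cohort_crc_cum_incidence_70_pct"]),
    )
    df = pd.DataFrame(
        [
            {
                "contrast": "population_asr_per_100k",
                "finland": cmp.population_rate_a,
                "other": cmp.population_rate_b,
                "ratio": cmp.population_ratio,
            },
            {
                "contrast": "carrier_crc_risk_age70_pct",
                "finland": cmp.cohort_q_a,
                "other": cmp.cohort_q_b,
                "ratio": cmp.cohort_ratio,
            },
        ]
    )
    df.to_csv(OUT / "population_comparison.csv", index=False)
    print(df.to_string(index=False))
    print(
        f"population ratio {cmp.population_ratio} vs carrier-risk ratio "
        f"{cmp.cohort_ratio}: the lower Finnish carrier risk tracks the lower "
        "population incidence in direction but is not explained away by it"
    )
    print(f"wrote {OUT / 'population_comparison.csv'}")


if __name__ == "__main__":
    main()
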