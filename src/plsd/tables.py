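"""Access to the packaged reference summary tables.

Three published summary tables of the two-series MLH1 surveillance study
(baseline characteristics, cumulative incidences by age, CRC counts by
months since last colonoscopy) plus the population age-standardized CRC
rates are shipped as small CSV files.  They are inputs for the reporting
diagnostics and the test suite, not outputs of the pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .intervals import BIN_LABELS, IntervalHistogram


def _read(name: str) -> pd.DataFrame:
    with resources.files("plsd.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def load_baseline_reference() -> pd.DataFrame:
    """Per-series baseline table: n, sex counts, observation years, means/SDs."""
    return _read("table3_baseline.csv").set_index("series")


def load_cumulative_incidence_reference() -> pd.DataFrame:
    """Cumulative incidence (%) with 95% CI by series, class, sex and age stop."""
    return _read("table4_cumulative_incidence.csv")


def load_interval_counts_reference() -> pd.DataFrame:
    """CRC counts per months-since-colonoscopy bin, per series."""
    return _read("table5_interval_counts.csv")


def load_population_rates() -> pd.DataFrame:
    """Population ASR (per 100,000) and cohort risk at 70 (%) per region."""
    return _read("population_rates.csv").set_index("region")


def interval_histogram_reference(series: str) -> IntervalHistogram:
    """The packaged per-bin CRC counts for one series as an IntervalHistogram."""
    df = load_interval_counts_reference()
    sub = df[df["series"] == series].set_index("bin")["count"]
    if sub.empty:
        raise KeyError(f"no interval counts for series {series!r}")
    return IntervalHistogram(counts=tuple(int(sub[label]) for label in BIN_LABELS))
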