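"""Report assembly: baseline tables, incidence ratios and the full bundle.

Percentages are rounded to 1 decimal and ratios to 2 decimals using
banker's rounding (round-half-even), the convention of the published
tables.  ``full_report`` is pure: the same cohort and settings always
produce byte-identical output files.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ExclusionReport, PatientRecord, apply_inclusion_criteria, first_event_age
from .incidence import cumulative_incidence_from_cohort
from .intervals import bin_months, interval_cancer_rate, mean_months, months_from_cohort
from .survival import crude_survival, survival_at


@dataclass(frozen=True)
class PopulationComparison:
    """Population vs carrier-cohort incidence contrast between two regions."""

    population_rate_a: float  # age-standardized, per 100,000
    population_rate_b: float
    cohort_q_a: float         # cumulative incidence at the reference age, percent
    cohort_q_b: float

    @property
    def population_ratio(self) -> float:
        return incidence_ratio(self.population_rate_a, self.population_rate_b)

    @property
    def cohort_ratio(self) -> float:
        return incidence_ratio(self.cohort_q_a, self.cohort_q_b)


def incidence_ratio(a: float, b: float) -> float:
    """Ratio a/b rounded to 2 decimals (round-half-even)."""
    if b <= 0:
        raise ValueError(f"denominator rate must be positive, got {b}")
    return round(a / b, 2)


def baseline_table(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-series baseline summary with an 'all' row (SD uses n-1).

    Columns: subjects, sex counts, observation years, mean/SD age at
    inclusion and follow-up.  SDs are NaN below two subjects; an empty
    series yields a zero row.
    """
    rows = {}
    series_labels = sorted({rec.series for rec in cohort})
    for label in series_labels + ["all"]:
        group = [r for r in cohort if label == "all" or r.series == label]
        ages = np.array([r.age_inclusion for r in group])
        fup = np.array([r.followup_years for r in group])
        rows[label] = {
            "n_subjects": len(group),
            "n_male": sum(r.sex == "male" for r in group),
            "n_female": sum(r.sex == "female" for r in group),
            "observation_years": float(fup.sum()) if group else 0.0,
            "age_inclusion_mean": float(ages.mean()) if group else math.nan,
            "age_inclusion_sd": float(ages.std(ddof=1)) if len(group) > 1 else math.nan,
            "followup_mean": float(fup.mean()) if group else math.nan,
            "followup_sd": float(fup.std(ddof=1)) if len(group) > 1 else math.nan,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "series"
    return df


def _incidence_summary(
    cohort: Sequence[PatientRecord], cancer_class: str, age_stops=(40, 50, 60, 70)
) -> pd.DataFrame:
    """Per-series cumulative incidence at decade stops, published-table layout."""
    rows = []
    for series in sorted({r.series for r in cohort}):
        group = [r for r in cohort if r.series == series]
        table, curve = cumulative_incidence_from_cohort(group, cancer_class)
        band_stops = np.array([hi for _, hi in table.bands])
        cum_py = np.cumsum(table.person_years)
        cum_ca = np.cumsum(table.n_first_cancers)
        for stop in age_stops:
            i = int(np.searchsorted(band_stops, stop))
            lo, hi = curve.ci_at(stop)
            rows.append(
                {
                    "series": series,
                    "cancer_class": cancer_class,
                    "age_stop": stop,
                    "obs_years": round(float(cum_py[i]), 1),
                    "n_cancers": int(cum_ca[i]),
                    "cum_incidence_pct": round(100.0 * curve.q_at(stop), 1),
                    "ci_low_pct": round(100.0 * lo, 1),
                    "ci_high_pct": round(100.0 * hi, 1),
                }
            )
    return pd.DataFrame(rows)


def _interval_summary(
    cohort: Sequence[PatientRecord], planned_intervals: Mapping[str, int]
) -> tuple[pd.DataFrame, list[str]]:
    frames, notes = [], []
    for series in sorted({r.series for r in cohort}):
        months = months_from_cohort(cohort, series=series)
        n_crc = sum(
            1 for r in cohort if r.series == series and any(e.is_crc for e in r.events)
        )
        if n_crc > len(months):
            notes.append(
                f"{series}: {n_crc - len(months)} CRC case(s) without recorded "
                "colonoscopy-to-CRC months"
            )
        if not months:
            notes.append(f"{series}: no CRCs with recorded months; interval table skipped")
            continue
        hist = bin_months(months)
        df = hist.to_frame()
        df.insert(0, "series", series)
        planned = planned_intervals.get(series)
        if planned is not None:
            mean, sd = mean_months(months)
            df["planned_interval_months"] = planned
            df["interval_cancer_rate_pct"] = round(
                100.0 * interval_cancer_rate(months, planned), 1
            )
            df["mean_months"] = round(mean, 1)
            df["sd_months"] = round(sd, 1) if not math.isnan(sd) else math.nan
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return out, notes


def _survival_summary(
    cohort: Sequence[PatientRecord], at_years=(5.0, 10.0)
) -> tuple[pd.DataFrame, list[str]]:
    rows, notes = [], []
    for series in sorted({r.series for r in cohort}):
        group = [r for r in cohort if r.series == series]
        for cls in ("crc", "extracolonic"):
            cases = [r for r in group if first_event_age(r, cls)[0]]
            if not cases:
                notes.append(f"{series}/{cls}: no cases; crude survival skipped")
                continue
            curve = crude_survival(group, cls)
            for t in at_years:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    s, (lo, hi) = survival_at(curve, t)
                rows.append(
                    {
                        "series": series,
                        "cancer_class": cls,
                        "years_after_diagnosis": t,
                        "n_cases": len(cases),
                        "n_deaths": int(sum(r.died for r in cases)),
                        "survival_pct": round(100.0 * s, 1),
                        "ci_low_pct": round(100.0 * lo, 1),
                        "ci_high_pct": round(100.0 * hi, 1),
                    }
                )
    return pd.DataFrame(rows), notes


def full_report(
    records: Sequence[PatientRecord],
    out_dir,
    planned_intervals: Mapping[str, int] | None = None,
    min_followup_years: float = 1.0,
    calendar_cutoff: int | None = 1997,
) -> dict[str, pd.DataFrame]:
    """Run the whole analysis on a cohort file's records and write the bundle.

    Applies the inclusion filter, then writes baseline.csv, exclusions.csv,
    incidence_crc.csv, incidence_extracolonic.csv, intervals.csv,
    survival.csv and a human-readable summary.txt under ``out_dir``.
    Returns the tables keyed by file stem.  Deterministic for fixed input.
    """
    planned_intervals = dict(planned_intervals or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort, report = apply_inclusion_criteria(
        records, min_followup_years=min_followup_years, calendar_cutoff=calendar_cutoff
    )
    tables: dict[str, pd.DataFrame] = {}
    notes: list[str] = []

    tables["baseline"] = baseline_table(cohort).reset_index()
    tables["exclusions"] = pd.DataFrame(
        sorted(report.excluded.items()), columns=["id", "reason"]
    )
    for cls in ("crc", "extracolonic"):
        tables[f"incidence_{cls}"] = _incidence_summary(cohort, cls)
    tables["intervals"], interval_notes = _interval_summary(cohort, planned_intervals)
    notes.extend(interval_notes)
    if any(r.events for r in cohort):
        tables["survival"], surv_notes = _survival_summary(cohort)
        notes.extend(surv_notes)
    else:
        tables["survival"] = pd.DataFrame()
        notes.append("no cancers observed; survival section skipped")

    for stem, df in tables.items():
        df.to_csv(out_dir / f"{stem}.csv", index=False, float_format="%.6f")

    counts = report.counts
    lines = [
        "Surveillance cohort analysis report",
        "===================================",
        f"input records: {report.n_input}",
        f"included: {report.n_included}  excluded: {report.n_excluded} "
        f"(prevalent_cancer={counts['prevalent_cancer']}, "
        f"insufficient_followup={counts['insufficient_followup']}, "
        f"pre_cutoff_calendar={counts['pre_cutoff_calendar']})",
        "",
        "tables: " + ", ".join(f"{s}.csv" for s in tables),
    ]
    if notes:
        lines += ["", "notes:"] + [f"  - {n}" for n in notes]
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return tables
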