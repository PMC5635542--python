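"""Time from last cancer-free colonoscopy to CRC: binning and interval-cancer rates.

Months are binned into the reporting scheme <6, 7-11, 12-17, ..., 42-47,
48-120.  A CRC is an *interval cancer* when it was diagnosed strictly
before the next planned surveillance colonoscopy was due, i.e. when the
months since the last cancer-free colonoscopy are below the recommended
interval (36 for the 3-yearly protocol, 24 for 2-yearly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: (label, low, high) with inclusive integer-month bounds; exhaustive over [0, 120].
BIN_EDGES: tuple[tuple[str, int, int], ...] = (
    ("<6", 0, 6),
    ("7-11", 7, 11),
    ("12-17", 12, 17),
    ("18-23", 18, 23),
    ("24-29", 24, 29),
    ("30-35", 30, 35),
    ("36-41", 36, 41),
    ("42-47", 42, 47),
    ("48-120", 48, 120),
)
BIN_LABELS: tuple[str, ...] = tuple(label for label, _, _ in BIN_EDGES)


@dataclass(frozen=True)
class IntervalHistogram:
    """Counts of CRCs per months-since-colonoscopy bin, with cumulative %."""

    counts: tuple[int, ...]
    labels: tuple[str, ...] = BIN_LABELS

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def cumulative_counts(self) -> tuple[int, ...]:
        return tuple(np.cumsum(self.counts).tolist())

    @property
    def cumulative_percent(self) -> tuple[float, ...] | None:
        """Cumulative percentages to 1 decimal; None when the histogram is empty."""
        if self.total == 0:
            return None
        return tuple(round(100.0 * c / self.total, 1) for c in self.cumulative_counts)

    def to_frame(self) -> pd.DataFrame:
        pct = self.cumulative_percent
        return pd.DataFrame(
            {
                "months_since_colonoscopy": self.labels,
                "n_crc": self.counts,
                "cumulative_n": self.cumulative_counts,
                "cumulative_percent": pct if pct is not None else [math.nan] * len(self.counts),
            }
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bin_months(months: Iterable[float]) -> IntervalHistogram:
    """Bin months since last cancer-free colonoscopy into the reporting scheme.

    Fractional inputs are rounded half-up to integer months first.  Values
    outside [0, 120] are rejected (the error lists the offenders).
    """
    rounded = [_round_half_up(float(m)) for m in months]
    bad = [m for m in rounded if m < 0 or m > 120]
    if bad:
        raise ValueError(f"months outside [0, 120]: {sorted(set(bad))}")
    counts = [0] * len(BIN_EDGES)
    for m in rounded:
        for i, (_, lo, hi) in enumerate(BIN_EDGES):
            if lo <= m <= hi:
                counts[i] += 1
                break
    return IntervalHistogram(counts=tuple(counts))


def expand_histogram(hist: IntervalHistogram) -> list[int]:
    """Representative integer months (one bin-lower-edge value per count)."""
    months: list[int] = []
    for (label, lo, hi), c in zip(BIN_EDGES, hist.counts):
        months.extend([lo] * c)
    return months


def interval_cancer_rate(
    data: IntervalHistogram | Sequence[float], planned_interval_months: int
) -> float:
    """Proportion of CRCs diagnosed strictly before the next planned colonoscopy.

    Accepts raw months or a binned histogram; for a histogram the planned
    interval must fall on a bin boundary (as 24 and 36 do), otherwise the
    raw months are required.  Undefined (raises) when there are no CRCs.
    """
    if isinstance(data, IntervalHistogram):
        if data.total == 0:
            raise ValueError("interval-cancer rate undefined: no CRCs")
        below = 0
        for (label, lo, hi), c in zip(BIN_EDGES, data.counts):
            if hi < planned_interval_months:
                below += c
            elif lo < planned_interval_months:
                raise ValueError(
                    f"planned interval {planned_interval_months} falls inside bin "
                    f"{label}; pass raw months instead"
                )
        return below / data.total
    months = [float(m) for m in data]
    if not months:
        raise ValueError("interval-cancer rate undefined: no CRCs")
    return sum(m < planned_interval_months for m in months) / len(months)


def mean_months(months: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of months since last colonoscopy.

    The SD is NaN for a single observation; empty input raises.
    """
    if len(months) == 0:
        raise ValueError("mean_months requires at least one observation")
    arr = np.asarray(months, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else math.nan
    return mean, sd


def months_from_cohort(records, series: str | None = None) -> list[int]:
    """Collect recorded colonoscopy-to-CRC months from CRC cases in a cohort."""
    out = []
    for rec in records:
        if series is not None and rec.series != series:
            continue
        if rec.months_colonoscopy_to_crc is not None and any(ev.is_crc for ev in rec.events):
            out.append(rec.months_colonoscopy_to_crc)
    return out
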