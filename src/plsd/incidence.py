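"""Person-year tabulation and the life-table cumulative-incidence estimator.

Observation time is allocated to 5-year age bands from age 25; the annual
incidence rate (AIR) in a band is first cancers divided by person-years.
Cumulative incidence Q is built by the yearly recursion

    Q(age) = Q(age-1) + [1 - Q(age-1)] * AIR(age),        Q(24) = 0,

where AIR(age) is the annual rate of the band containing ``age`` (zero
incidence is assumed before 25 and for ages not covered by an exposed
band).  The equivalent hazard scale H = -ln(1-AIR) with
SE_H = SE_AIR / (1-AIR) carries the standard-error propagation: the
cumulative hazard is a sum of independent per-band terms, and
SE_Q = (1-Q) * SE(cumulative hazard).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import AGE_TOL, CancerClass, PatientRecord, first_event_age

#: Default 5-year age bands, half-open [start, start+5).
DEFAULT_BANDS: tuple[tuple[int, int], ...] = tuple((a, a + 5) for a in range(25, 75, 5))

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AgeBandTable:
    """Person-years, first-cancer counts and annual rates per 5-year band."""

    bands: tuple[tuple[int, int], ...]
    person_years: np.ndarray
    n_first_cancers: np.ndarray
    air: np.ndarray | None = None
    se_air: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.person_years < 0) or np.any(self.n_first_cancers < 0):
            raise ValueError("person_years and n_first_cancers must be non-negative")

    @property
    def undefined(self) -> np.ndarray:
        """Bands with zero exposure, where the annual rate is undefined."""
        return self.person_years <= 0

    def band_index(self, age: float) -> int | None:
        for i, (lo, hi) in enumerate(self.bands):
            if lo <= age < hi:
                return i
        return None

    def air_for_age(self, age: float) -> float:
        """Annual rate of the band containing ``age``; 0 outside exposed bands."""
        if self.air is None:
            raise ValueError("annual rates not computed; call annual_incidence_rates first")
        i = self.band_index(age)
        if i is None or self.undefined[i]:
            return 0.0
        return float(self.air[i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "age_start": [lo for lo, _ in self.bands],
                "age_stop": [hi for _, hi in self.bands],
                "person_years": self.person_years,
                "n_first_cancers": self.n_first_cancers,
            }
        )
        if self.air is not None:
            df["air"] = self.air
            df["se_air"] = self.se_air
        return df


@dataclass(frozen=True)
class CumulativeIncidenceCurve:
    """Q(age) with standard errors and symmetric 95% CIs, per integer age."""

    age: np.ndarray
    q: np.ndarray
    se_q: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    band_h: np.ndarray = field(default_factory=lambda: np.array([]))
    band_se_h: np.ndarray = field(default_factory=lambda: np.array([]))

    def q_at(self, age: int) -> float:
        i = int(np.searchsorted(self.age, age))
        if i >= len(self.age) or self.age[i] != age:
            raise ValueError(f"age {age} outside curve range {self.age[0]}..{self.age[-1]}")
        return float(self.q[i])

    def ci_at(self, age: int) -> tuple[float, float]:
        i = int(np.searchsorted(self.age, age))
        if i >= len(self.age) or self.age[i] != age:
            raise ValueError(f"age {age} outside curve range {self.age[0]}..{self.age[-1]}")
        return float(self.ci_low[i]), float(self.ci_high[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.age,
                "Q": self.q,
                "SE_Q": self.se_q,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def tabulate_person_years(
    cohort: Sequence[PatientRecord],
    cancer_class: CancerClass,
    censor_policy: Literal["any", "class"] = "any",
    bands: Sequence[tuple[int, int]] = DEFAULT_BANDS,
) -> AgeBandTable:
    """Allocate observation time and first cancers to 5-year age bands.

    Each patient contributes from max(25, age at inclusion) to the first
    cancer or censoring, split fractionally across bands.  Under the
    default ``censor_policy="any"`` the first cancer of *any* class ends
    incidence follow-up ("to age at last observation or first cancer");
    ``"class"`` follows each patient to the first cancer of the analysed
    class, ignoring earlier cancers of other classes.

    Raises if a record still carries a prevalent cancer — input must have
    passed :func:`plsd.cohort.apply_inclusion_criteria`.
    """
    bands = tuple((int(lo), int(hi)) for lo, hi in bands)
    floor = bands[0][0]
    ceiling = bands[-1][1]
    edges = np.array([lo for lo, _ in bands] + [ceiling], dtype=float)
    py = np.zeros(len(bands))
    counts = np.zeros(len(bands), dtype=int)

    for rec in cohort:
        if any(ev.age_at_diagnosis <= rec.age_inclusion + AGE_TOL for ev in rec.events):
            raise ValueError(
                f"patient {rec.id}: prevalent cancer in incidence input; "
                "apply the inclusion filter first"
            )
        has_class, age_class = first_event_age(rec, cancer_class)
        if censor_policy == "class":
            event = has_class
            stop = age_class if has_class else rec.age_last_observation
        elif censor_policy == "any":
            has_any, age_any = first_event_age(rec, "any")
            stop = age_any if has_any else rec.age_last_observation
            # the analysed class scores only if it is (part of) the first cancer
            event = has_class and has_any and age_class <= age_any + AGE_TOL
        else:
            raise ValueError(f"unknown censor_policy {censor_policy!r}")

        start = max(float(floor), rec.age_inclusion)
        stop = min(stop, float(ceiling))
        if stop <= start:
            continue  # observation entirely before the first band
        lo_clip = np.clip(edges[:-1], start, stop)
        hi_clip = np.clip(edges[1:], start, stop)
        py += hi_clip - lo_clip
        if event:
            event_age = min(age_class, stop)
            if floor <= event_age < ceiling:
                counts[int(np.searchsorted(edges, event_age, side="right")) - 1] += 1
    return AgeBandTable(bands=bands, person_years=py, n_first_cancers=counts)


def annual_incidence_rates(table: AgeBandTable) -> AgeBandTable:
    """Fill AIR = cancers / person-years and its Poisson standard error.

    SE_AIR = sqrt(n_cancers) / person_years (Poisson count over fixed
    person-time).  Bands with zero exposure are flagged undefined (NaN) and
    treated as rate 0 downstream, with a warning.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        air = np.where(table.person_years > 0, table.n_first_cancers / table.person_years, np.nan)
        se = np.where(
            table.person_years > 0, np.sqrt(table.n_first_cancers) / table.person_years, np.nan
        )
    if np.any(table.undefined & (np.asarray(table.n_first_cancers) > 0)):
        raise ValueError("cancers recorded in a band with zero person-years")
    return replace(table, air=air, se_air=se)


def hazard_transform(air: float | np.ndarray, se_air: float | np.ndarray):
    """Annual rate -> hazard scale: H = -ln(1-AIR), SE_H = SE_AIR/(1-AIR)."""
    air = np.asarray(air, dtype=float)
    se_air = np.asarray(se_air, dtype=float)
    if np.any(air < 0) or np.any(air >= 1):
        raise ValueError("AIR must lie in [0, 1) for the hazard transform")
    h = -np.log1p(-air)
    se_h = se_air / (1.0 - air)
    if h.ndim == 0:
        return float(h), float(se_h)
    return h, se_h


def cumulative_incidence(
    table: AgeBandTable,
    age_start: int = 25,
    age_stop: int = 70,
    seq_method: Literal["hazard", "recursion"] = "hazard",
) -> CumulativeIncidenceCurve:
    """Run the yearly cumulative-incidence recursion over the band rates.

    One recursion step per integer year of age from ``age_start`` to
    ``age_stop``; the step for age ``a`` uses the annual rate of the band
    containing ``a`` (zero when no exposed band covers it).  Standard
    errors are propagated on the hazard scale by default (``"hazard"``):
    Var(cumH) = sum_b (years_used_b * SE_H_b)^2 over independent bands and
    SE_Q = (1-Q)*SE(cumH).  ``"recursion"`` instead applies the per-year
    delta recursion Var Q(a) = (1-AIR_a)^2 Var Q(a-1) + (1-Q(a-1))^2
    Var AIR_a with every year treated as independent; because one band's
    rate estimate is shared by its five years, this variant understates
    the variance and is kept for comparison only.

    The 95% CI is the symmetric normal interval Q +/- 1.96*SE_Q clipped
    to [0, 1].
    """
    if age_stop <= age_start:
        raise ValueError(f"age_stop ({age_stop}) must exceed age_start ({age_start})")
    if table.air is None:
        table = annual_incidence_rates(table)
    if np.any(table.undefined):
        warnings.warn(
            "bands with zero person-years treated as annual rate 0", stacklevel=2
        )

    n_bands = len(table.bands)
    air_b = np.where(table.undefined, 0.0, np.nan_to_num(table.air))
    se_b = np.where(table.undefined, 0.0, np.nan_to_num(table.se_air))

    ages = np.arange(age_start, age_stop + 1)
    q = np.empty(len(ages))
    var_q = np.empty(len(ages))
    years_used = np.zeros(n_bands)  # recursion years drawing on each band

    q_prev = 0.0
    v_prev = 0.0  # per-year recursion variance state
    for k, a in enumerate(ages):
        i = table.band_index(a)
        air = 0.0 if i is None or table.undefined[i] else float(air_b[i])
        se_air = 0.0 if i is None or table.undefined[i] else float(se_b[i])
        q_new = q_prev + (1.0 - q_prev) * air
        if i is not None:
            years_used[i] += 1.0
        if seq_method == "hazard":
            if q_new >= 1.0 - 1e-15:
                var_q[k] = 0.0  # absorbing state: no uncertainty left
            else:
                se_h = se_b / np.where(air_b < 1.0, 1.0 - air_b, np.inf)
                var_cum_h = float(np.sum((years_used * se_h) ** 2))
                var_q[k] = (1.0 - q_new) ** 2 * var_cum_h
        elif seq_method == "recursion":
            v_prev = (1.0 - air) ** 2 * v_prev + (1.0 - q_prev) ** 2 * se_air**2
            var_q[k] = v_prev
        else:
            raise ValueError(f"unknown seq_method {seq_method!r}")
        q[k] = q_new
        q_prev = q_new

    se_q = np.sqrt(var_q)
    ci_low = np.clip(q - Z95 * se_q, 0.0, 1.0)
    ci_high = np.clip(q + Z95 * se_q, 0.0, 1.0)

    safe = air_b < 1.0
    band_h = np.where(safe, -np.log1p(-np.where(safe, air_b, 0.0)), np.inf)
    band_se_h = np.where(safe, se_b / np.where(safe, 1.0 - air_b, 1.0), np.inf)
    return CumulativeIncidenceCurve(
        age=ages, q=q, se_q=se_q, ci_low=ci_low, ci_high=ci_high,
        band_h=band_h, band_se_h=band_se_h,
    )


def cumulative_incidence_from_cohort(
    cohort: Sequence[PatientRecord],
    cancer_class: CancerClass,
    censor_policy: Literal["any", "class"] = "any",
    age_start: int = 25,
    age_stop: int = 70,
    seq_method: Literal["hazard", "recursion"] = "hazard",
) -> tuple[AgeBandTable, CumulativeIncidenceCurve]:
    """Convenience pipeline: tabulate, rate, then run the recursion."""
    table = annual_incidence_rates(tabulate_person_years(cohort, cancer_class, censor_policy))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = cumulative_incidence(table, age_start, age_stop, seq_method)
    return table, curve
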