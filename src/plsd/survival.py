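"""Crude Kaplan-Meier survival and the Mantel-Cox (log-rank) comparison.

Crude survival runs from the first cancer of the analysed class to death
(any cause) or last observation; carriers who never develop the cancer do
not enter the crude-survival analysis.  Time-from-inclusion-to-event
curves reuse the same product-limit machinery with diagnosis as the event.

The product-limit fit is delegated to :class:`lifelines.KaplanMeierFitter`
(log-log / exponential-Greenwood 95% CIs, events before censorings at tied
times); the Greenwood variance is evaluated on its event table.  The
log-rank test is computed here because the result exposes per-group
observed and expected event counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import CancerClass, PatientRecord, first_event_age


@dataclass(frozen=True)
class SurvivalCurve:
    """A right-continuous product-limit step function with Greenwood variance."""

    times: np.ndarray          # distinct observed times (events and censorings)
    survival: np.ndarray       # S(t) immediately after each time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "S": self.survival,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "greenwood_var": self.greenwood_var,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass(frozen=True)
class LogrankResult:
    """1-df Mantel-Cox test over pooled event times."""

    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def km_estimate(durations: Sequence[float], event_flags: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood variance and log-log CI."""
    durations = np.asarray(durations, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if durations.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    if durations.shape != flags.shape:
        raise ValueError("durations and event_flags must have equal length")
    if np.any(durations < 0):
        raise ValueError("durations must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=flags)
    table = kmf.event_table  # indexed by time, includes t=0 row
    times = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    observed = table["observed"].to_numpy(dtype=float)

    # survival and Greenwood's cumulative variance term at each tabled time
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, observed / at_risk, 0.0)
        surv = np.cumprod(1.0 - frac)
        gw_term = np.where(
            (at_risk > 0) & (at_risk > observed),
            observed / (at_risk * (at_risk - observed)),
            np.where(observed > 0, np.inf, 0.0),
        )
    gw_var = surv**2 * np.cumsum(gw_term)
    gw_var = np.where(surv == 0.0, 0.0, gw_var)

    ci = kmf.confidence_interval_survival_function_
    ci_low = np.clip(ci.iloc[:, 0].to_numpy(dtype=float), 0.0, 1.0)
    ci_high = np.clip(ci.iloc[:, 1].to_numpy(dtype=float), 0.0, 1.0)

    keep = times >= 0
    return SurvivalCurve(
        times=times[keep],
        survival=surv[keep],
        n_at_risk=at_risk[keep],
        n_events=observed[keep],
        greenwood_var=gw_var[keep],
        ci_low=ci_low[keep],
        ci_high=ci_high[keep],
    )


def survival_at(curve: SurvivalCurve, t: float) -> tuple[float, tuple[float, float]]:
    """Evaluate the step function (right-continuous) at time ``t``.

    Beyond the last observed time the last value is returned with an
    extrapolation warning.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t > curve.times[-1]:
        warnings.warn(
            f"t={t} beyond last observed time {curve.times[-1]}; returning last value",
            stacklevel=2,
        )
    i = int(np.searchsorted(curve.times, t, side="right")) - 1
    if i < 0:
        return 1.0, (1.0, 1.0)
    return float(curve.survival[i]), (float(curve.ci_low[i]), float(curve.ci_high[i]))


def logrank_test(
    durations_a: Sequence[float],
    events_a: Sequence[bool],
    durations_b: Sequence[float],
    events_b: Sequence[bool],
) -> LogrankResult:
    """Two-group 1-df Mantel-Cox test (hypergeometric O-E over pooled times)."""
    da = np.asarray(durations_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    db = np.asarray(durations_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must be nonempty")
    total_events = int(ea.sum() + eb.sum())
    if total_events == 0:
        raise ValueError("log-rank statistic undefined: no events in either group")

    event_times = np.unique(np.concatenate([da[ea], db[eb]]))
    obs_a = exp_a = var = 0.0
    for t in event_times:
        n_a = float(np.sum(da >= t))
        n_b = float(np.sum(db >= t))
        d_a = float(np.sum(ea & (da == t)))
        d_b = float(np.sum(eb & (db == t)))
        n = n_a + n_b
        d = d_a + d_b
        if n <= 0:
            continue
        obs_a += d_a
        exp_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var <= 0:
        # all events in risk sets of one; the statistic degenerates to 0
        stat = 0.0
    else:
        stat = (obs_a - exp_a) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    obs_b = float(ea.sum() + eb.sum()) - obs_a
    exp_b = float(ea.sum() + eb.sum()) - exp_a
    return LogrankResult(
        statistic=float(stat), p_value=p, observed=(obs_a, obs_b), expected=(exp_a, exp_b)
    )


# ---------------------------------------------------------------------------
# Cohort-level conveniences
# ---------------------------------------------------------------------------

def crude_survival(cohort: Sequence[PatientRecord], cancer_class: CancerClass) -> SurvivalCurve:
    """Overall survival from first cancer of the class, all-cause deaths as events.

    Only carriers with a first cancer of the class enter; censoring is at
    last observation (patients confirmed alive when censored).
    """
    durations, flags = [], []
    for rec in cohort:
        has, age = first_event_age(rec, cancer_class)
        if not has:
            continue
        durations.append(rec.age_last_observation - age)
        flags.append(rec.died)
    if not durations:
        raise ValueError(f"no {cancer_class} cases in cohort; crude survival undefined")
    return km_estimate(durations, flags)


def km_event_from_inclusion(
    cohort: Sequence[PatientRecord], cancer_class: CancerClass
) -> SurvivalCurve:
    """Time from inclusion to first diagnosis of the class (1 - S = event proportion)."""
    durations, flags = [], []
    for rec in cohort:
        has, age = first_event_age(rec, cancer_class)
        durations.append((age if has else rec.age_last_observation) - rec.age_inclusion)
        flags.append(has)
    if not durations:
        raise ValueError("empty cohort")
    return km_estimate(durations, flags)
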