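"""Domain types, inclusion/exclusion rules and cohort file I/O.

The unit of observation is one confirmed mismatch-repair variant carrier
followed prospectively from their first planned surveillance colonoscopy.
A record carries the ages that frame the observation window, any cancers
diagnosed (3-digit ICD-9 codes), and — for colorectal cancers — the number
of months since the last cancer-free colonoscopy.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

#: ICD-9 three-position codes counted as colorectal cancer (colon, rectum).
CRC_ICD9 = frozenset({"153", "154"})

#: Tolerance for age-equality comparisons (ages are stored to 2 decimals).
AGE_TOL = 1e-9

CancerClass = Literal["crc", "extracolonic", "any"]
_VALID_CLASSES = ("crc", "extracolonic", "any")

EXCLUSION_REASONS = ("prevalent_cancer", "insufficient_followup", "pre_cutoff_calendar")


class CohortValidationError(ValueError):
    """A record or cohort file violates the data contract."""


@dataclass(frozen=True, order=True)
class CancerEvent:
    """A first (or synchronous-first) invasive cancer diagnosis."""

    age_at_diagnosis: float
    icd9: str

    def __post_init__(self) -> None:
        if not self.age_at_diagnosis > 0:
            raise CohortValidationError(
                f"age_at_diagnosis must be positive, got {self.age_at_diagnosis}"
            )
        if len(self.icd9) != 3:
            raise CohortValidationError(
                f"icd9 must be a 3-character code, got {self.icd9!r}"
            )

    @property
    def is_crc(self) -> bool:
        return self.icd9 in CRC_ICD9


@dataclass(frozen=True)
class PatientRecord:
    """One carrier's prospective observation window and events.

    ``age_inclusion`` is the age at the first prospectively planned
    colonoscopy; observation runs to ``age_last_observation``.  When the
    patient died under observation, ``age_death`` equals
    ``age_last_observation`` (death is the last observation).
    """

    id: str
    series: str
    sex: Literal["male", "female"]
    age_inclusion: float
    year_inclusion: int
    age_last_observation: float
    age_death: float | None = None
    events: tuple[CancerEvent, ...] = ()
    months_colonoscopy_to_crc: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise CohortValidationError(f"{self.id}: sex must be male/female, got {self.sex!r}")
        if self.age_last_observation < self.age_inclusion - AGE_TOL:
            raise CohortValidationError(
                f"{self.id}: age_last_observation ({self.age_last_observation}) "
                f"precedes age_inclusion ({self.age_inclusion})"
            )
        if self.age_death is not None and abs(self.age_death - self.age_last_observation) > 1e-6:
            raise CohortValidationError(
                f"{self.id}: age_death must equal age_last_observation when present "
                f"(death is the last observation)"
            )
        if self.months_colonoscopy_to_crc is not None and self.months_colonoscopy_to_crc < 0:
            raise CohortValidationError(
                f"{self.id}: months_colonoscopy_to_crc must be >= 0, "
                f"got {self.months_colonoscopy_to_crc}"
            )
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.age_at_diagnosis))
        )

    @property
    def followup_years(self) -> float:
        return self.age_last_observation - self.age_inclusion

    @property
    def died(self) -> bool:
        return self.age_death is not None


@dataclass(frozen=True)
class ExclusionReport:
    """Audit trail of the inclusion filter: every removed id, one reason each."""

    excluded: dict[str, str] = field(default_factory=dict)
    n_input: int = 0
    n_included: int = 0

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.excluded.values())
        return {reason: c.get(reason, 0) for reason in EXCLUSION_REASONS}

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass(frozen=True)
class CohortGroup:
    """A surveillance series sharing one recommended colonoscopy interval."""

    label: str
    recommended_interval_months: int
    members: tuple[PatientRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.recommended_interval_months <= 0:
            raise CohortValidationError("recommended_interval_months must be positive")


def _matches_class(event: CancerEvent, cancer_class: CancerClass) -> bool:
    if cancer_class == "any":
        return True
    if cancer_class == "crc":
        return event.is_crc
    if cancer_class == "extracolonic":
        return not event.is_crc
    raise ValueError(f"unknown cancer_class {cancer_class!r}; expected one of {_VALID_CLASSES}")


def first_event_age(record: PatientRecord, cancer_class: CancerClass) -> tuple[bool, float]:
    """Age at the first cancer of the class, or censoring age.

    Synchronous cancers at the same age count as a single event; a patient
    with no event of the class returns ``(False, age_last_observation)``.
    The returned age is clamped to the observation window.
    """
    if cancer_class not in _VALID_CLASSES:
        raise ValueError(
            f"unknown cancer_class {cancer_class!r}; expected one of {_VALID_CLASSES}"
        )
    for ev in record.events:  # events are age-sorted
        if _matches_class(ev, cancer_class):
            age = min(max(ev.age_at_diagnosis, record.age_inclusion), record.age_last_observation)
            return True, age
    return False, record.age_last_observation


def apply_inclusion_criteria(
    records: Sequence[PatientRecord],
    min_followup_years: float = 1.0,
    calendar_cutoff: int | None = 1997,
) -> tuple[list[PatientRecord], ExclusionReport]:
    """Apply the prospective-observation inclusion rules.

    Removes carriers enrolled before ``calendar_cutoff``, carriers with a
    prevalent cancer (any cancer at or before the age of first colonoscopy)
    and carriers with less than ``min_followup_years`` of prospective
    observation.  A record violating several rules is reported once, under
    the first rule in that order.
    """
    included: list[PatientRecord] = []
    excluded: dict[str, str] = {}
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise CohortValidationError(f"duplicate patient id {rec.id!r}")
        seen.add(rec.id)
        if calendar_cutoff is not None and rec.year_inclusion < calendar_cutoff:
            excluded[rec.id] = "pre_cutoff_calendar"
        elif any(ev.age_at_diagnosis <= rec.age_inclusion + AGE_TOL for ev in rec.events):
            excluded[rec.id] = "prevalent_cancer"
        elif rec.followup_years < min_followup_years - AGE_TOL:
            excluded[rec.id] = "insufficient_followup"
        else:
            included.append(rec)
    report = ExclusionReport(excluded=excluded, n_input=len(records), n_included=len(included))
    return included, report


# ---------------------------------------------------------------------------
# Cohort file I/O
#
# UTF-8 CSV with header; `events` is a semicolon-separated list of
# `age@icd9` tokens; ages written to 2 decimals.
# ---------------------------------------------------------------------------

_COLUMNS = [
    "id",
    "series",
    "sex",
    "age_inclusion",
    "year_inclusion",
    "age_last_observation",
    "age_death",
    "months_colonoscopy_to_crc",
    "events",
]


def _parse_events(text: str, row: int) -> tuple[CancerEvent, ...]:
    if not text:
        return ()
    events = []
    for token in text.split(";"):
        try:
            age_s, icd9 = token.split("@")
            events.append(CancerEvent(age_at_diagnosis=float(age_s), icd9=icd9))
        except (ValueError, CohortValidationError) as exc:
            raise CohortValidationError(f"row {row}: bad event token {token!r}: {exc}") from exc
    return tuple(events)


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV, validating every row (errors name the row number)."""
    records: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortValidationError(f"{path}: empty file")
        missing = [c for c in _COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortValidationError(f"{path}: missing required column(s) {missing}")
        for i, row in enumerate(reader, start=2):  # header is row 1
            try:
                age_death = float(row["age_death"]) if row["age_death"] else None
                months = (
                    int(row["months_colonoscopy_to_crc"])
                    if row["months_colonoscopy_to_crc"]
                    else None
                )
                rec = PatientRecord(
                    id=row["id"],
                    series=row["series"],
                    sex=row["sex"],
                    age_inclusion=float(row["age_inclusion"]),
                    year_inclusion=int(row["year_inclusion"]),
                    age_last_observation=float(row["age_last_observation"]),
                    age_death=age_death,
                    events=_parse_events(row["events"], i),
                    months_colonoscopy_to_crc=months,
                )
            except CohortValidationError as exc:
                raise CohortValidationError(f"row {i}: {exc}") from exc
            except (ValueError, KeyError) as exc:
                raise CohortValidationError(f"row {i}: unparsable field: {exc}") from exc
            records.append(rec)
    return records


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write a cohort CSV (ages to 2 decimals; round-trips via read_cohort)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in records:
            events = ";".join(f"{ev.age_at_diagnosis:.2f}@{ev.icd9}" for ev in rec.events)
            writer.writerow(
                [
                    rec.id,
                    rec.series,
                    rec.sex,
                    f"{rec.age_inclusion:.2f}",
                    rec.year_inclusion,
                    f"{rec.age_last_observation:.2f}",
                    "" if rec.age_death is None else f"{rec.age_death:.2f}",
                    "" if rec.months_colonoscopy_to_crc is None else rec.months_colonoscopy_to_crc,
                    events,
                ]
            )


def round_ages(record: PatientRecord, ndigits: int = 2) -> PatientRecord:
    """Return a copy with all ages rounded to the file precision."""
    return replace(
        record,
        age_inclusion=round(record.age_inclusion, ndigits),
        age_last_observation=round(record.age_last_observation, ndigits),
        age_death=None if record.age_death is None else round(record.age_death, ndigits),
        events=tuple(
            CancerEvent(round(ev.age_at_diagnosis, ndigits), ev.icd9) for ev in record.events
        ),
    )
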