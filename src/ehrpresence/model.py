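"""Core domain types and interval conventions.

All spells (registrations, coverage periods, presence records, exclusions)
are intervals of calendar dates, CLOSED on both ends: a person registered
``start``..``end`` is registered on both boundary dates.  Two spells are
*adjacent* when ``next.start == prev.end + 1 day``; the *gap* between two
ordered disjoint spells is the number of whole days strictly between them,
so adjacency has gap 0 and a single uncovered day has gap 1.

Open-ended registrations ("still registered") are materialized at load time
to a global censor date — by default the latest data-extract date across
practices — so that all downstream interval algebra works on finite dates.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, fields
from datetime import date, timedelta
from typing import Optional

#: Sentinel practice identifier for presence records whose practice identity
#: was collapsed by merging across practices (``group_on_practice = 0``).
MERGED = "MERGED"

#: Earliest plausible event date; anything earlier is an obvious sentinel
#: (1900-01-01 is the classic placeholder for an unknown date).
PLAUSIBLE_FLOOR = date(1950, 1, 1)


class ContractViolation(ValueError):
    """An operation was called with inputs that violate its preconditions."""


class NoReferenceYear(ValueError):
    """No year qualifies as a normalization reference for a practice."""


class ZeroReferenceRate(ValueError):
    """The reference-period event rate is zero; rates cannot be normalized."""


@dataclass(frozen=True)
class EventRecord:
    """One clinical event: the unit counted in rate estimation.

    Raw tables may carry implausible dates (year 1900 sentinels, future
    dates); these are retained at load and handled by the rate-based
    coverage inference, never silently dropped.
    """

    person_id: str
    practice_id: str
    event_date: date


@dataclass(frozen=True)
class RegistrationRecord:
    """One registration spell with a GP practice, closed interval.

    ``end is None`` means the registration is still open; open ends are
    materialized to the censor date at load time.
    """

    person_id: str
    practice_id: str
    start: date
    end: Optional[date]

    def __post_init__(self) -> None:
        if self.end is not None and self.start > self.end:
            raise ContractViolation(
                f"registration start {self.start} after end {self.end}"
            )

    @property
    def n_days(self) -> int:
        if self.end is None:
            raise ContractViolation("open-ended record has no finite length")
        return (self.end - self.start).days + 1

    def contains(self, d: date) -> bool:
        return self.start <= d and (self.end is None or d <= self.end)


@dataclass(frozen=True)
class PracticeMeta:
    """Per-practice metadata: participation flag and last-extract date."""

    practice_id: str
    in_sail: bool
    extract_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.in_sail and self.extract_date is None:
            raise ContractViolation(
                f"practice {self.practice_id} contributes data but has no extract date"
            )


@dataclass(frozen=True)
class MonthlyRate:
    """Event-recording rate of one practice in one calendar month.

    ``raw_rate`` is the median, over weekday calendar days of the month, of
    the day's total event count, divided by the number of persons registered
    on the 15th.  ``None`` encodes EXCLUDED (at most ``min_registered``
    persons registered that month).
    """

    practice_id: str
    year: int
    month: int
    registered_count: int
    raw_rate: Optional[float]
    normalized_rate: Optional[float] = None


@dataclass(frozen=True)
class PracticeCoverage:
    """Inferred period of usable electronic data at one practice.

    ``data_start`` is always the first day of a calendar month;
    ``data_end`` is either the day before the data extract or the last day
    of the final month that met the rate threshold.  ``None`` fields mean
    the threshold was never met.
    """

    practice_id: str
    data_start: Optional[date]
    data_end: Optional[date]
    reference_year: Optional[int]

    def __post_init__(self) -> None:
        if (
            self.data_start is not None
            and self.data_end is not None
            and self.data_start > self.data_end
        ):
            raise ContractViolation("coverage start after end")


@dataclass(frozen=True)
class PresenceRecord:
    """A cleaned, non-overlapping spell of presence in the dataset.

    ``practice_id`` is :data:`MERGED` when the record spans several
    practices collapsed by grouping.  ``sail_data`` is ``True``/``False``
    when tracked, ``None`` (NOT-TRACKED) when a merged record spans mixed
    availability.
    """

    person_id: str
    practice_id: str
    start: date
    end: date
    sail_data: Optional[bool]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ContractViolation("presence start after end")


@dataclass(frozen=True)
class ExclusionPeriod:
    """A per-person period of known-missing data, subtracted from presence."""

    person_id: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ContractViolation("exclusion start after end")


@dataclass
class Parameters:
    """Tunable parameters of the coverage and presence algorithms.

    threshold
        Normalized event-rate threshold a month must reach to count as
        recorded data (default 0.10, i.e. 10% of the reference-year rate).
    max_gap_days
        Longest gap (whole days strictly between consecutive spells) that is
        closed by attributing it to the second practice; default 30.
    min_registered
        A month counts only if *more than* this many persons are registered
        on the 15th; default 5.
    reference_year_preferred / reference_min_registrations
        Preferred normalization year (2009) and, for practices without data
        then, the minimum number of registration records starting before
        1 January for a year to act as fallback reference (100).
    sustain_months
        Number of consecutive counted months that must hold the threshold
        for the start date to be declared; default 3.
    group_on_sail_data / group_on_practice
        The two aggregation switches: records differing in data
        availability (resp. practice) are never merged when set to 1.
    """

    threshold: float = 0.10
    max_gap_days: int = 30
    min_registered: int = 5
    reference_year_preferred: int = 2009
    reference_min_registrations: int = 100
    sustain_months: int = 3
    group_on_sail_data: int = 1
    group_on_practice: int = 0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ContractViolation("threshold must be > 0")
        if self.max_gap_days < 0:
            raise ContractViolation("max_gap_days must be >= 0")
        if self.sustain_months < 1:
            raise ContractViolation("sustain_months must be >= 1")
        for flag in ("group_on_sail_data", "group_on_practice"):
            if getattr(self, flag) not in (0, 1):
                raise ContractViolation(f"{flag} must be 0 or 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def interval_gap(a: RegistrationRecord, b: RegistrationRecord) -> int:
    """Whole days strictly between ``a.end`` and ``b.start``.

    0 means adjacency (``b`` starts the day after ``a`` ends).  Requires
    same person, ``a`` closed, and ``a`` strictly before ``b``.
    """
    if a.person_id != b.person_id:
        raise ContractViolation("interval_gap across different persons")
    if a.end is None:
        raise ContractViolation("first record is open-ended")
    if a.end >= b.start:
        raise ContractViolation("records overlap or are out of order")
    return (b.start - a.end).days - 1


def month_first(year: int, month: int) -> date:
    return date(year, month, 1)


def month_last(year: int, month: int) -> date:
    return date(year, month, calendar.monthrange(year, month)[1])


def add_months(year: int, month: int, k: int) -> tuple[int, int]:
    """(year, month) shifted by k months, 1-based months."""
    idx = year * 12 + (month - 1) + k
    return idx // 12, idx % 12 + 1
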