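"""Resolve anomalies in raw per-person registration histories.

Registration histories carry occasional administrative errors — duplicate
rows, spells nested inside other spells, partially overlapping spells, and
identical spells at two practices — even though a person can only be
registered with one practice at a time.  The rules here resolve every such
conflict deterministically so that, afterwards, at most one record covers
any calendar day:

* exact duplicates collapse to one row;
* duplicate periods (identical span, different practice) keep the record
  whose practice contributes data, then the lexicographically lower
  practice id — always applied, whatever output options are requested, so
  the same record wins in every run;
* nested records keep the outer (first) record;
* overlaps shorten the first record to end the day before the second
  starts (the second registration is the better-evidenced one).

Resolution order is duplicates -> nested -> overlaps, so the
always-applied duplicate preference acts on raw records before any
interval is mutated.  Every mutation is logged as a
:class:`ConflictReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import ContractViolation, RegistrationRecord


@dataclass(frozen=True)
class ConflictReport:
    """Audit-trail entry: one mutation of a registration history."""

    person_id: str
    conflict_kind: str  # exact_duplicate | duplicate_period | nested | overlap
    records_involved: tuple[str, ...]  # "practice:start..end" keys
    resolution: str


def _key(rec: RegistrationRecord) -> str:
    return f"{rec.practice_id}:{rec.start.isoformat()}..{rec.end.isoformat()}"


def _sorted(history: Iterable[RegistrationRecord]) -> list[RegistrationRecord]:
    # start asc, end desc (longer first, so same-start shorter spells read as
    # nested), then practice id for total determinism
    return sorted(
        history,
        key=lambda r: (
            r.start,
            r.end is not None,  # open end = unbounded = longest first
            -(r.end.toordinal() if r.end is not None else 0),
            r.practice_id,
        ),
    )


def _check_one_person(history: Sequence[RegistrationRecord]) -> None:
    persons = {r.person_id for r in history}
    if len(persons) > 1:
        raise ContractViolation(f"history mixes persons: {sorted(persons)}")


def remove_exact_duplicates(
    history: Sequence[RegistrationRecord],
    reports: Optional[list[ConflictReport]] = None,
) -> list[RegistrationRecord]:
    """Collapse records identical on (practice, start, end) to one."""
    _check_one_person(history)
    seen: dict[tuple, RegistrationRecord] = {}
    for rec in _sorted(history):
        k = (rec.practice_id, rec.start, rec.end)
        if k in seen:
            if reports is not None:
                reports.append(
                    ConflictReport(
                        rec.person_id, "exact_duplicate", (_key(rec),), "dropped copy"
                    )
                )
        else:
            seen[k] = rec
    return _sorted(seen.values())


def resolve_duplicate_periods(
    history: Sequence[RegistrationRecord],
    in_sail: Mapping[str, bool],
    reports: Optional[list[ConflictReport]] = None,
) -> list[RegistrationRecord]:
    """Keep one record per identical (start, end) span.

    Preference: practice contributing data beats one that does not, then
    the lower practice id.  Practices absent from ``in_sail`` count as not
    contributing.
    """
    _check_one_person(history)
    by_span: dict[tuple, list[RegistrationRecord]] = {}
    for rec in history:
        by_span.setdefault((rec.start, rec.end), []).append(rec)
    out = []
    for group in by_span.values():
        group.sort(key=lambda r: (not in_sail.get(r.practice_id, False), r.practice_id))
        winner = group[0]
        out.append(winner)
        for loser in group[1:]:
            if reports is not None:
                reports.append(
                    ConflictReport(
                        loser.person_id,
                        "duplicate_period",
                        (_key(winner), _key(loser)),
                        f"kept {winner.practice_id}",
                    )
                )
    return _sorted(out)


def resolve_nested(
    history: Sequence[RegistrationRecord],
    reports: Optional[list[ConflictReport]] = None,
) -> list[RegistrationRecord]:
    """Drop any record wholly contained in an earlier-starting record.

    The outer record is kept unchanged regardless of either record's
    data-availability status.  Same-start spells with different ends are
    treated as nested: the shorter one is inside the longer.
    """
    _check_one_person(history)
    out: list[RegistrationRecord] = []
    max_end = None  # latest end among kept records; its record starts earliest
    outer_by_end: dict = {}
    for rec in _sorted(history):
        if max_end is not None and rec.end <= max_end:
            if reports is not None:
                reports.append(
                    ConflictReport(
                        rec.person_id,
                        "nested",
                        (_key(outer_by_end[max_end]), _key(rec)),
                        "kept outer",
                    )
                )
            continue
        out.append(rec)
        max_end = rec.end
        outer_by_end[max_end] = rec
    return out


def resolve_overlaps(
    history: Sequence[RegistrationRecord],
    reports: Optional[list[ConflictReport]] = None,
) -> list[RegistrationRecord]:
    """Shorten each overlapped record to end just before its successor.

    Expects nested records already resolved, so starts and ends are both
    strictly increasing; a single left-to-right pass reaches the fixpoint.
    The overlap period is thereby awarded to the second registration.
    """
    _check_one_person(history)
    recs = _sorted(history)
    out: list[RegistrationRecord] = []
    for nxt in recs:
        while out:
            prev = out[-1]
            if nxt.start <= prev.end:
                new_end = nxt.start - timedelta(days=1)
                if new_end < prev.start:
                    out.pop()
                    if reports is not None:
                        reports.append(
                            ConflictReport(
                                prev.person_id,
                                "overlap",
                                (_key(prev), _key(nxt)),
                                "dropped emptied record",
                            )
                        )
                    continue  # re-check against the record before it
                else:
                    out[-1] = RegistrationRecord(
                        prev.person_id, prev.practice_id, prev.start, new_end
                    )
                    if reports is not None:
                        reports.append(
                            ConflictReport(
                                prev.person_id,
                                "overlap",
                                (_key(prev), _key(nxt)),
                                f"shortened to {new_end.isoformat()}",
                            )
                        )
            break
        out.append(nxt)
    return out


def clean_history(
    history: Sequence[RegistrationRecord],
    in_sail: Mapping[str, bool],
) -> tuple[list[RegistrationRecord], list[ConflictReport]]:
    """Full per-person cleaning pass; idempotent and order-insensitive.

    Applies, in order: exact-duplicate removal, duplicate-period
    preference, nested-record resolution, overlap shortening.  The output
    is sorted and pairwise non-overlapping; every mutation appears exactly
    once in the returned conflict reports.
    """
    reports: list[ConflictReport] = []
    recs = remove_exact_duplicates(history, reports)
    recs = resolve_duplicate_periods(recs, in_sail, reports)
    recs = resolve_nested(recs, reports)
    recs = resolve_overlaps(recs, reports)
    return recs, reports


def clean_registrations(
    registrations: pd.DataFrame, practice_meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Table-level wrapper: clean every person's history.

    Expects finite ends (open ends materialized to the censor date at
    load).  Returns the cleaned registration table in the input schema and
    a conflict-report table.
    """
    in_sail = dict(zip(practice_meta["practice_id"], practice_meta["in_sail"]))
    out_rows = []
    report_rows = []
    for person_id, group in registrations.groupby("person_id", sort=True):
        history = [
            RegistrationRecord(
                str(person_id),
                r.practice_id,
                pd.Timestamp(r.start).date(),
                pd.Timestamp(r.end).date(),
            )
            for r in group.itertuples()
        ]
        cleaned, reports = clean_history(history, in_sail)
        out_rows.extend(
            (r.person_id, r.practice_id, r.start, r.end) for r in cleaned
        )
        report_rows.extend(
            (c.person_id, c.conflict_kind, ";".join(c.records_involved), c.resolution)
            for c in reports
        )
    cleaned_df = pd.DataFrame(
        out_rows, columns=["person_id", "practice_id", "start", "end"]
    )
    for col in ("start", "end"):
        cleaned_df[col] = pd.to_datetime(cleaned_df[col])
    conflicts = pd.DataFrame(
        report_rows,
        columns=["person_id", "conflict_kind", "records_involved", "resolution"],
    )
    return cleaned_df, conflicts
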