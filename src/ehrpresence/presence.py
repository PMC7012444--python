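"""Build per-person presence records from cleaned registrations and coverage.

A person's availability for follow-up is the intersection of two things:
when they were registered with a GP, and when that GP's data actually
exists in the dataset.  This module composes the per-person pipeline:

    clean history -> close short gaps -> split by practice coverage
        -> merge adjacent records per the grouping switches
        -> subtract known-missing periods

Gap closing runs before coverage splitting so that a closed gap inherits
the second practice's coverage status (had care been needed during the
gap, the person would have registered there earlier).  Splitting always
precedes merging.

The two grouping switches give four outputs:

====================  =================  ===========================================
group_on_sail_data    group_on_practice  result
====================  =================  ===========================================
0                     0                  continuous any-GP registration periods
1                     0                  periods with data available in the dataset
0                     1                  cleaned per-practice registration history
1                     1                  cleaned history + data-availability flag
====================  =================  ===========================================

Merged records spanning several practices carry the ``MERGED`` practice
sentinel; merged records spanning mixed availability carry ``sail_data =
None`` (NOT-TRACKED) rather than a misleading boolean.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cleaning import ConflictReport, clean_history
from .model import (
    MERGED,
    ExclusionPeriod,
    Parameters,
    PracticeCoverage,
    PresenceRecord,
    RegistrationRecord,
    interval_gap,
)


def split_by_coverage(
    record: RegistrationRecord, coverage: Optional[PracticeCoverage]
) -> list[tuple[RegistrationRecord, bool]]:
    """Split one registration at the practice's coverage boundaries.

    The part inside ``[data_start, data_end]`` is flagged as having data;
    leading/trailing remainders are flagged without.  A practice with no
    coverage (not contributing, or threshold never met) yields the whole
    record unflagged.
    """
    if coverage is None or coverage.data_start is None or coverage.data_end is None:
        return [(record, False)]
    lo, hi = coverage.data_start, coverage.data_end
    if record.end < lo or record.start > hi:
        return [(record, False)]
    parts: list[tuple[RegistrationRecord, bool]] = []
    if record.start < lo:
        parts.append(
            (
                RegistrationRecord(
                    record.person_id,
                    record.practice_id,
                    record.start,
                    lo - timedelta(days=1),
                ),
                False,
            )
        )
    parts.append(
        (
            RegistrationRecord(
                record.person_id,
                record.practice_id,
                max(record.start, lo),
                min(record.end, hi),
            ),
            True,
        )
    )
    if record.end > hi:
        parts.append(
            (
                RegistrationRecord(
                    record.person_id,
                    record.practice_id,
                    hi + timedelta(days=1),
                    record.end,
                ),
                False,
            )
        )
    return parts


def close_gaps(
    history: Sequence[RegistrationRecord], max_gap_days: int
) -> list[RegistrationRecord]:
    """Extend each following record backwards over short gaps.

    A gap of 1..``max_gap_days`` whole days between consecutive spells is
    attributed to the second practice (delayed re-registration, during
    which the person would have appeared in the data had they needed
    care).  ``max_gap_days = 0`` disables the feature.  Input must be
    cleaned (sorted, non-overlapping).
    """
    out: list[RegistrationRecord] = []
    for rec in history:
        if out:
            gap = interval_gap(out[-1], rec)
            if 1 <= gap <= max_gap_days:
                rec = RegistrationRecord(
                    rec.person_id,
                    rec.practice_id,
                    out[-1].end + timedelta(days=1),
                    rec.end,
                )
        out.append(rec)
    return out


def merge_adjacent(
    records: Sequence[tuple[RegistrationRecord, bool]], params: Parameters
) -> list[PresenceRecord]:
    """Merge adjacent flagged records under the two grouping switches.

    Adjacent records merge unless a raised switch separates them:
    ``group_on_sail_data = 1`` forbids merging across availability,
    ``group_on_practice = 1`` across practices.  Cross-practice merges
    carry the ``MERGED`` sentinel; cross-availability merges carry
    ``sail_data = None``.
    """
    out: list[PresenceRecord] = []
    for rec, flag in records:
        if out:
            prev = out[-1]
            adjacent = rec.start == prev.end + timedelta(days=1)
            ok_flag = params.group_on_sail_data == 0 or (
                prev.sail_data is not None and prev.sail_data == flag
            )
            ok_prac = params.group_on_practice == 0 or prev.practice_id == rec.practice_id
            if adjacent and ok_flag and ok_prac:
                out[-1] = PresenceRecord(
                    person_id=prev.person_id,
                    practice_id=(
                        prev.practice_id
                        if prev.practice_id == rec.practice_id
                        else MERGED
                    ),
                    start=prev.start,
                    end=rec.end,
                    sail_data=(
                        prev.sail_data if prev.sail_data == flag else None
                    ),
                )
                continue
        out.append(
            PresenceRecord(
                person_id=rec.person_id,
                practice_id=rec.practice_id,
                start=rec.start,
                end=rec.end,
                sail_data=flag,
            )
        )
    return out


def subtract_exclusions(
    records: Sequence[PresenceRecord], exclusions: Sequence[ExclusionPeriod]
) -> list[PresenceRecord]:
    """Clip/split presence records around known-missing periods."""
    out = list(records)
    for excl in exclusions:
        nxt: list[PresenceRecord] = []
        for rec in out:
            if rec.person_id != excl.person_id or excl.end < rec.start or excl.start > rec.end:
                nxt.append(rec)
                continue
            if rec.start < excl.start:
                nxt.append(
                    PresenceRecord(
                        rec.person_id,
                        rec.practice_id,
                        rec.start,
                        excl.start - timedelta(days=1),
                        rec.sail_data,
                    )
                )
            if rec.end > excl.end:
                nxt.append(
                    PresenceRecord(
                        rec.person_id,
                        rec.practice_id,
                        excl.end + timedelta(days=1),
                        rec.end,
                        rec.sail_data,
                    )
                )
        out = nxt
    return out


def build_person_presence(
    history: Sequence[RegistrationRecord],
    coverage: Mapping[str, PracticeCoverage],
    exclusions: Sequence[ExclusionPeriod],
    params: Parameters,
    censor: date,
    in_sail: Mapping[str, bool],
) -> tuple[list[PresenceRecord], list[ConflictReport]]:
    """Full per-person pipeline from raw history to presence records."""
    finite = []
    for rec in history:
        if rec.start > censor:
            continue
        end = rec.end if rec.end is not None else censor
        finite.append(
            RegistrationRecord(rec.person_id, rec.practice_id, rec.start, min(end, censor))
        )
    cleaned, reports = clean_history(finite, in_sail)
    closed = close_gaps(cleaned, params.max_gap_days)
    flagged: list[tuple[RegistrationRecord, bool]] = []
    for rec in closed:
        flagged.extend(split_by_coverage(rec, coverage.get(rec.practice_id)))
    merged = merge_adjacent(flagged, params)
    final = subtract_exclusions(merged, exclusions)
    return final, reports


def build_presence(
    registrations: pd.DataFrame,
    coverage: pd.DataFrame,
    exclusions: Optional[pd.DataFrame],
    practice_meta: pd.DataFrame,
    params: Parameters,
    censor: date,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Table-level presence build for every person.

    Registrations at practices unknown to the metadata are kept but
    treated as not contributing data.  Returns the presence table
    (person_id, practice_id, start, end, sail_data) and the conflict
    reports.  ``sail_data`` is a nullable boolean: ``None`` marks merged
    records of mixed availability.
    """
    from .coverage import coverage_map  # local import to avoid cycle

    cov = coverage_map(coverage)
    in_sail = dict(zip(practice_meta["practice_id"], practice_meta["in_sail"]))
    excl_by_person: dict[str, list[ExclusionPeriod]] = {}
    if exclusions is not None and len(exclusions):
        for r in exclusions.itertuples():
            excl_by_person.setdefault(str(r.person_id), []).append(
                ExclusionPeriod(
                    str(r.person_id),
                    pd.Timestamp(r.start).date(),
                    pd.Timestamp(r.end).date(),
                )
            )
    rows = []
    report_rows = []
    for person_id, group in registrations.groupby("person_id", sort=True):
        history = [
            RegistrationRecord(
                str(person_id),
                r.practice_id,
                pd.Timestamp(r.start).date(),
                None if pd.isna(r.end) else pd.Timestamp(r.end).date(),
            )
            for r in group.itertuples()
        ]
        final, reports = build_person_presence(
            history,
            cov,
            excl_by_person.get(str(person_id), []),
            params,
            censor,
            in_sail,
        )
        rows.extend(
            (p.person_id, p.practice_id, p.start, p.end, p.sail_data) for p in final
        )
        report_rows.extend(
            (c.person_id, c.conflict_kind, ";".join(c.records_involved), c.resolution)
            for c in reports
        )
    presence = pd.DataFrame(
        rows, columns=["person_id", "practice_id", "start", "end", "sail_data"]
    )
    if len(presence):
        presence["start"] = pd.to_datetime(presence["start"])
        presence["end"] = pd.to_datetime(presence["end"])
    presence["sail_data"] = presence["sail_data"].astype(object)
    conflicts = pd.DataFrame(
        report_rows,
        columns=["person_id", "conflict_kind", "records_involved", "resolution"],
    )
    return presence, conflicts
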