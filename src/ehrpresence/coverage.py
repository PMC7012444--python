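"""Infer per-practice periods of usable electronic data from event rates.

The beginning of usable data at a practice (the date it started coded
electronic record-keeping) is not recorded anywhere, and raw event dates
cannot be trusted: unknown dates are parked on sentinel days such as
1900-01-01, events are legitimately backdated to 1 January / month firsts,
and some dates lie in the future.  The inference therefore works on
aggregate monthly event-recording *rates*:

1. for every practice-month, count the persons registered on the 15th;
   months with at most ``min_registered`` persons are EXCLUDED;
2. the month's raw rate is the median (robust to single-day backdating
   spikes) over weekday calendar days of the day's total event count,
   divided by the registered count;
3. rates are normalized per practice to the median rate of a reference
   year in which recording is known to be under way;
4. the data start is the first month that holds a user-chosen threshold
   for a sustained run of months; the data end is the day before the last
   extract, unless recording demonstrably stopped earlier.

Monthly tables use ``NaN`` for EXCLUDED rates.
"""

from __future__ import annotations

import warnings
from datetime import date, timedelta
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import (
    ContractViolation,
    NoReferenceYear,
    Parameters,
    PracticeCoverage,
    ZeroReferenceRate,
    month_first,
    month_last,
)

MONTHLY_COLUMNS = [
    "practice_id",
    "year",
    "month",
    "registered_count",
    "raw_rate",
    "normalized_rate",
]


def _interval_mask(
    starts: np.ndarray, ends: np.ndarray, day: np.datetime64
) -> np.ndarray:
    """Rows whose [start, end] interval contains ``day``; NaT end = open."""
    started = starts <= day
    not_ended = np.isnat(ends) | (ends >= day)
    return started & not_ended


def count_registered_on_15th(
    registrations: pd.DataFrame, practice_id: str, month: tuple[int, int]
) -> int:
    """Distinct persons registered at the practice on the 15th of ``month``."""
    year, mon = month
    regs = registrations[registrations["practice_id"] == practice_id]
    if regs.empty:
        return 0
    day = np.datetime64(date(year, mon, 15))
    mask = _interval_mask(
        regs["start"].to_numpy("datetime64[ns]"),
        regs["end"].to_numpy("datetime64[ns]"),
        day,
    )
    return int(regs.loc[mask, "person_id"].nunique())


def monthly_raw_rate(
    events: pd.DataFrame,
    registered_count: int,
    practice_id: str,
    month: tuple[int, int],
    min_registered: int = 5,
    statistic: str = "median",
) -> Optional[float]:
    """Weekday daily event counts summarized per registered person.

    Returns ``None`` (EXCLUDED) when at most ``min_registered`` persons are
    registered.  Zero-event weekdays count as zeros; ``statistic`` may be
    ``"median"`` (default, robust to backdating spikes) or ``"mean"``.
    """
    if registered_count <= min_registered:
        return None
    year, mon = month
    weekdays = pd.date_range(month_first(year, mon), month_last(year, mon), freq="B")
    ev = events[
        (events["practice_id"] == practice_id)
        & (events["event_date"] >= weekdays[0])
        & (events["event_date"] <= pd.Timestamp(month_last(year, mon)))
    ]
    daily = ev.groupby("event_date").size().reindex(weekdays, fill_value=0)
    agg = daily.median() if statistic == "median" else daily.mean()
    return float(agg) / registered_count


def practice_monthly_rates(
    events: pd.DataFrame,
    registrations: pd.DataFrame,
    practice_id: str,
    last_day: date,
    params: Parameters,
    statistic: str = "median",
) -> pd.DataFrame:
    """Monthly registered counts and raw rates for one practice.

    The month range runs from the practice's first registration month to
    the month containing ``last_day`` (normally the day before the data
    extract).  Events outside the range — 1900 sentinels, future dates —
    fall into no row and thus influence nothing beyond their own
    (non-existent) month.
    """
    regs = registrations[registrations["practice_id"] == practice_id]
    if regs.empty:
        return pd.DataFrame(columns=MONTHLY_COLUMNS)
    first_day: date = regs["start"].min().date()
    if first_day > last_day:
        return pd.DataFrame(columns=MONTHLY_COLUMNS)
    months = pd.period_range(first_day, last_day, freq="M")

    # registered persons on the 15th of each month (distinct persons)
    starts = regs["start"].to_numpy("datetime64[ns]")
    ends = regs["end"].to_numpy("datetime64[ns]")
    persons = regs["person_id"].to_numpy()
    counts = np.empty(len(months), dtype=int)
    for i, p in enumerate(months):
        mask = _interval_mask(starts, ends, np.datetime64(date(p.year, p.month, 15)))
        counts[i] = len(np.unique(persons[mask])) if mask.any() else 0

    # daily event totals on weekdays, zero-filled, aggregated per month
    ev = events[events["practice_id"] == practice_id]
    bdays = pd.date_range(
        month_first(months[0].year, months[0].month),
        month_last(months[-1].year, months[-1].month),
        freq="B",
    )
    daily = (
        ev.groupby("event_date").size().reindex(bdays, fill_value=0)
        if not ev.empty
        else pd.Series(0, index=bdays)
    )
    grouped = daily.groupby(daily.index.to_period("M"))
    per_month = (grouped.median() if statistic == "median" else grouped.mean()).reindex(
        months, fill_value=0.0
    )

    raw = np.where(
        counts > params.min_registered, per_month.to_numpy() / np.maximum(counts, 1), np.nan
    )
    return pd.DataFrame(
        {
            "practice_id": practice_id,
            "year": months.year,
            "month": months.month,
            "registered_count": counts,
            "raw_rate": raw,
            "normalized_rate": np.nan,
        }
    )


def choose_reference_year(
    registrations: pd.DataFrame, practice_id: str, params: Parameters
) -> int:
    """Pick the normalization reference year for a practice.

    The preferred year (2009 by default, believed to postdate the start of
    electronic recording everywhere) is used whenever the practice has
    registration data then, i.e. some month of that year is not EXCLUDED.
    Otherwise the earliest year with at least
    ``reference_min_registrations`` registration records starting before
    its 1 January is used; if none qualifies a :class:`NoReferenceYear`
    error is raised and the practice is flagged uncoverable.
    """
    regs = registrations[registrations["practice_id"] == practice_id]
    if regs.empty:
        raise NoReferenceYear(f"practice {practice_id} has no registration records")
    preferred = params.reference_year_preferred
    for mon in range(1, 13):
        if (
            count_registered_on_15th(registrations, practice_id, (preferred, mon))
            > params.min_registered
        ):
            return preferred
    start_years = regs["start"].dt.year.to_numpy()
    for year in range(int(start_years.min()) + 1, int(start_years.max()) + 2):
        n_before = int((regs["start"] < pd.Timestamp(date(year, 1, 1))).sum())
        if n_before >= params.reference_min_registrations:
            return year
    raise NoReferenceYear(
        f"practice {practice_id}: no year with >= "
        f"{params.reference_min_registrations} prior registration records"
    )


def normalize_rates(monthly: pd.DataFrame, reference_year: int) -> pd.DataFrame:
    """Divide raw rates by the reference-year median rate (per practice).

    The reference rate is the median of the non-EXCLUDED raw rates within
    ``reference_year``.  EXCLUDED months propagate.
    """
    out = monthly.copy()
    ref = out.loc[(out["year"] == reference_year), "raw_rate"].dropna()
    if ref.empty:
        raise NoReferenceYear(
            f"no counted month in reference year {reference_year}"
        )
    ref_rate = float(ref.median())
    if ref_rate == 0.0:
        raise ZeroReferenceRate(
            f"reference year {reference_year} has zero event rate"
        )
    out["normalized_rate"] = out["raw_rate"] / ref_rate
    return out


def infer_start_date(monthly: pd.DataFrame, params: Parameters) -> Optional[date]:
    """First day of the earliest month holding the threshold sustainedly.

    EXCLUDED months are treated as missing and skipped: the scan runs over
    the subsequence of counted months, and a month qualifies when it and
    the following ``sustain_months - 1`` counted months (fewer at the end
    of the series) all have normalized rate >= threshold.
    """
    nz = monthly.dropna(subset=["normalized_rate"]).reset_index(drop=True)
    ok = (nz["normalized_rate"] >= params.threshold).to_numpy()
    n = len(ok)
    for i in range(n):
        if ok[i : min(i + params.sustain_months, n)].all():
            return month_first(int(nz.loc[i, "year"]), int(nz.loc[i, "month"]))
    return None


def infer_end_date(
    monthly: pd.DataFrame, extract_date: date, params: Parameters
) -> Optional[date]:
    """Day before the extract, unless recording stopped earlier.

    The candidate end is ``extract_date - 1``.  It is accepted when the
    last *complete* counted month before the candidate still meets the
    threshold; otherwise the end is the last day of the latest month that
    did (recording stopped before the extract, e.g. a closed practice).
    Returns ``None`` when the threshold was never met.
    """
    candidate = extract_date - timedelta(days=1)
    nz = monthly.dropna(subset=["normalized_rate"]).reset_index(drop=True)
    if not nz.empty:
        last_full = nz[
            [
                month_last(int(r.year), int(r.month)) <= candidate
                for r in nz.itertuples()
            ]
        ]
        if not last_full.empty:
            if last_full.iloc[-1]["normalized_rate"] >= params.threshold:
                return candidate
    qual = nz[nz["normalized_rate"] >= params.threshold]
    if qual.empty:
        return None
    last = qual.iloc[-1]
    return min(month_last(int(last["year"]), int(last["month"])), candidate)


def compute_all_coverage(
    events: pd.DataFrame,
    registrations: pd.DataFrame,
    practice_meta: pd.DataFrame,
    params: Parameters,
    statistic: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Coverage inference for every contributing practice.

    Returns ``(coverage, monthly_rates, warnings)``.  Practices with
    ``in_sail`` false are absent from the output; per-practice failures
    (no usable reference year, zero reference rate) yield a coverage row
    with empty dates plus a warning rather than aborting the run.
    """
    coverage_rows = []
    monthly_frames = []
    messages: list[str] = []
    contributing = practice_meta[practice_meta["in_sail"]].sort_values("practice_id")
    for row in contributing.itertuples():
        pid = row.practice_id
        extract: date = pd.Timestamp(row.extract_date).date()
        none_row = {
            "practice_id": pid,
            "data_start": None,
            "data_end": None,
            "reference_year": None,
        }
        try:
            monthly = practice_monthly_rates(
                events,
                registrations,
                pid,
                extract - timedelta(days=1),
                params,
                statistic=statistic,
            )
            if monthly.empty:
                raise NoReferenceYear(f"practice {pid} has no registration records")
            ref_year = choose_reference_year(registrations, pid, params)
            monthly = normalize_rates(monthly, ref_year)
            start = infer_start_date(monthly, params)
            end = infer_end_date(monthly, extract, params)
            monthly_frames.append(monthly)
            if start is not None and end is not None and start > end:
                messages.append(
                    f"practice {pid}: inferred start {start} after end {end}; "
                    "coverage voided"
                )
                coverage_rows.append({**none_row, "reference_year": ref_year})
                continue
            if start is None or end is None:
                start = end = None
            coverage_rows.append(
                {
                    "practice_id": pid,
                    "data_start": start,
                    "data_end": end,
                    "reference_year": ref_year,
                }
            )
        except (NoReferenceYear, ZeroReferenceRate) as exc:
            messages.append(f"practice {pid}: {exc}")
            coverage_rows.append(none_row)
    coverage = pd.DataFrame(
        coverage_rows,
        columns=["practice_id", "data_start", "data_end", "reference_year"],
    )
    monthly_all = (
        pd.concat(monthly_frames, ignore_index=True)
        if monthly_frames
        else pd.DataFrame(columns=MONTHLY_COLUMNS)
    )
    return coverage, monthly_all, messages


def coverage_map(coverage: pd.DataFrame) -> dict[str, PracticeCoverage]:
    """Index a coverage table by practice for interval lookups."""
    out = {}
    for row in coverage.itertuples():
        ds = row.data_start
        de = row.data_end
        out[row.practice_id] = PracticeCoverage(
            practice_id=row.practice_id,
            data_start=None if pd.isna(ds) else pd.Timestamp(ds).date(),
            data_end=None if pd.isna(de) else pd.Timestamp(de).date(),
            reference_year=None if pd.isna(row.reference_year) else int(row.reference_year),
        )
    return out
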