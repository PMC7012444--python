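"""Brute-force day-level evaluation of the cleaning and presence rules.

Deliberately independent of the interval implementation: every rule is
restated in terms of explicit per-day ownership so the interval pipeline
can be checked against it.

* exact duplicates collapse; identical spans keep the preferred practice
  (contributing data first, then lower id);
* a record wholly contained in another is dropped;
* on any remaining day covered by several records, the latest-starting
  record owns the day (overlap periods belong to the second registration);
* unowned runs of 1..max_gap_days between owned days belong to the
  practice owning the next day;
* a day has data when its owning practice's coverage interval contains it.
"""

from __future__ import annotations

from datetime import date
from typing import Mapping, Optional, Sequence


def clean_day_ownership(
    records: Sequence[tuple[str, date, date]], in_sail: Mapping[str, bool]
) -> dict[int, str]:
    """Day-ordinal -> owning practice after the four cleaning rules."""
    uniq: list[tuple[str, date, date]] = []
    seen = set()
    for r in records:
        if r not in seen:
            seen.add(r)
            uniq.append(r)
    by_span: dict[tuple[date, date], list[str]] = {}
    for prac, s, e in uniq:
        by_span.setdefault((s, e), []).append(prac)
    survivors = [
        (min(pracs, key=lambda p: (not in_sail.get(p, False), p)), s, e)
        for (s, e), pracs in by_span.items()
    ]
    kept = [
        r
        for r in survivors
        if not any(o != r and o[1] <= r[1] and r[2] <= o[2] for o in survivors)
    ]
    owner: dict[int, tuple[int, str]] = {}
    for prac, s, e in kept:
        so = s.toordinal()
        for o in range(so, e.toordinal() + 1):
            cur = owner.get(o)
            if cur is None or so > cur[0]:
                owner[o] = (so, prac)
    return {o: prac for o, (_, prac) in owner.items()}


def day_level_presence(
    records: Sequence[tuple[str, date, Optional[date]]],
    in_sail: Mapping[str, bool],
    coverage: Mapping[str, Optional[tuple[date, date]]],
    max_gap_days: int,
    censor: date,
) -> dict[int, tuple[str, bool]]:
    """Day-ordinal -> (practice, data-available flag), before exclusions."""
    finite = []
    for prac, s, e in records:
        e = censor if e is None else min(e, censor)
        if s <= e:
            finite.append((prac, s, e))
    own = clean_day_ownership(finite, in_sail)
    days = sorted(own)
    filled = dict(own)
    for a, b in zip(days, days[1:]):
        gap = b - a - 1
        if 1 <= gap <= max_gap_days:
            for o in range(a + 1, b):
                filled[o] = own[b]
    out = {}
    for o, prac in filled.items():
        cov = coverage.get(prac)
        flag = bool(cov and cov[0].toordinal() <= o <= cov[1].toordinal())
        out[o] = (prac, flag)
    return out
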