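from datetime import date, timedelta

import pandas as pd
import pytest

from ehrpresence.model import (
    MERGED,
    ExclusionPeriod,
    Parameters,
    PracticeCoverage,
    PresenceRecord,
    RegistrationRecord,
)
from ehrpresence.presence import (
    build_presence,
    close_gaps,
    merge_adjacent,
    split_by_coverage,
    subtract_exclusions,
)

from conftest import rec


def cov(practice, start, end):
    return PracticeCoverage(practice, date.fromisoformat(start), date.fromisoformat(end), 2009)


class TestSplitByCoverage:
    def test_three_way_split(self):
        r = rec("x", "P1", "2005-01-01", "2015-12-31")
        parts = split_by_coverage(r, cov("P1", "2008-03-01", "2014-06-30"))
        assert parts == [
            (rec("x", "P1", "2005-01-01", "2008-02-29"), False),
            (rec("x", "P1", "2008-03-01", "2014-06-30"), True),
            (rec("x", "P1", "2014-07-01", "2015-12-31"), False),
        ]

    def test_entirely_inside(self):
        r = rec("x", "P1", "2009-01-01", "2010-12-31")
        parts = split_by_coverage(r, cov("P1", "2008-03-01", "2014-06-30"))
        assert parts == [(r, True)]

    def test_no_coverage(self):
        r = rec("x", "P3", "2009-01-01", "2010-12-31")
        assert split_by_coverage(r, None) == [(r, False)]
        void = PracticeCoverage("P3", None, None, None)
        assert split_by_coverage(r, void) == [(r, False)]


class TestCloseGaps:
    def test_short_gap_closed_to_second_practice(self):
        h = [
            rec("x", "P1", "2010-01-01", "2010-03-31"),
            rec("x", "P2", "2010-04-20", "2010-12-31"),
        ]
        out = close_gaps(h, 30)
        assert out == [
            rec("x", "P1", "2010-01-01", "2010-03-31"),
            rec("x", "P2", "2010-04-01", "2010-12-31"),
        ]

    def test_long_gap_untouched(self):
        h = [
            rec("x", "P1", "2010-01-01", "2010-03-31"),
            rec("x", "P2", "2010-05-16", "2010-12-31"),  # 45-day gap
        ]
        assert close_gaps(h, 30) == h

    def test_disabled(self):
        h = [
            rec("x", "P1", "2010-01-01", "2010-03-31"),
            rec("x", "P2", "2010-04-03", "2010-12-31"),
        ]
        assert close_gaps(h, 0) == h

    def test_monotone_in_max_gap(self):
        h = [
            rec("x", "P1", "2010-01-01", "2010-03-31"),
            rec("x", "P2", "2010-04-20", "2010-10-31"),
            rec("x", "P3", "2010-12-15", "2011-12-31"),
        ]
        def total_days(recs):
            return sum(r.n_days for r in recs)
        days = [total_days(close_gaps(h, g)) for g in (0, 10, 30, 60)]
        assert days == sorted(days)


class TestMergeAdjacent:
    def flagged(self):
        return [
            (rec("x", "P1", "2010-01-01", "2010-06-30"), True),
            (rec("x", "P2", "2010-07-01", "2010-12-31"), True),
            (rec("x", "P2", "2011-01-01", "2011-06-30"), False),
        ]

    def test_grouping_10_merges_across_practices(self):
        out = merge_adjacent(self.flagged(), Parameters(group_on_sail_data=1, group_on_practice=0))
        assert out == [
            PresenceRecord("x", MERGED, date(2010, 1, 1), date(2010, 12, 31), True),
            PresenceRecord("x", "P2", date(2011, 1, 1), date(2011, 6, 30), False),
        ]

    def test_grouping_11_never_merges_across_flags(self):
        out = merge_adjacent(self.flagged(), Parameters(group_on_sail_data=1, group_on_practice=1))
        assert len(out) == 3  # flags or practices differ at both joins

    def test_grouping_00_merges_everything_adjacent(self):
        out = merge_adjacent(self.flagged(), Parameters(group_on_sail_data=0, group_on_practice=0))
        assert out == [
            PresenceRecord("x", MERGED, date(2010, 1, 1), date(2011, 6, 30), None)
        ]

    def test_non_adjacent_never_merges(self):
        parts = [
            (rec("x", "P1", "2010-01-01", "2010-06-30"), True),
            (rec("x", "P1", "2010-07-02", "2010-12-31"), True),  # 1-day hole
        ]
        out = merge_adjacent(parts, Parameters(group_on_sail_data=0, group_on_practice=0))
        assert len(out) == 2


class TestSubtractExclusions:
    def test_split_around_exclusion(self):
        r = PresenceRecord("x", "P1", date(2010, 1, 1), date(2010, 12, 31), True)
        out = subtract_exclusions([r], [ExclusionPeriod("x", date(2010, 6, 1), date(2010, 6, 30))])
        assert out == [
            PresenceRecord("x", "P1", date(2010, 1, 1), date(2010, 5, 31), True),
            PresenceRecord("x", "P1", date(2010, 7, 1), date(2010, 12, 31), True),
        ]

    def test_no_overlap_identity(self):
        r = PresenceRecord("x", "P1", date(2010, 1, 1), date(2010, 5, 31), True)
        out = subtract_exclusions([r], [ExclusionPeriod("x", date(2011, 1, 1), date(2011, 1, 31))])
        assert out == [r]

    def test_full_cover_drops_record(self):
        r = PresenceRecord("x", "P1", date(2010, 3, 1), date(2010, 3, 31), True)
        out = subtract_exclusions([r], [ExclusionPeriod("x", date(2010, 1, 1), date(2010, 12, 31))])
        assert out == []

    def test_other_person_untouched(self):
        r = PresenceRecord("x", "P1", date(2010, 1, 1), date(2010, 12, 31), True)
        out = subtract_exclusions([r], [ExclusionPeriod("y", date(2010, 6, 1), date(2010, 6, 30))])
        assert out == [r]


def _expected_composite(combo):
    """Hand-derived presence for the 8-record composite fixture."""
    D = date.fromisoformat
    if combo in ((1, 0), (1, 1)):
        rows = [
            ("X", "P1", "2000-01-01", "2001-12-31", False),
            ("X", "P1", "2002-01-01", "2004-09-30", True),
            ("X", "P2", "2004-10-01", "2004-12-31", False),
            ("X", "P2", "2005-01-01", "2008-05-31", True),
            ("X", "P3", "2008-06-01", "2010-12-31", False),
            ("X", "P2", "2011-01-01", "2016-06-29", True),
            ("X", "P2", "2016-06-30", "2016-06-30", False),
        ]
    elif combo == (0, 0):
        rows = [("X", MERGED, "2000-01-01", "2016-06-30", None)]
    else:  # (0, 1)
        rows = [
            ("X", "P1", "2000-01-01", "2004-09-30", None),
            ("X", "P2", "2004-10-01", "2008-05-31", None),
            ("X", "P3", "2008-06-01", "2010-12-31", False),
            ("X", "P2", "2011-01-01", "2016-06-30", None),
        ]
    df = pd.DataFrame(rows, columns=["person_id", "practice_id", "start", "end", "sail_data"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    df["sail_data"] = df["sail_data"].astype(object)
    return df


@pytest.mark.parametrize("combo", [(1, 0), (0, 0), (0, 1), (1, 1)])
def test_composite_person_all_groupings(
    combo, composite_registrations, composite_coverage, composite_meta
):
    """Canonical scenario: one person, 2000-2016, three practices, one
    exact duplicate, one nested spell, one overlap, a 10-day gap, one
    duplicate period and an open end; output derived by hand."""
    params = Parameters(group_on_sail_data=combo[0], group_on_practice=combo[1])
    presence, conflicts = build_presence(
        composite_registrations,
        composite_coverage,
        None,
        composite_meta,
        params,
        date(2016, 6, 30),
    )
    expected = _expected_composite(combo)
    pd.testing.assert_frame_equal(presence.reset_index(drop=True), expected)
    kinds = sorted(conflicts["conflict_kind"])
    assert kinds == ["duplicate_period", "exact_duplicate", "nested", "overlap"]


def test_unknown_practice_treated_as_not_contributing(
    composite_coverage, composite_meta
):
    regs = pd.DataFrame(
        [("Z", "P99", "2010-01-01", "2012-12-31")],
        columns=["person_id", "practice_id", "start", "end"],
    )
    regs["start"] = pd.to_datetime(regs["start"])
    regs["end"] = pd.to_datetime(regs["end"])
    presence, _ = build_presence(
        regs, composite_coverage, None, composite_meta,
        Parameters(group_on_sail_data=1), date(2016, 6, 30),
    )
    assert list(presence["sail_data"]) == [False]


def test_person_fully_outside_coverage_with_flag_grouping(
    composite_coverage, composite_meta
):
    regs = pd.DataFrame(
        [("Z", "P3", "2010-01-01", "2012-12-31")],
        columns=["person_id", "practice_id", "start", "end"],
    )
    regs["start"] = pd.to_datetime(regs["start"])
    regs["end"] = pd.to_datetime(regs["end"])
    presence, _ = build_presence(
        regs, composite_coverage, None, composite_meta,
        Parameters(group_on_sail_data=1), date(2016, 6, 30),
    )
    flagged = presence[presence["sail_data"] == True]  # noqa: E712
    assert flagged.empty
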