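from datetime import date

import pandas as pd
import pytest

from ehrpresence.model import RegistrationRecord


def rec(person, practice, start, end):
    """Shorthand RegistrationRecord builder with ISO date strings."""
    return RegistrationRecord(
        person,
        practice,
        date.fromisoformat(start),
        None if end is None else date.fromisoformat(end),
    )


@pytest.fixture
def composite_meta():
    """Two contributing practices and one that never joined."""
    return pd.DataFrame(
        {
            "practice_id": ["P1", "P2", "P3"],
            "in_sail": [True, True, False],
            "extract_date": pd.to_datetime(["2016-06-30", "2016-06-30", None]),
        }
    )


@pytest.fixture
def composite_registrations():
    """Eight raw records for one person combining every anomaly:

    exact duplicate, a nested spell, a partial overlap, a 10-day gap, a
    duplicate period at a non-contributing practice, and an open end.
    """
    rows = [
        ("X", "P1", "2000-01-01", "2004-12-31"),
        ("X", "P1", "2000-01-01", "2004-12-31"),  # exact duplicate
        ("X", "P3", "2001-03-01", "2001-03-31"),  # nested in the first spell
        ("X", "P2", "2004-10-01", "2008-05-31"),  # overlaps the first spell
        ("X", "P3", "2008-06-11", "2010-12-31"),  # 10-day gap after previous
        ("X", "P2", "2011-01-01", "2012-12-31"),
        ("X", "P3", "2011-01-01", "2012-12-31"),  # duplicate period, loses to P2
        ("X", "P2", "2013-01-01", None),  # open end -> censor
    ]
    df = pd.DataFrame(rows, columns=["person_id", "practice_id", "start", "end"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


@pytest.fixture
def composite_coverage():
    """Hand-fixed coverage: P1 stopped recording before its extract."""
    return pd.DataFrame(
        {
            "practice_id": ["P1", "P2"],
            "data_start": [date(2002, 1, 1), date(2005, 1, 1)],
            "data_end": [date(2015, 12, 31), date(2016, 6, 29)],
            "reference_year": [2009, 2009],
        }
    )
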