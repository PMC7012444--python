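from datetime import date

import numpy as np
import pandas as pd
import pytest

from ehrpresence.coverage import (
    choose_reference_year,
    compute_all_coverage,
    count_registered_on_15th,
    infer_end_date,
    infer_start_date,
    monthly_raw_rate,
    normalize_rates,
    practice_monthly_rates,
)
from ehrpresence.model import NoReferenceYear, Parameters, ZeroReferenceRate
from ehrpresence.simulate import ScenarioConfig, generate_scenario


def regs_df(rows):
    df = pd.DataFrame(rows, columns=["person_id", "practice_id", "start", "end"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


def events_df(rows):
    df = pd.DataFrame(rows, columns=["person_id", "practice_id", "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def monthly_df(practice, rates, first=(2004, 1), counts=100):
    """Build a monthly-rate table from a list of normalized rates (None=EXCLUDED)."""
    y, m = first
    rows = []
    for r in rates:
        rows.append((practice, y, m, counts, r, r))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return pd.DataFrame(
        rows,
        columns=["practice_id", "year", "month", "registered_count", "raw_rate", "normalized_rate"],
    ).astype({"raw_rate": float, "normalized_rate": float})


class TestCountRegistered:
    def test_empty(self):
        assert count_registered_on_15th(regs_df([]), "P", (2010, 6)) == 0

    def test_containment(self):
        regs = regs_df([("a", "P", "2010-01-01", "2010-12-31")])
        assert count_registered_on_15th(regs, "P", (2010, 6)) == 1
        assert count_registered_on_15th(regs, "P", (2011, 1)) == 0
        assert count_registered_on_15th(regs, "Q", (2010, 6)) == 0

    def test_boundaries_and_distinctness(self):
        rows = [
            ("a", "P", "2010-06-15", "2010-07-01"),  # starts on the 15th
            ("b", "P", "2010-01-01", "2010-06-15"),  # ends on the 15th
            ("c", "P", "2010-01-01", None),  # open end
            ("c", "P", "2010-05-01", "2010-07-01"),  # same person twice
            ("d", "P", "2010-01-01", "2010-06-14"),
            ("e", "P", "2010-06-16", "2010-12-31"),
        ]
        assert count_registered_on_15th(regs_df(rows), "P", (2010, 6)) == 3


class TestMonthlyRawRate:
    def test_uniform_weekdays(self):
        # every weekday of June 2010 carries exactly 4 events
        days = pd.date_range("2010-06-01", "2010-06-30", freq="B")
        ev = events_df(
            [("x", "P", d) for d in days for _ in range(4)]
        )
        assert monthly_raw_rate(ev, 10, "P", (2010, 6)) == pytest.approx(0.4)

    def test_no_events_is_zero(self):
        assert monthly_raw_rate(events_df([]), 100, "P", (2010, 6)) == 0.0

    def test_excluded_when_too_few_registered(self):
        assert monthly_raw_rate(events_df([]), 5, "P", (2010, 6)) is None
        assert monthly_raw_rate(events_df([]), 6, "P", (2010, 6)) == 0.0

    def test_median_robust_to_single_day_spike(self):
        # Jan 2010 has 21 weekdays: one bulk-upload day with 500 events,
        # the other 20 days with 2 each.  The median ignores the spike.
        days = pd.date_range("2010-01-01", "2010-01-31", freq="B")
        assert len(days) == 21
        rows = [("x", "P", days[3]) for _ in range(500)]
        rows += [("x", "P", d) for d in days if d != days[3] for _ in range(2)]
        ev = events_df(rows)
        assert monthly_raw_rate(ev, 10, "P", (2010, 1)) == pytest.approx(0.2)
        mean_rate = monthly_raw_rate(ev, 10, "P", (2010, 1), statistic="mean")
        assert mean_rate == pytest.approx((500 + 40) / 21 / 10)

    def test_weekend_events_do_not_count(self):
        ev = events_df([("x", "P", "2010-06-05")] * 50)  # a Saturday
        assert monthly_raw_rate(ev, 10, "P", (2010, 6)) == 0.0


class TestReferenceYear:
    def test_preferred_year_when_data_exists(self):
        rows = [(f"p{i}", "P", "2000-01-01", "2015-12-31") for i in range(10)]
        assert choose_reference_year(regs_df(rows), "P", Parameters()) == 2009

    def test_fallback_first_complete_year(self):
        rows = [(f"p{i}", "P", "2011-04-01", None) for i in range(150)]
        assert choose_reference_year(regs_df(rows), "P", Parameters()) == 2012

    def test_no_reference_year(self):
        rows = [(f"p{i}", "P", "2011-04-01", None) for i in range(20)]
        with pytest.raises(NoReferenceYear):
            choose_reference_year(regs_df(rows), "P", Parameters())


class TestNormalize:
    def test_scaling_against_reference_median(self):
        rates = [0.05] + [0.5] * 12
        m = monthly_df("P", rates, first=(2008, 12))  # 2009 holds the 0.5s
        out = normalize_rates(m.assign(normalized_rate=np.nan), 2009)
        assert out["normalized_rate"].iloc[0] == pytest.approx(0.10)
        assert out["normalized_rate"].iloc[5] == pytest.approx(1.0)

    def test_excluded_propagates(self):
        m = monthly_df("P", [None, 0.5, 0.5], first=(2009, 1))
        out = normalize_rates(m.assign(normalized_rate=np.nan), 2009)
        assert np.isnan(out["normalized_rate"].iloc[0])

    def test_zero_reference_rate(self):
        m = monthly_df("P", [0.0] * 12, first=(2009, 1))
        with pytest.raises(ZeroReferenceRate):
            normalize_rates(m, 2009)

    def test_reference_year_without_data(self):
        m = monthly_df("P", [0.5] * 12, first=(2010, 1))
        with pytest.raises(NoReferenceYear):
            normalize_rates(m, 2009)


class TestInferStart:
    def test_degenerate_all_above(self):
        m = monthly_df("P", [0.5, 0.6, 0.7, 0.8], first=(2004, 1))
        assert infer_start_date(m, Parameters()) == date(2004, 1, 1)

    def test_isolated_crossing_skipped(self):
        rates = [0.02, 0.04, 0.15, 0.01, 0.40, 0.55, 0.60, 0.62, 0.61]
        m = monthly_df("P", rates, first=(2004, 1))
        # the lone 0.15 in March is noise; the sustained run starts in May
        assert infer_start_date(m, Parameters()) == date(2004, 5, 1)

    def test_never_crosses(self):
        m = monthly_df("P", [0.01, 0.02, 0.05], first=(2004, 1))
        assert infer_start_date(m, Parameters()) is None

    def test_excluded_months_are_skipped_not_zero(self):
        rates = [0.5, None, None, 0.6, 0.7]
        m = monthly_df("P", rates, first=(2004, 1))
        assert infer_start_date(m, Parameters()) == date(2004, 1, 1)


class TestInferEnd:
    def test_recording_to_extract(self):
        m = monthly_df("P", [0.5] * 24, first=(2014, 1))
        end = infer_end_date(m, date(2015, 12, 20), Parameters())
        assert end == date(2015, 12, 19)

    def test_recording_stopped_early(self):
        rates = [0.5] * 10 + [0.0] * 14
        m = monthly_df("P", rates, first=(2014, 1))
        end = infer_end_date(m, date(2016, 1, 15), Parameters())
        assert end == date(2014, 10, 31)

    def test_threshold_never_met(self):
        m = monthly_df("P", [0.01] * 12, first=(2014, 1))
        assert infer_end_date(m, date(2015, 1, 1), Parameters()) is None


@pytest.fixture(scope="module")
def scenario():
    cfg = ScenarioConfig(n_practices=6, n_persons=400, seed=42,
                         backdating_fraction=0.1)
    return generate_scenario(cfg)


class TestFullCoverage:
    def test_start_recovered_and_non_sail_absent(self, scenario):
        events, regs, meta, excl, truth = scenario
        cov, monthly, warns = compute_all_coverage(events, regs, meta, Parameters())
        assert set(cov["practice_id"]) == set(
            meta.loc[meta["in_sail"], "practice_id"]
        )
        merged = cov.merge(truth.practices, on="practice_id")
        for row in merged.itertuples():
            err = abs((row.data_start - row.true_start).days)
            assert err <= 31
            assert row.data_end == row.true_end

    def test_threshold_monotonicity(self, scenario):
        events, regs, meta, excl, truth = scenario
        results = {}
        for thr in (0.05, 0.10, 0.20):
            cov, _, _ = compute_all_coverage(
                events, regs, meta, Parameters(threshold=thr)
            )
            results[thr] = cov.set_index("practice_id")
        for pid in results[0.05].index:
            starts = [results[t].loc[pid, "data_start"] for t in (0.05, 0.10, 0.20)]
            ends = [results[t].loc[pid, "data_end"] for t in (0.05, 0.10, 0.20)]
            assert starts[0] <= starts[1] <= starts[2]
            assert ends[0] >= ends[1] >= ends[2]

    def test_scale_invariance(self, scenario):
        events, regs, meta, excl, truth = scenario
        pid = meta.loc[meta["in_sail"], "practice_id"].iloc[0]
        base, _, _ = compute_all_coverage(events, regs, meta, Parameters())
        tripled = pd.concat([events] * 3, ignore_index=True)
        scaled, _, _ = compute_all_coverage(tripled, regs, meta, Parameters())
        assert base.set_index("practice_id")["data_start"].equals(
            scaled.set_index("practice_id")["data_start"]
        )
        assert base.set_index("practice_id")["data_end"].equals(
            scaled.set_index("practice_id")["data_end"]
        )

    def test_sentinel_pile_has_no_influence(self, scenario):
        events, regs, meta, excl, truth = scenario
        base, _, _ = compute_all_coverage(events, regs, meta, Parameters())
        pile = events.head(2000).copy()
        pile["event_date"] = pd.Timestamp("1900-01-01")
        with_pile = pd.concat([events, pile], ignore_index=True)
        cov, _, _ = compute_all_coverage(with_pile, regs, meta, Parameters())
        assert base.equals(cov)


@pytest.fixture(scope="module")
def rates():
    """One practice with steady recording from 2005 plus January-first
    backdating spikes in 2001-2004."""
    regs = regs_df([(f"p{i}", "P", "2000-01-01", None) for i in range(50)])
    rows = []
    for d in pd.date_range("2005-01-01", "2009-12-31", freq="B"):
        rows += [("x", "P", d)] * 4  # steady recording from 2005
    for year in (2001, 2002, 2003, 2004):
        rows += [("x", "P", pd.Timestamp(f"{year}-01-01"))] * 300
    events = events_df(rows)
    out = {}
    for stat in ("median", "mean"):
        m = practice_monthly_rates(
            events, regs, "P", date(2009, 12, 31), Parameters(), statistic=stat
        )
        out[stat] = normalize_rates(m, 2009)
    return out


class TestMedianVsMean:
    """Backdated events pile up on 1 January; the median-based monthly
    series must be less distorted by those spikes than the mean-based one."""

    @staticmethod
    def _january_spike_ratio(monthly):
        pre = monthly[monthly["year"] < 2005]
        total = pre["raw_rate"].sum()
        if total == 0:
            return 0.0
        return pre.loc[pre["month"] == 1, "raw_rate"].sum() / total

    def test_january_median_not_above_mean(self, rates):
        for year in (2001, 2002, 2003, 2004):
            med = rates["median"].query("year == @year and month == 1")[
                "normalized_rate"
            ].iloc[0]
            mean = rates["mean"].query("year == @year and month == 1")[
                "normalized_rate"
            ].iloc[0]
            assert med <= mean

    def test_january_spike_ratio_strictly_smaller(self, rates):
        assert self._january_spike_ratio(rates["median"]) < self._january_spike_ratio(
            rates["mean"]
        )

    def test_median_series_is_smoother(self, rates):
        def max_jump(monthly):
            r = monthly["normalized_rate"].dropna().to_numpy()
            return np.abs(np.diff(r)).max()

        assert max_jump(rates["median"]) <= max_jump(rates["mean"])
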