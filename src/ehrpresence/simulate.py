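"""Synthetic practices, registration histories and event streams.

No public deposit of a real primary-care extract with registration
histories exists (and none could, for governance reasons), so every other
module is exercised against generated data with known ground truth.  The
generator's job is to reproduce the *signatures* of the documented data
pathologies — not any real population's epidemiology:

* events parked on the 1900-01-01 sentinel, future-dated events, and
  backdated events whose mass concentrates on 1 January and month firsts;
* per-practice onset of electronic recording (abrupt or ramped), with the
  event volume before onset essentially limited to erroneous dates;
* registration anomalies: exact duplicate rows, nested spells, partial
  overlaps, identical spells at two practices, and short gaps from delayed
  re-registration;
* genuine absences: moves between practices, emigration with optional
  return, and long (>30 day) registration gaps.

Anomalies are injected on top of a clean history whose pre-injection truth
is recorded, and each injection is constructed to be exactly reversible by
the cleaning rules (e.g. an injected duplicate period is placed at a
practice that loses the preference ordering).  Long gaps are the
exception: they are genuine features of the clean history, because the
pipeline deliberately leaves them open.

Identical seed and config give bit-identical output, independent of
enumeration order (per-person child random streams).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .model import MERGED, Parameters, month_first

_EPOCH_MONDAY = date(1970, 1, 5).toordinal()  # anchor for weekday arithmetic
_ORD_1970 = date(1970, 1, 1).toordinal()  # proleptic ordinal of the unix epoch
_AVG_WEEKDAYS_PER_MONTH = 21.7


def _ordinals_to_timestamps(ordinals: np.ndarray) -> pd.DatetimeIndex:
    return pd.to_datetime(ordinals - _ORD_1970, unit="D")


def _jan1_ordinal(years: np.ndarray) -> np.ndarray:
    d = (years - 1970).astype("datetime64[Y]").astype("datetime64[D]")
    return d.astype(np.int64) + _ORD_1970


def _month_first_ordinal(years: np.ndarray, months: np.ndarray) -> np.ndarray:
    d = ((years - 1970) * 12 + months - 1).astype("datetime64[M]").astype("datetime64[D]")
    return d.astype(np.int64) + _ORD_1970


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Rates are per person-year hazards; fractions are proportions of events
    or histories affected.  Defaults describe a mid-size mixed scenario:
    76% of practices contribute data, modest backdating, and rare
    registration anomalies (each kind affects a few percent of histories).
    """

    n_practices: int = 20
    n_persons: int = 1000
    study_start: date = date(2000, 1, 1)
    censor: date = date(2016, 1, 1)
    frac_in_sail: float = 0.76
    onset_shape: str = "abrupt"  # or "linear_ramp"
    ramp_months: int = 24
    onset_year_range: tuple[int, int] = (2000, 2008)
    extract_lag_max_days: int = 0
    events_per_person_month: float = 2.0
    weekend_weight: float = 0.15
    backdating_fraction: float = 0.05
    sentinel_fraction: float = 0.005
    future_fraction: float = 0.002
    snap_jan1: float = 0.6
    snap_month_first: float = 0.3
    backdate_floor_year: int = 1995
    move_rate: float = 0.10
    emigration_rate: float = 0.02
    return_prob: float = 0.5
    frac_present_from_start: float = 0.7
    anomaly_exact_duplicate: float = 0.02
    anomaly_nested: float = 0.02
    anomaly_overlap: float = 0.02
    anomaly_duplicate_period: float = 0.01
    anomaly_short_gap: float = 0.03
    anomaly_long_gap: float = 0.02
    exclusion_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        fracs = [
            self.frac_in_sail,
            self.backdating_fraction,
            self.sentinel_fraction,
            self.future_fraction,
            self.snap_jan1,
            self.snap_month_first,
            self.frac_present_from_start,
            self.return_prob,
            self.exclusion_rate,
            self.anomaly_exact_duplicate,
            self.anomaly_nested,
            self.anomaly_overlap,
            self.anomaly_duplicate_period,
            self.anomaly_short_gap,
            self.anomaly_long_gap,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions/probabilities must lie in [0, 1]")
        if self.sentinel_fraction + self.future_fraction + self.backdating_fraction > 1:
            raise ValueError("pathology fractions sum to more than 1")
        if self.snap_jan1 + self.snap_month_first > 1:
            raise ValueError("snap probabilities sum to more than 1")
        if min(self.move_rate, self.emigration_rate, self.events_per_person_month) < 0:
            raise ValueError("rates must be non-negative")
        if self.n_practices < 1:
            raise ValueError("need at least one practice")
        anomalous = (
            self.anomaly_exact_duplicate
            or self.anomaly_nested
            or self.anomaly_overlap
            or self.anomaly_duplicate_period
            or self.anomaly_short_gap
        )
        if self.n_persons < 1 and anomalous:
            raise ValueError("positive anomaly rates require at least one person")
        if self.study_start >= self.censor:
            raise ValueError("study_start must precede censor")
        if self.onset_shape not in ("abrupt", "linear_ramp"):
            raise ValueError(f"unknown onset_shape {self.onset_shape!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("study_start", "censor"):
            d[k] = d[k].isoformat()
        d["onset_year_range"] = list(d["onset_year_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for k in ("study_start", "censor"):
            if k in d and isinstance(d[k], str):
                d[k] = date.fromisoformat(d[k])
        if "onset_year_range" in d:
            d["onset_year_range"] = tuple(d["onset_year_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that the tables do not say."""

    practices: pd.DataFrame  # practice_id, in_sail, true_start, true_end
    clean_registrations: pd.DataFrame  # person_id, practice_id, start, end, open_end
    presence: dict  # (group_on_sail_data, group_on_practice) -> presence table
    erroneous: np.ndarray  # bool per row of the events table
    anomaly_log: pd.DataFrame  # person_id, kind
    censor: date = date(2016, 1, 1)


def _generate_practices(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"P{i:03d}" for i in range(config.n_practices)]
    n_sail = int(round(config.frac_in_sail * config.n_practices))
    sail_idx = rng.choice(config.n_practices, size=n_sail, replace=False)
    in_sail = np.zeros(config.n_practices, dtype=bool)
    in_sail[sail_idx] = True
    y0, y1 = config.onset_year_range
    rows = []
    for i, pid in enumerate(ids):
        if in_sail[i]:
            year = int(rng.integers(y0, y1 + 1))
            month = int(rng.integers(1, 13))
            true_start = month_first(year, month)
            lag = int(rng.integers(0, config.extract_lag_max_days + 1)) if config.extract_lag_max_days else 0
            extract = config.censor - timedelta(days=lag)
            rows.append((pid, True, true_start, extract - timedelta(days=1), extract))
        else:
            rows.append((pid, False, None, None, None))
    return pd.DataFrame(
        rows, columns=["practice_id", "in_sail", "true_start", "true_end", "extract_date"]
    )


def _person_spells(
    config: ScenarioConfig, rng: np.random.Generator
) -> list[tuple[str, date, date, bool]]:
    """Clean spells for one person: (practice_id, start, end, open_end)."""
    span_days = (config.censor - config.study_start).days
    if rng.random() < config.frac_present_from_start or span_days <= 365:
        entry = config.study_start
    else:
        entry = config.study_start + timedelta(days=int(rng.integers(0, span_days - 365)))
    spells = []
    t = entry
    practice = f"P{int(rng.integers(0, config.n_practices)):03d}"
    while t < config.censor:
        dt_move = (
            rng.exponential(1.0 / config.move_rate) if config.move_rate > 0 else math.inf
        )
        dt_emig = (
            rng.exponential(1.0 / config.emigration_rate)
            if config.emigration_rate > 0
            else math.inf
        )
        dt = min(dt_move, dt_emig)
        if math.isinf(dt):
            spells.append((practice, t, config.censor, True))
            break
        n_days = max(2, int(round(dt * 365.25)))
        end = t + timedelta(days=n_days - 1)
        if end >= config.censor:
            spells.append((practice, t, config.censor, True))
            break
        spells.append((practice, t, end, False))
        if dt_move <= dt_emig:  # moved practice
            gap = 0
            if rng.random() < config.anomaly_long_gap:
                gap = int(rng.integers(31, 181))
            t = end + timedelta(days=1 + gap)
        else:  # emigrated
            if rng.random() >= config.return_prob:
                break
            t = end + timedelta(days=int(rng.integers(183, 1826)))
        practice = f"P{int(rng.integers(0, config.n_practices)):03d}"
    return spells


def _ramp_factor(days: np.ndarray, true_start: date, config: ScenarioConfig) -> np.ndarray:
    if config.onset_shape == "abrupt":
        return np.ones(len(days))
    months = (days - true_start.toordinal()) / 30.4375
    return np.clip((months + 1.0) / config.ramp_months, 0.0, 1.0)


def _spell_events(
    practice_row,
    start: date,
    end: date,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Event-day ordinals for one person-spell at a contributing practice."""
    lo = max(start, practice_row.true_start)
    hi = min(end, practice_row.true_end)
    if lo > hi:
        return np.empty(0, dtype=np.int64)
    days = np.arange(lo.toordinal(), hi.toordinal() + 1, dtype=np.int64)
    dow = (days - _EPOCH_MONDAY) % 7
    w = np.where(dow < 5, 1.0, config.weekend_weight)
    w = w * _ramp_factor(days, practice_row.true_start, config)
    total = w.sum()
    if total <= 0:
        return np.empty(0, dtype=np.int64)
    lam = config.events_per_person_month / _AVG_WEEKDAYS_PER_MONTH
    n = rng.poisson(lam * total)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(days, size=n, p=w / total)


def _apply_event_pathologies(
    ordinals: np.ndarray, config: ScenarioConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Re-date a configured share of events; returns (ordinals, erroneous)."""
    n = len(ordinals)
    out = ordinals.copy()
    erroneous = np.zeros(n, dtype=bool)
    u = rng.random(n)
    s, f, b = config.sentinel_fraction, config.future_fraction, config.backdating_fraction

    sent = u < s
    out[sent] = date(1900, 1, 1).toordinal()
    erroneous |= sent

    fut = (u >= s) & (u < s + f)
    out[fut] = config.censor.toordinal() + rng.integers(1, 1096, size=int(fut.sum()))
    erroneous |= fut

    back = (u >= s + f) & (u < s + f + b)
    years = 1970 + (ordinals - _ORD_1970).astype("datetime64[D]").astype(
        "datetime64[Y]"
    ).astype(np.int64)
    back &= years > config.backdate_floor_year  # no earlier year to move to
    k = int(back.sum())
    if k:
        yb = years[back]
        # uniform earlier year in [floor, original year - 1]
        ny = config.backdate_floor_year + (
            rng.random(k) * (yb - config.backdate_floor_year)
        ).astype(np.int64)
        v = rng.random(k)
        new_ord = _jan1_ordinal(ny) + rng.integers(0, 365, size=k)  # unsnapped
        snap_m = v < config.snap_jan1 + config.snap_month_first
        months = rng.integers(1, 13, size=k)
        new_ord[snap_m] = _month_first_ordinal(ny[snap_m], months[snap_m])
        snap_j = v < config.snap_jan1
        new_ord[snap_j] = _jan1_ordinal(ny[snap_j])
        out[back] = new_ord
    erroneous |= back
    return out, erroneous


def _inject_registration_anomalies(
    spells: list[tuple[str, date, date, bool]],
    practices: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, date, Optional[date]]], list[str]]:
    """Emitted (possibly corrupted) rows for one person's history.

    Each injection is reversible by the cleaning rules; the spells touched
    by interval mutations are kept disjoint so the injections cannot
    interact.  Open ends are emitted as ``None``.
    """
    rows: list[tuple[str, date, Optional[date]]] = [
        (p, s, (None if op else e)) for (p, s, e, op) in spells
    ]
    kinds: list[str] = []
    used: set[int] = set()
    # adjacent pairs eligible for gap/overlap mutations
    adj = [
        i
        for i in range(len(spells) - 1)
        if not spells[i][3]
        and spells[i + 1][1] == spells[i][2] + timedelta(days=1)
        and (spells[i + 1][2] - spells[i + 1][1]).days >= 2
    ]
    rng.shuffle(adj)
    if adj and rng.random() < config.anomaly_short_gap:
        i = adj.pop()
        p, s, e, op = spells[i + 1]
        g = int(rng.integers(1, min(30, (e - s).days) + 1))
        rows[i + 1] = (p, s + timedelta(days=g), rows[i + 1][2])
        used.update((i, i + 1))
        kinds.append("short_gap")
    if adj and rng.random() < config.anomaly_overlap:
        i = adj.pop()
        p, s, e, op = spells[i]
        nxt_len = (spells[i + 1][2] - spells[i + 1][1]).days  # >= 2 by eligibility
        d = int(rng.integers(1, min(30, nxt_len) + 1))
        rows[i] = (p, s, e + timedelta(days=d))
        used.update((i, i + 1))
        kinds.append("overlap")
    free = [
        i
        for i in range(len(spells))
        if i not in used and (spells[i][2] - spells[i][1]).days >= 3
    ]
    rng.shuffle(free)
    if free and rng.random() < config.anomaly_nested:
        i = free.pop()
        p, s, e, op = spells[i]
        span = (e - s).days + 1
        inner_len = int(rng.integers(1, min(90, span - 1) + 1))
        off = int(rng.integers(0, span - inner_len + 1))
        inner_start = s + timedelta(days=off)
        q = f"P{int(rng.integers(0, config.n_practices)):03d}"
        if q == p:
            q = f"P{(int(q[1:]) + 1) % config.n_practices:03d}"
        rows.append((q, inner_start, inner_start + timedelta(days=inner_len - 1)))
        kinds.append("nested")
    if rng.random() < config.anomaly_duplicate_period and spells:
        i = int(rng.integers(0, len(spells)))
        p = rows[i][0]
        p_sail = bool(practices.set_index("practice_id")["in_sail"].get(p, False))
        losers = [
            r.practice_id
            for r in practices.itertuples()
            if (p_sail and not r.in_sail)
            or (bool(r.in_sail) == p_sail and r.practice_id > p)
        ]
        if losers:
            q = losers[int(rng.integers(0, len(losers)))]
            rows.append((q, rows[i][1], rows[i][2]))
            kinds.append("duplicate_period")
    if rng.random() < config.anomaly_exact_duplicate and rows:
        i = int(rng.integers(0, len(rows)))
        rows.append(rows[i])
        kinds.append("exact_duplicate")
    return rows, kinds


def _collapse_runs(
    person_id: str,
    days: np.ndarray,
    practices: np.ndarray,
    flags: np.ndarray,
    combo: tuple[int, int],
) -> list[tuple]:
    """Collapse day-level (day, practice, flag) tuples into presence rows."""
    if len(days) == 0:
        return []
    gos, gop = combo
    key = np.zeros(len(days), dtype=np.int64)
    codes, inv = np.unique(practices, return_inverse=True)
    if gos:
        key = key * 2 + flags
    if gop:
        key = key * (len(codes) + 1) + inv
    brk = np.flatnonzero((np.diff(days) != 1) | (np.diff(key) != 0))
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [len(days) - 1]))
    rows = []
    for a, b in zip(starts, ends):
        prac = codes[inv[a]] if len(np.unique(inv[a : b + 1])) == 1 else MERGED
        fl_unique = np.unique(flags[a : b + 1])
        fl = bool(fl_unique[0]) if len(fl_unique) == 1 else None
        rows.append(
            (
                person_id,
                prac,
                date.fromordinal(int(days[a])),
                date.fromordinal(int(days[b])),
                fl,
            )
        )
    return rows


def _truth_presence(
    person_id: str,
    spells: list[tuple[str, date, date, bool]],
    exclusions: list[tuple[date, date]],
    practices: pd.DataFrame,
    censor: date,
) -> dict[tuple[int, int], list[tuple]]:
    """Ground-truth presence at day resolution for all four groupings."""
    meta = practices.set_index("practice_id")
    day_arrays, prac_arrays, flag_arrays = [], [], []
    for p, s, e, op in spells:
        e = min(e, censor)
        if s > e:
            continue
        d = np.arange(s.toordinal(), e.toordinal() + 1, dtype=np.int64)
        row = meta.loc[p]
        if bool(row["in_sail"]):
            t0, t1 = row["true_start"].toordinal(), row["true_end"].toordinal()
            fl = (d >= t0) & (d <= t1)
        else:
            fl = np.zeros(len(d), dtype=bool)
        day_arrays.append(d)
        prac_arrays.append(np.full(len(d), p))
        flag_arrays.append(fl)
    if not day_arrays:
        return {c: [] for c in ((0, 0), (1, 0), (0, 1), (1, 1))}
    days = np.concatenate(day_arrays)
    order = np.argsort(days)
    days = days[order]
    pracs = np.concatenate(prac_arrays)[order]
    flags = np.concatenate(flag_arrays)[order].astype(np.int64)
    out = {}
    for combo in ((0, 0), (1, 0), (0, 1), (1, 1)):
        rows = _collapse_runs(person_id, days, pracs, flags, combo)
        # known-missing periods are clipped out *after* aggregation, so the
        # surviving pieces keep the labels of the record they came from
        for xs, xe in exclusions:
            clipped = []
            for pid, prac, s, e, fl in rows:
                if xe < s or xs > e:
                    clipped.append((pid, prac, s, e, fl))
                    continue
                if s < xs:
                    clipped.append((pid, prac, s, xs - timedelta(days=1), fl))
                if e > xe:
                    clipped.append((pid, prac, xe + timedelta(days=1), e, fl))
            rows = clipped
        out[combo] = rows
    return out


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a full consistent dataset plus its ground truth.

    Returns ``(events, registrations, practice_meta, exclusions, truth)``
    in the loader schemas.  Every non-erroneous event lies inside a true
    presence interval at its true practice of registration, by
    construction.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    prac_ss, path_ss, *person_ss = root.spawn(2 + config.n_persons)
    rng_prac = np.random.default_rng(prac_ss)
    practices = _generate_practices(config, rng_prac)
    sail_rows = {r.practice_id: r for r in practices[practices["in_sail"]].itertuples()}

    reg_rows = []
    event_person, event_practice, event_day = [], [], []
    clean_rows = []
    presence: dict[tuple[int, int], list] = {c: [] for c in ((0, 0), (1, 0), (0, 1), (1, 1))}
    anomaly_rows = []
    excl_rows = []
    for idx in range(config.n_persons):
        person_id = f"I{idx:06d}"
        rng = np.random.default_rng(person_ss[idx])
        spells = _person_spells(config, rng)
        if not spells:
            continue
        clean_rows.extend(
            (person_id, p, s, min(e, config.censor), op) for (p, s, e, op) in spells
        )
        exclusions: list[tuple[date, date]] = []
        if config.exclusion_rate and rng.random() < config.exclusion_rate:
            p, s, e, op = spells[int(rng.integers(0, len(spells)))]
            span = (min(e, config.censor) - s).days + 1
            length = int(rng.integers(30, min(365, max(31, span)) + 1))
            off = int(rng.integers(0, max(1, span - length + 1)))
            xs = s + timedelta(days=off)
            xe = min(xs + timedelta(days=length - 1), config.censor)
            exclusions.append((xs, xe))
            excl_rows.append((person_id, xs, xe))
        for combo, rows in _truth_presence(
            person_id, spells, exclusions, practices, config.censor
        ).items():
            presence[combo].extend(rows)
        for p, s, e, op in spells:
            row = sail_rows.get(p)
            if row is None:
                continue
            ords = _spell_events(row, s, min(e, config.censor), config, rng)
            if len(ords):
                event_person.append(np.full(len(ords), person_id))
                event_practice.append(np.full(len(ords), p))
                event_day.append(ords)
        rows, kinds = _inject_registration_anomalies(spells, practices, config, rng)
        reg_rows.extend((person_id, p, s, e) for (p, s, e) in rows)
        anomaly_rows.extend((person_id, k) for k in kinds)

    if event_day:
        ordinals = np.concatenate(event_day)
        persons = np.concatenate(event_person)
        pracs = np.concatenate(event_practice)
    else:
        ordinals = np.empty(0, dtype=np.int64)
        persons = pracs = np.empty(0, dtype=object)
    rng_path = np.random.default_rng(path_ss)
    ordinals, erroneous = _apply_event_pathologies(ordinals, config, rng_path)
    events = pd.DataFrame(
        {
            "person_id": persons,
            "practice_id": pracs,
            "event_date": _ordinals_to_timestamps(ordinals),
        }
    )

    registrations = pd.DataFrame(
        reg_rows, columns=["person_id", "practice_id", "start", "end"]
    )
    registrations["start"] = pd.to_datetime(registrations["start"])
    registrations["end"] = pd.to_datetime(registrations["end"])

    practice_meta = practices[["practice_id", "in_sail", "extract_date"]].copy()
    practice_meta["extract_date"] = pd.to_datetime(practice_meta["extract_date"])

    exclusions_df = pd.DataFrame(excl_rows, columns=["person_id", "start", "end"])
    if len(exclusions_df):
        exclusions_df["start"] = pd.to_datetime(exclusions_df["start"])
        exclusions_df["end"] = pd.to_datetime(exclusions_df["end"])

    clean_df = pd.DataFrame(
        clean_rows, columns=["person_id", "practice_id", "start", "end", "open_end"]
    )
    clean_df["start"] = pd.to_datetime(clean_df["start"])
    clean_df["end"] = pd.to_datetime(clean_df["end"])

    presence_tables = {}
    for combo, rows in presence.items():
        df = pd.DataFrame(
            rows, columns=["person_id", "practice_id", "start", "end", "sail_data"]
        )
        if len(df):
            df["start"] = pd.to_datetime(df["start"])
            df["end"] = pd.to_datetime(df["end"])
        df["sail_data"] = df["sail_data"].astype(object)
        presence_tables[combo] = df

    truth = GroundTruth(
        practices=practices[["practice_id", "in_sail", "true_start", "true_end"]].copy(),
        clean_registrations=clean_df,
        presence=presence_tables,
        erroneous=erroneous,
        anomaly_log=pd.DataFrame(anomaly_rows, columns=["person_id", "kind"]),
        censor=config.censor,
    )
    return events, registrations, practice_meta, exclusions_df, truth


def simulate_cohort(
    truth: GroundTruth,
    seed: int,
    p_outcome: float = 0.5,
    horizon_years: int = 10,
    diag_years: tuple[int, int] = (2001, 2005),
    diag_source: str = "presence",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diagnosis dates and outcome events with a known true annual rate.

    Each cohort member gets a diagnosis date drawn uniformly from their
    days within ``diag_years`` — days with data truly available when
    ``diag_source="presence"`` (a condition spotted in the dataset
    itself), or any truly-registered day when
    ``diag_source="registration"`` (a diagnosis known from a linked
    source, possibly outside coverage).  In each follow-up year an
    outcome occurs with probability ``p_outcome``, dated uniformly within
    the year, and is *recorded* only if the date falls inside true
    in-dataset presence — so the true per-presence-year rate is
    ``p_outcome`` and any shortfall measured under a weaker follow-up
    requirement is attributable to unobserved person-time.
    """
    from dateutil.relativedelta import relativedelta

    if diag_source not in ("presence", "registration"):
        raise ValueError(f"unknown diag_source {diag_source!r}")
    rng = np.random.default_rng(seed)
    sail = truth.presence[(1, 0)]
    sail = sail[sail["sail_data"] == True]  # noqa: E712
    registered = sail if diag_source == "presence" else truth.presence[(0, 0)]
    sail_by_person = dict(tuple(sail.groupby("person_id", sort=True)))
    lo = date(diag_years[0], 1, 1).toordinal()
    hi = date(diag_years[1], 12, 31).toordinal()
    cohort_rows = []
    outcome_rows = []
    for person_id, reg_group in registered.groupby("person_id", sort=True):
        days = np.concatenate(
            [
                np.arange(
                    max(pd.Timestamp(r.start).toordinal(), lo),
                    min(pd.Timestamp(r.end).toordinal(), hi) + 1,
                )
                for r in reg_group.itertuples()
            ]
            or [np.empty(0, dtype=np.int64)]
        )
        days = days[(days >= lo) & (days <= hi)]
        if len(days) == 0:
            continue
        diag = date.fromordinal(int(rng.choice(days)))
        cohort_rows.append((person_id, diag))
        group = sail_by_person.get(person_id)
        if group is None:
            continue
        all_days = np.concatenate(
            [
                np.arange(
                    pd.Timestamp(r.start).toordinal(), pd.Timestamp(r.end).toordinal() + 1
                )
                for r in group.itertuples()
            ]
        )
        present = set(all_days.tolist())
        for k in range(horizon_years):
            if rng.random() >= p_outcome:
                continue
            y0 = diag + relativedelta(years=k)
            y1 = diag + relativedelta(years=k + 1) - timedelta(days=1)
            d = int(rng.integers(y0.toordinal(), y1.toordinal() + 1))
            if d in present:
                outcome_rows.append((person_id, date.fromordinal(d)))
    cohort = pd.DataFrame(cohort_rows, columns=["person_id", "diagnosis_date"])
    outcomes = pd.DataFrame(outcome_rows, columns=["person_id", "event_date"])
    for df, col in ((cohort, "diagnosis_date"), (outcomes, "event_date")):
        if len(df):
            df[col] = pd.to_datetime(df[col])
    return cohort, outcomes
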