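# Methods

## Problem and model

A person contributes follow-up time to a primary-care dataset only while two
conditions hold simultaneously: they are registered with a GP practice, and
that practice's electronic data for that period actually exists in the
dataset. Neither condition is directly recorded. The start of electronic
record-keeping at a practice is unknown and cannot be read off the earliest
event date, because event dates are user-entered: unknown dates are parked on
sentinels (1900-01-01 above all), some dates lie in the future, and genuine
retrospective coding piles events on 1 January (year known) or the first of a
month (month known). Registration histories, meanwhile, carry duplicate rows,
nested and overlapping spells, identical spells at two practices, and short
unregistered gaps from delayed re-registration.

The package therefore works entirely from aggregate event volumes and
registration records — never from whether an individual has events, which
would bias the covered population toward care users.

## Step 1 — practice coverage

For practice *p* and calendar month *m*:

* `registered_count(p, m)` — distinct persons whose registration interval
  contains the 15th of *m*. Months with `registered_count <= min_registered`
  (default 5) are **excluded**: they indicate missing registration data, not
  absence of recording, and are treated as missing (skipped), not as zero.
* `raw_rate(p, m)` — the median over the *weekday calendar days* of *m* of
  that day's total event count (zero-filled), divided by
  `registered_count`. The median is taken across days, not persons: this is
  what makes it robust to single-day spikes (backdating to 1 January, bulk
  administrative uploads). Weekends are down-weighted in reality rather than
  absent, so only weekdays enter; public holidays are not modelled — they
  appear as low-count weekdays and the median absorbs them. The proleptic
  Gregorian calendar determines weekdays.
* `normalized_rate(p, m) = raw_rate(p, m) / reference_rate(p)`, where
  `reference_rate` is the median of the non-excluded raw rates in the
  practice's reference year. The preferred reference year (default 2009) is
  used whenever the practice has any counted month then; otherwise the first
  year with at least `reference_min_registrations` (default 100)
  registration records starting before its 1 January. If no year qualifies,
  or the reference rate is zero, the practice is reported uncoverable with a
  warning.

**Start date.** `data_start` is the first day of the earliest counted month
whose normalized rate reaches `threshold` (default 0.10) and holds it for
`sustain_months` (default 3) consecutive counted months (fewer at the end of
the series). A bare first-crossing rule would fire on isolated noise months;
the sustained-crossing rule is exposed as a parameter, and `sustain_months=1`
recovers plain first crossing. Excluded months are skipped in this scan.

**End date.** The candidate end is `extract_date − 1 day`. It is accepted
when the last *complete* counted month before it still meets the threshold;
otherwise (recording stopped early, e.g. a closed practice extracting late)
the end is the last day of the latest month that met it. The month containing
the extract is truncated mid-month and would read as a spuriously low rate,
which is why the check uses the last complete month. The same user threshold
is used for the start and end checks.

The monthly table is computed over months from the practice's first
registration to the extract; sentinel-dated and future events fall outside
this range and influence nothing (verified by an invariance test).

## Step 2 — individual presence

Per person, in fixed order:

1. **Materialize** open ends to the global censor date (default: the latest
   extract date across practices; recorded in run metadata) and clip at it.
2. **Clean** (order: exact duplicates → duplicate periods → nested →
   overlaps):
   * exact duplicates collapse to one row;
   * identical spans at different practices keep the contributing practice,
     then the lexicographically lower practice id — applied always,
     whatever output options are requested, so the same record wins in
     every run;
   * a spell wholly contained in an earlier-starting spell is dropped
     (outer kept). Same-start spells with different ends are treated as
     nested (shorter inside longer) — a case the three canonical rules do
     not cover; keeping the longer record minimizes fragmentation;
   * overlaps shorten the first record to end the day before the second
     starts (the overlap period belongs to the better-evidenced second
     registration). Chains of ≥ 3 overlapping records are processed
     left-to-right to a fixpoint.
   Every mutation is logged as one conflict report.
3. **Close short gaps**: a gap of 1..`max_gap_days` (default 30) whole days
   between consecutive spells is awarded to the *second* practice by moving
   its start back — a person needing care during such a gap would have
   registered earlier. Intervals are closed on both ends; adjacency means
   `next.start = prev.end + 1`, and the gap counts the days strictly
   between, so "a gap of up to 30 empty days" is closable and
   `max_gap_days = 0` disables the feature.
4. **Split at coverage boundaries**: the part of a spell inside
   `[data_start, data_end]` is flagged as having data; remainders (and all
   spells at non-contributing or uncoverable practices) are flagged
   without. Gap-closing runs *before* splitting so a closed gap inherits
   the second practice's coverage status; splitting always precedes
   merging.
5. **Merge adjacent records** under the two switches (see README table).
   Cross-practice merges carry a `MERGED` sentinel; a merged record
   spanning mixed availability carries `sail_data = None` (not-tracked)
   rather than a misleading boolean.
6. **Subtract exclusion periods** (known per-person missing data), clipping
   or splitting records; pieces keep the labels of the record they came
   from.

The output is, per person, sorted and pairwise non-overlapping, and is
checked in the tests against a day-level brute-force restatement of every
rule (ownership of each day = the latest-starting surviving record covering
it, which is equivalent to the interval rules).

## Synthetic data

The generator's job is to reproduce the *signatures* of the documented
pathologies with recorded ground truth — not any real population's
epidemiology. Study span 2000-01-01 to 2016-01-01; defaults: 20 practices of
which 76% contribute data, 1000 persons, onset months drawn uniformly
2000–2008 (snapped to month firsts — deployments are treated as starting
with a month), abrupt onset (a linear ramp over a configurable number of
months is available), extracts on the censor date.

* **Histories**: entry at study start (70%) or staggered; moves between
  practices at 0.10/person-year (the target may be the same practice,
  producing the legitimate consecutive-same-practice quirk); emigration at
  0.02/person-year with 50% probability of return after 0.5–5 years.
* **Events**: per person-spell, Poisson with mean
  `events_per_person_month / 21.7` per weekday-equivalent day (weekends
  weighted 0.15), only while the practice is truly recording. 2 events per
  person-month approximates the volume of coded primary-care activity
  (consultations, prescriptions, results).
* **Date pathologies**: configurable fractions of events are re-dated to
  1900-01-01 (0.5%), the future (0.2%), or backdated (5%) to a uniform
  earlier year and snapped to 1 January with probability 0.6, a month first
  with 0.3, unsnapped otherwise. All displaced events are flagged erroneous
  in the ground truth.
* **Registration anomalies** (per-history probabilities, each a few
  percent): duplicate rows, nested spells, partial overlaps, identical
  spans, short gaps. Each injection is constructed to be exactly reversible
  by the cleaning rules — e.g. an injected duplicate period is placed at a
  practice that loses the preference ordering, and the spells touched by
  interval mutations are kept disjoint — so the pre-injection truth remains
  the correct answer. Long gaps are the deliberate exception: the pipeline
  leaves gaps > `max_gap_days` open by design, so they are generated as
  genuine features of the clean history and the truth includes them.
* **Ground truth** is evaluated at day resolution from the clean history
  and true coverage, collapsed to intervals under each of the four grouping
  combinations with the same exclusion-last ordering as the pipeline.

What passing tests on this generator do *not* show: performance on real
registration data with pathologies outside this catalogue (e.g. clock skew
between systems, practice mergers re-keying identifiers, gradual
multi-year onsets mixed with volume trends), or realistic Welsh demography.
The generator makes onset detection *exactly* recoverable under its default
conditions; the acceptance thresholds (≥ 95% starts within 31 days, ≥ 90% /
≥ 98% event capture) are generator-conditional design targets, not
reproductions of any real-data figure.

* **Cohort simulation**: diagnosis dates are drawn uniformly from each
  person's days in 2001–2005, either from days with data truly available
  (`diag_source="presence"`, a condition spotted in the dataset itself —
  the setting for the divergence-over-follow-up property) or from any
  truly-registered day (`diag_source="registration"`, a diagnosis known
  from a linked source, which makes the present-at-diagnosis requirement a
  real restriction); outcomes occur at 0.5/follow-up-year and are recorded
  only when the date falls in true in-dataset presence. The true
  per-presence-year rate is therefore known (0.5), and the shortfall
  measured under weak follow-up requirements is attributable, by
  construction, to unobserved person-time.

## Follow-up impact analysis

Follow-up years are anchored at each person's diagnosis date (year *k* =
`[diagnosis + k years, diagnosis + (k+1) years)`), matching rate curves
plotted against "years since diagnosis"; whether "present at start of year"
means calendar or anchored years was an open choice, resolved in favour of
anchored. `present_entire_year` and `present_entire_horizon` require a
*single* presence span to cover the interval — continuous availability, not
patchwork coverage. The annual rate is the fraction of eligible persons with
at least one outcome event in year *k*; a year with zero eligible persons
reports an absent rate, not 0.

## Numerical and interface choices

* Excluded months are `NaN` in tabular form, `None` scalar.
* All spells are closed intervals of calendar dates; no times or time zones.
* Practice preference uses lexicographic order on the opaque identifier —
  any fixed total order satisfies the determinism requirement.
* `count_registered_on_15th` counts *distinct* persons, so not-yet-cleaned
  duplicate registrations do not double-count.
* The monthly-rates intermediate is persisted and reused when a SHA-256
  content hash of the inputs (plus the rate-relevant parameters and censor
  date) is unchanged; coverage and presence are always recomputed, so
  changing only the threshold reuses the rates.
* Row-level input problems are rejected with reason codes and logged, never
  silently dropped; a missing column is fatal.
* Test and acceptance problem sizes (100 practices / 5000 persons for
  start-date recovery; 1000 persons × ~15 years for the day-level oracle
  comparison; 500 persons for exact recovery) were chosen to give stable
  statistics at desk scale.

## Known limitations

* Un-deregistered emigrants inflate apparent follow-up; registration data
  cannot detect them and no mitigation is attempted.
* The coverage algorithm assumes a roughly stationary post-onset recording
  rate; a practice whose volume later collapses below threshold for a spell
  is still assigned a single `[data_start, data_end]` interval.
* Holidays and local closures are absorbed by the median rather than
  modelled.
* The day before the extract is taken as the data end even though the last
  partial month is never checked directly (only complete months are).
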