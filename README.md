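# ehrpresence

Measure **individual follow-up time** in routinely-collected primary-care
datasets.

Longitudinal studies on administrative health data must know *who is in the
data, and when*: a person with no recorded events may be a healthy member of
the covered population — or simply absent from the dataset. In a primary-care
databank where practices opt in individually, a person's follow-up is the
intersection of two things: the period over which their practice's electronic
data actually exists, and their own registration history (moves, emigration,
administrative errors). Using recorded events as a presence signal biases
cohorts toward care users, so both ingredients must be derived from
registration and aggregate volumes only.

`ehrpresence` implements a two-step algorithm:

1. **Practice coverage.** For every contributing practice and calendar month,
   count the persons registered on the 15th (months with ≤ 5 registered are
   excluded) and compute the *median* over weekday days of the daily event
   count per registered person — the median resists the 1-January /
   month-first spikes produced by backdated and sentinel-dated events. Rates
   are normalized to a reference year (2009 by default, or the first year
   with ≥ 100 pre-existing registrations) and the data start is the first
   month sustaining a user threshold (default 10%). The data end is the day
   before the last extract unless recording demonstrably stopped earlier.
2. **Individual presence.** Each person's registration history is cleaned by
   deterministic conflict rules (exact duplicates collapse; identical spans
   prefer the contributing practice, then the lower practice id; nested
   spells keep the outer record; overlaps end the first record the day
   before the second starts), short gaps (≤ 30 days by default) are awarded
   to the second practice, registrations are split at coverage boundaries,
   and adjacent records are merged under two switches:

   | `group_on_sail_data` | `group_on_practice` | output |
   |---|---|---|
   | 0 | 0 | continuous any-GP registration periods |
   | 1 | 0 | periods with data available in the dataset |
   | 0 | 1 | cleaned per-practice registration history |
   | 1 | 1 | cleaned history + data-availability flag |

Because no real extract of this kind can be shared, the package includes a
first-class synthetic-data generator (`ehrpresence.simulate`) that reproduces
the documented pathologies — 1900-01-01 sentinels, future dates, backdating
snapped to year/month firsts, duplicate/nested/overlapping registrations,
short gaps — with full ground truth, plus a follow-up-impact analysis
(`ehrpresence.analysis`) comparing annual outcome rates under five
eligibility requirements (none / at diagnosis / at year start / entire year /
entire horizon).

## Worked example

```python
from ehrpresence import (ScenarioConfig, generate_scenario, Parameters,
                         compute_all_coverage, build_presence)

cfg = ScenarioConfig(n_practices=6, n_persons=400, seed=42, backdating_fraction=0.1)
events, regs, meta, excl, truth = generate_scenario(cfg)

cov, monthly, warnings_ = compute_all_coverage(events, regs, meta, Parameters())
print(cov.to_string(index=False))
```

```
practice_id data_start   data_end  reference_year
       P000 2008-11-01 2015-12-31            2009
       P001 2001-12-01 2015-12-31            2009
       P002 2008-08-01 2015-12-31            2009
       P003 2006-10-01 2015-12-31            2009
       P004 2001-01-01 2015-12-31            2009
```

Each row is one contributing practice: the inferred first month of usable
electronic recording, the inferred end of data (here: the day before the
extract), and the reference year used for normalization. Despite 10% of
events being backdated before the true onset, every `data_start` equals the
generator's true onset (`truth.practices`). Building presence with the
"periods with data available" grouping:

```python
params = Parameters(group_on_sail_data=1, group_on_practice=0)
presence, conflicts = build_presence(regs, cov, excl, meta, params, truth.censor)
print(presence.head(3).to_string(index=False))
print(conflicts["conflict_kind"].value_counts().to_dict())
```

```
person_id practice_id      start        end sail_data
  I000000        P004 2000-01-01 2000-12-31     False
  I000000        P004 2001-01-01 2015-12-31      True
  I000000        P004 2016-01-01 2016-01-01     False
{'nested': 7, 'overlap': 7, 'exact_duplicate': 4, 'duplicate_period': 1}
```

Person `I000000` is registered throughout, but only 2001-01-01 to 2015-12-31
falls inside their practice's coverage (`sail_data = True`): that interval
is their usable follow-up time. The conflict report counts every mutation
the cleaning rules made.

The same pipeline is available from the shell:

```bash
ehrpresence simulate --seed 7 --cohort --out-dir sim
ehrpresence presence --events sim/events.csv --registrations sim/registrations.csv \
    --practice-meta sim/practice_meta.csv --group-on-sail-data 1 --out-dir out
ehrpresence impact --presence out/presence.csv --cohort sim/cohort.csv \
    --events sim/outcome_events.csv --out impact.csv
```

All tables are plain CSV with ISO dates; open registration ends are an empty
`end` field, materialized to the censor date (the latest extract date) at
load. Schemas: events `person_id,practice_id,event_date`; registrations
`person_id,practice_id,start,end`; practice metadata
`practice_id,in_sail,extract_date`; exclusions `person_id,start,end`;
presence output `person_id,practice_id,start,end,sail_data`.

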