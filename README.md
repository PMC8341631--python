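# odtcube

Origin–destination–time (ODT) mobility cubes: extraction of daily
origin–destination flows from heterogeneous movement records, their
aggregation into a sparse multi-scale data cube with OLAP-style query
operations, a standard CSV flow-export dialect, and downstream
epidemic-mobility analyses.

## Who this is for

Researchers in spatial epidemiology, transport and human-mobility
science who need place-to-place daily flow matrices — "how many people
moved from county *i* to county *j* on day *t*" — derived from point
observations (geotagged social-media posts) or from home-based
device-count summaries, and who then want to query those flows at
several geographic scales and relate them to epidemic case counts.

## The model

**The ODT cube.** Entity-level movements are first organised as a 4D
table (entity, origin place, destination place, day), then aggregated
into a sparse 3D cube `C[o, d, t]` = the number of entities (or
devices) that moved from place *o* to place *d* on day *t*.  Slicing
the cube yields the OD matrix (flows between places over a period),
the OT matrix (outflows per origin-day) and the DT matrix (inflows per
destination-day); the OD diagonal (`o = d`) holds intra-place
movements.  Roll-up re-keys the cube to a coarser geographic level
through a place hierarchy (block group → county → state), or to
coarser time bins (ISO week, calendar month); dicing restricts it to a
subcube by place sets and a closed date interval.

**Flow extraction from event streams.**  For each entity and day with
at least two events, the *single-day* movement runs from the day's
chronologically first event to the event farthest (great-circle) from
that initial location.  For each pair of consecutive active days, the
*cross-day* movement runs from the first day's mean center of event
coordinates to the second day's.  Zero-distance movements are
discarded, automated accounts are removed by posting-client source
rules, and an entity contributes at most once per (origin,
destination, day) cell.

**Flow extraction from home-based records.**  A record gives a home
census block group, a map `destination cbg → device count`, and a
date; each map entry becomes a weighted home-based flow.  Weights sum
under aggregation, so coarser levels deliberately over-count distinct
visitors, as the underlying data product does.

**Analyses.**  The mobility reduction rate of period *i* against a
baseline period is `R_i = (M_i − M_base) / M_base` on total flow
masses.  The outflow–case correlation fixes a focal place and a short
flow window, forms the vector of windowed outflows to every other
place (zero for places without a stored cell), and correlates it
(Pearson, by default) with each day's cumulative case counts across
places.

A seeded synthetic-data module generates every input — nested grid
geographies with FIPS-like codes, random-walker event streams with a
bot sub-population, home-based records, and case tables with a planted
linear dependence on flows — together with ground-truth flow tables
computed by an independent straight-line implementation of the rules.

## Worked example

```python
from datetime import timedelta
from odtcube import (synth, extract_entity_flows, SourceRules, build_cube,
                     rollup_spatial, place_series, reduction_rate)
from odtcube.analysis import outflow_case_correlation

cfg = synth.SynthConfig(seed=42)                 # 60 walkers, 30 days, 12x12 grid
geo = synth.make_geography(cfg)
events, _ = synth.simulate_events(cfg, geo)
flows = extract_entity_flows(events, geo, "county",
                             SourceRules(deny=frozenset(cfg.bot_sources)))
cube = build_cube(flows, "county", source="synthetic")
print(cube)
print(rollup_spatial(cube, "state", geo))
```

```
ODTCube(level='county', source='synthetic', cells=742, total=1764)
ODTCube(level='state', source='synthetic', cells=214, total=1764)
```

1764 entity-movements fill 742 sparse county-level cells; rolling up
to states merges cells (742 → 214) but conserves the total mass.

```python
s = place_series(cube, "10004", "in_and_out", geography=geo)
rr = reduction_rate({"first-half": s.iloc[:15].sum(),
                     "second-half": s.iloc[15:].sum()}, "first-half")
print({k: round(v, 3) for k, v in rr.rates.items()})
```

```
{'first-half': 0.0, 'second-half': -0.634}
```

County 10004's combined in-and-out traffic dropped 63.4% between the
two halves of the month (0 by definition for the baseline period).

```python
d0, _ = cube.day_range
window = (d0, d0 + timedelta(days=1))
cases = synth.simulate_cases(cube, "10004", window, a=0.5, noise_sd=1.0, seed=42)
print(outflow_case_correlation(cube, "10004", window, cases).table.tail(3).to_string(index=False))
```

```
       day        r  n
2020-03-10 0.689768 15
2020-03-11 0.775508 15
2020-03-12 0.763541 15
```

Daily Pearson correlations between the two-day outflow vector from
county 10004 and each day's cumulative cases across the other 15
counties: with a planted linear dependence plus noise, *r* is high and
fluctuates with the noise realisation.

The same pipeline is scriptable from a shell:

```sh
odtcube simulate --seed 42 --out fixture/
odtcube extract-twitter --events fixture/events.csv --geo fixture/ \
    --level county --deny TweetMyJOBS --deny AutoWeatherBot --out flows.csv
odtcube build-cube --flows flows.csv --level county --out cube.csv
odtcube export --cube cube.csv --level county --mode aggregated --out od.csv
```

## Layout

- `odtcube.geography` — multi-level geographies, point-in-polygon
  assignment, hierarchy roll-up, haversine distance, mean centers
- `odtcube.events` — event-stream (single-day / cross-day) extraction
- `odtcube.sdm` — home-based record parsing and weighted flows
- `odtcube.cube` — the sparse ODT cube and its slice/dice/roll-up algebra
- `odtcube.analysis` — reduction rates, outflow–case correlation,
  scenario tables
- `odtcube.synth` — synthetic world + independent ground truth
- `odtcube.flowio` / `odtcube.cli` — CSV flow dialect, query specs, CLI

See `docs/methods.md` for modelling conventions, parameter meanings
and known limitations.
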