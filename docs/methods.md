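# Methods

This note records the modelling conventions, parameter choices and
numerical decisions behind `odtcube`, and what the synthetic test bed
does and does not establish about real movement data.

## The cube model

The core object is a sparse aggregate over entity-level movements: a
cell (origin place, destination place, day) holds the summed entity
weights of movements between those places on that day, plus the
weight-weighted mean center of the contributing flow origins and of
the flow destinations.  Cells with zero count are never stored; at
continental scale such cubes are billions of cells sparse, and the
desk-scale implementation keeps the same sparse long-format contract
(a pandas table keyed by cell) rather than dense arrays.

Two aggregation semantics coexist deliberately:

- **Presence flows (event streams).**  A person either moved between
  two places on a day or did not; within one extraction level an
  entity contributes at most 1 to any cell.  Consequence: spatially
  rolling up a *cube* of presence flows over-counts distinct movers
  relative to re-extracting at the coarser level (an entity with two
  distinct fine-level flows that merge at the coarser level counts
  twice in the rolled-up cube, once on re-extraction).  Re-extraction
  is therefore the honest way to change level for presence data, and
  the extraction layer is tested for exactly that consistency
  (fine-level flows re-keyed through the hierarchy and re-deduplicated
  equal direct coarse-level extraction).
- **Weighted flows (home-based device records).**  Weights are device
  counts and always sum; cube roll-up and flow-level roll-up commute
  exactly on counts, and the coarser totals intentionally over-count
  distinct visitors, matching the provenance of such data products.

Endpoint mean centers are path-dependent by construction: event-derived
cells carry means of actual event coordinates, record-derived cells
carry place-centroid means, and a spatial roll-up re-averages whatever
the finer cube stored.  Only counts are invariant across aggregation
paths; tests assert count equality, never coordinate equality, across
paths.

### Query conventions

- All time ranges are **closed** calendar-date intervals.
- `inflow`/`outflow` exclude the diagonal cell; `intraflow` is the
  diagonal (within-place movement with positive distance); `in_and_out`
  = inflow + outflow and **excludes** intraflow, which is its own
  direction.
- The minimum-count display filter is **strict** (`cnt > threshold`).
- Drill-down is recomputation from finer data; a stored cube cannot be
  refined below its own level (information loss is explicit).  The
  classical "pivot" cube operation is not implemented: for a 3D cube
  whose natural consumers are the OD/OT/DT slices it adds nothing
  beyond axis re-labelling.
- Temporal roll-up bins are ISO weeks (labelled by their Monday),
  calendar months (labelled by their first day), or explicit closed
  custom ranges; days covered by no custom range are dropped, and an
  empty intersection is an empty result, not an error.

## Extraction rules

**Event streams.**  Calendar days are UTC dates of the event
timestamps (a fixed UTC offset is configurable; real deployments would
want local time zones, which is out of scope).  An entity-day with ≥ 2
events yields a single-day movement: origin = the day's first event,
destination = the event at maximum great-circle distance from that
initial location (ties broken toward the earliest event).  This is the
only reading of "daily maximum travel distance relative to the initial
location" that fixes both endpoints.  Consecutive active days yield a
cross-day movement between daily mean centers, dated here to the
**earlier** day (configurable; the convention is arbitrary but must be
stated).  Movements of zero distance are not movements; endpoints
falling outside the geography are dropped and tallied in the log.  A
single-day and a cross-day flow landing in the same (entity, o, d,
day) cell collapse to one row — the cell is presence-based — with the
single-day row kept, since its endpoints are observed points rather
than derived means.

**Home-based records.**  Only three fields are consumed (home block
group, destination map, period start date); the period start is
truncated to a date, one record is treated as one day.  Self-loops
(home cbg among its own destinations) are kept and become intra-place
weight after roll-up.  Destination block groups sharing a coarser
parent merge by summing device counts.

**Source filtering.**  Bot removal is an allow-list XOR deny-list
match on the posting-client string — by design no content analysis, so
it can only catch automation that identifies itself in the source
field.

## Analyses

- **Reduction rate** `R_i = (M_i − M_base) / M_base` over period flow
  masses; defined only for a positive baseline mass, exactly 0 at the
  baseline, invariant under uniform rescaling of all masses.
- **Outflow–case correlation.**  Pearson by default (the case study
  framing is linear); Spearman is available.  Case counts are
  **cumulative** per evaluation day — the design correlates one fixed
  pre-lockdown flow vector against evolving totals.  Places present in
  the case table but absent from the sparse flow vector are imputed
  zero flow (absence of a cell means no observed movement).  Days with
  fewer than 3 paired places or a constant vector on either side give
  a missing value with a log warning, never an exception.

## Synthetic world

Defaults (`SynthConfig`): 60 walkers on a 12×12 fine grid (0.1° cells
anchored at 38°N, 98°W) nested into 4×4 mid and 2×2 coarse cells with
FIPS-like codes whose prefixes encode the hierarchy; 30 days from
2020-03-01; Poisson(3) events per entity-day; stay probability 0.6
with jumps of up to 2 cells per axis; 10% automated accounts posting
from recognisable bot sources; 20 home-based records per day with
1 + Poisson(2) destinations of 1 + Poisson(1) devices; case tables
generated as daily new cases `max(0, a·outflow + N(0, σ))`
accumulated so cumulative counts are non-decreasing (`a = 0.5`,
`σ = 0` by default, so the planted dependence is exact).  These sizes
keep every oracle comparison exhaustive while the full suite runs in
well under a minute per module.

Ground truth is produced by a deliberately duplicated straight-line
implementation of the movement rules over the raw walker itineraries:
arithmetic cell indexing instead of polygon search, an inline
haversine, plain loops.  The duplication is the point — the oracle
shares no code with the modules it checks.

What the generator does **not** emulate, and hence what passing tests
do not show: realistic gravity/radiation-style trip-length
distributions, demographic or platform sampling bias, local-time day
boundaries, GPS error structure, multi-polygon or disputed
territories, boundary-straddling jitter (events are kept off cell
boundaries so arithmetic and geometric assignment agree exactly), and
real epidemic dynamics (cases are a planted linear signal, not a
transmission model).  Correctness here means faithful implementation
of the stated rules, not predictive validity on real corpora.

## Numerical choices

- Great-circle distance: haversine on a sphere of radius 6371 km;
  cross-checked against the spherical law of cosines to < 1 m.
- Mean centers are arithmetic in lon/lat degrees.  Adequate for
  small-extent mid-latitude geographies; meaningless across the
  antimeridian (a mean of longitudes ±179.9 is ~0).  Synthetic
  geographies stay far from ±180° and the poles; real-world use near
  the antimeridian would need a projected or vector mean.
- Point-in-polygon counts the boundary as inside; a point claimed by
  several polygons goes to the smallest place id — reproducibility
  over geometric fastidiousness.  The spatial index (an STRtree) is an
  internal optimisation; the contract, and the test, is equality with
  an exhaustive polygon scan.
- Place centroids use the polygon centroid, falling back to a
  representative interior point when the centroid falls outside (none
  of the synthetic shapes need the fallback, concave real-world shapes
  would).
- The CSV dialect writes coordinates with fixed 6-decimal formatting
  (≈ 0.1 m) so that write → read → write is byte-stable; counts are
  validated as positive integers on export.
- Aggregated-mode exports carry no date columns; the aggregation range
  is recorded in a leading `#` metadata line.
- All simulation randomness flows through one seeded NumPy generator
  per sub-stream (events, records, cases), so equal seeds give
  byte-identical outputs across runs and platforms; nothing depends on
  wall-clock time.

## Known limitations

- No local-time day boundaries beyond a fixed UTC offset.
- Source-string rules are the only bot defence.
- Presence-flow cubes cannot be spatially rolled up without
  over-counting (see above); the API allows it because weighted cubes
  need it, and the caveat lives here and in the extraction docstrings.
- The in-memory cube targets desk-scale data (≲ 10⁶ cells); the
  distributed storage and SQL engines a production deployment would
  use are out of scope, as are web/API front-ends and map rendering.
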