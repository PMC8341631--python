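"""Synthetic movement data with known ground truth.

Everything the pipeline consumes can be generated here with a fixed
seed: a three-level nested grid geography with FIPS-like codes (block
group -> county -> state), geotagged event streams from seeded random
walkers (with a bot sub-population posting from automated clients),
home-based device-count records, and case-count tables with a planted
linear dependence on inflows.

The ground-truth flow tables are computed by a deliberately separate
straight-line re-implementation of the movement rules over the raw
walker itineraries — arithmetic cell lookup instead of polygon search,
an inline haversine, plain loops — so they can serve as an independent
oracle for the extraction modules rather than echoing their code.

The grid lives in mid-latitude coordinates far from the poles and the
antimeridian, with event jitter kept off cell boundaries, so arithmetic
cell indexing and polygon containment agree exactly and great-circle
distance is monotone in grid distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import ConfigurationError
from .events import FLOW_COLUMNS
from .geography import Geography

LEVELS = ("cbg", "county", "state")

#: FIPS-like prefix lengths per level
_PREFIX = {"cbg": 12, "county": 5, "state": 2}

HUMAN_SOURCES = ("Twitter for iPhone", "Twitter for Android", "Twitter Web App")
BOT_SOURCES = ("TweetMyJOBS", "AutoWeatherBot")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic world.

    The defaults describe the standing test scenario: 60 walkers on a
    12x12 block-group grid nested 3-into-1 twice (4x4 counties, 2x2
    states) observed for 30 days, posting on average 3 geotagged events
    per active day, staying put 60% of day-steps, with 10% automated
    accounts; 20 home-based records per day with on average 3
    destination block groups of a few devices each.
    """

    seed: int = 0
    # nested grid: cells per side, finest to coarsest; each must divide the next finer
    fine_side: int = 12
    mid_side: int = 4
    coarse_side: int = 2
    lat0: float = 38.0  # grid south-west corner (degrees)
    lon0: float = -98.0
    cell_deg: float = 0.1  # fine-cell edge length (degrees)
    # walkers
    n_entities: int = 60
    days: int = 30
    start_date: date = date(2020, 3, 1)
    events_per_day: float = 3.0  # Poisson mean per entity-day
    stay_prob: float = 0.6
    step_max: int = 2  # max per-axis cell displacement of one day-step
    bot_fraction: float = 0.1
    bot_sources: tuple[str, ...] = BOT_SOURCES
    # home-based records
    sdm_records_per_day: int = 20
    sdm_dest_mean: float = 3.0  # 1 + Poisson mean destinations per record
    sdm_count_mean: float = 2.0  # 1 + Poisson mean devices per destination
    # planted epidemic dependence
    epi_coeff: float = 0.5  # new cases per unit windowed inflow per day
    epi_noise_sd: float = 0.0

    def __post_init__(self):
        if self.fine_side <= 0 or self.mid_side <= 0 or self.coarse_side <= 0:
            raise ConfigurationError("grid sides must be positive")
        if self.fine_side % self.mid_side or self.mid_side % self.coarse_side:
            raise ConfigurationError(
                f"grid sides must nest: {self.coarse_side} | {self.mid_side} | {self.fine_side}"
            )


# ---------------------------------------------------------------------------
# geography


def _codes_for_fine_cell(cfg: SynthConfig, ix: int, iy: int) -> tuple[str, str, str]:
    """(cbg, county, state) FIPS-like codes of fine cell (col ix, row iy)."""
    f2m = cfg.fine_side // cfg.mid_side
    m2c = cfg.mid_side // cfg.coarse_side
    mx, my = ix // f2m, iy // f2m
    cx, cy = mx // m2c, my // m2c
    state = f"{10 + cy * cfg.coarse_side + cx:02d}"
    county = state + f"{(my % m2c) * m2c + (mx % m2c) + 1:03d}"
    cbg = county + f"{(iy % f2m) * f2m + (ix % f2m) + 1:07d}"
    return cbg, county, state


def make_geography(cfg: SynthConfig) -> Geography:
    """Three nested square-grid levels with FIPS-like nested codes.

    Code-prefix truncation (12 -> 5 -> 2 digits) agrees with the
    geometric nesting by construction.
    """
    sides = {"cbg": cfg.fine_side, "county": cfg.mid_side, "state": cfg.coarse_side}
    polygons: dict[str, dict] = {lv: {} for lv in LEVELS}
    parents: dict[str, dict] = {lv: {} for lv in LEVELS}
    names: dict[str, dict] = {lv: {} for lv in LEVELS}
    extent = cfg.fine_side * cfg.cell_deg
    for lv in LEVELS:
        side = sides[lv]
        edge = extent / side
        scale = cfg.fine_side // side
        for iy in range(side):
            for ix in range(side):
                cbg, county, state = _codes_for_fine_cell(cfg, ix * scale, iy * scale)
                pid = {"cbg": cbg, "county": county, "state": state}[lv]
                lon_w = cfg.lon0 + ix * edge
                lat_s = cfg.lat0 + iy * edge
                polygons[lv][pid] = box(lon_w, lat_s, lon_w + edge, lat_s + edge)
                names[lv][pid] = f"{lv}-{pid}"
                if lv == "cbg":
                    parents[lv][pid] = county
                elif lv == "county":
                    parents[lv][pid] = state
    return Geography(LEVELS, polygons, parents, names)


def _cell_of_point(cfg: SynthConfig, lat: float, lon: float) -> tuple[int, int]:
    # arithmetic cell lookup -- independent of the polygon search path
    ix = int(math.floor((lon - cfg.lon0) / cfg.cell_deg))
    iy = int(math.floor((lat - cfg.lat0) / cfg.cell_deg))
    return ix, iy


def _truth_place(cfg: SynthConfig, lat: float, lon: float, level: str) -> str:
    ix, iy = _cell_of_point(cfg, lat, lon)
    cbg, county, state = _codes_for_fine_cell(cfg, ix, iy)
    return {"cbg": cbg, "county": county, "state": state}[level]


def _truth_haversine(lat1, lon1, lat2, lon2) -> float:
    # inline spherical distance for the oracle path (km, R = 6371)
    p1, p2 = math.radians(lat1), math.radians(lat2)
    a = (
        math.sin((p2 - p1) / 2) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin(math.radians(lon2 - lon1) / 2) ** 2
    )
    return 2 * 6371.0 * math.asin(math.sqrt(a))


# ---------------------------------------------------------------------------
# event streams


@dataclass
class GroundTruth:
    """Expected outputs recorded alongside a generated dataset."""

    itineraries: dict = field(default_factory=dict)  # entity -> [(day, ts, lat, lon)]
    flow_tables: dict = field(default_factory=dict)  # level -> expected flow DataFrame
    cube_cells: dict = field(default_factory=dict)  # level -> {(o, d, day): weight}
    total_weight: float = 0.0


def simulate_events(cfg: SynthConfig, geography: Geography | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Seeded random walkers emitting geotagged events, plus ground truth.

    Each entity starts in a random fine cell; each day it is active
    with the walk kernel (stay with probability ``stay_prob``, else
    jump up to ``step_max`` cells per axis) and posts Poisson-many
    events jittered inside its current cell.  ``bot_fraction`` of
    entities post from automated-client sources.  Timestamps are ISO
    strings, as an ingested CSV would carry.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    rows = []
    itineraries: dict[str, list] = {}
    n_bots = int(round(cfg.bot_fraction * cfg.n_entities))
    for e in range(cfg.n_entities):
        ent = f"u{e:04d}"
        is_bot = e < n_bots
        src_pool = cfg.bot_sources if is_bot else HUMAN_SOURCES
        ix = int(rng.integers(cfg.fine_side))
        iy = int(rng.integers(cfg.fine_side))
        pts: list[tuple[date, str, float, float]] = []
        for dday in range(cfg.days):
            day = cfg.start_date + timedelta(days=dday)
            if rng.random() >= cfg.stay_prob:
                ix = int(np.clip(ix + rng.integers(-cfg.step_max, cfg.step_max + 1), 0, cfg.fine_side - 1))
                iy = int(np.clip(iy + rng.integers(-cfg.step_max, cfg.step_max + 1), 0, cfg.fine_side - 1))
            n_ev = int(rng.poisson(cfg.events_per_day))
            if n_ev == 0:
                continue
            secs = np.sort(rng.integers(0, 86400, size=n_ev))
            for s in secs:
                # jitter within the central 90% of the cell: never on a boundary
                jx = 0.05 + 0.9 * rng.random()
                jy = 0.05 + 0.9 * rng.random()
                lon = cfg.lon0 + (ix + jx) * cfg.cell_deg
                lat = cfg.lat0 + (iy + jy) * cfg.cell_deg
                ts = f"{day.isoformat()}T{int(s) // 3600:02d}:{int(s) % 3600 // 60:02d}:{int(s) % 60:02d}Z"
                src = src_pool[int(rng.integers(len(src_pool)))]
                rows.append(
                    {"entity_id": ent, "lat": lat, "lon": lon, "timestamp": ts, "source": src}
                )
                if not is_bot:
                    pts.append((day, ts, lat, lon))
        if pts:
            itineraries[ent] = pts
    events = pd.DataFrame(rows, columns=["entity_id", "lat", "lon", "timestamp", "source"])
    truth = GroundTruth(itineraries=itineraries)
    for level in LEVELS:
        tbl = _truth_event_flows(cfg, itineraries, level)
        truth.flow_tables[level] = tbl
        truth.cube_cells[level] = _truth_cube_cells(tbl)
    return events, truth


def _truth_event_flows(cfg: SynthConfig, itineraries: dict, level: str) -> pd.DataFrame:
    """Straight-line application of the movement rules to itineraries.

    Independent oracle: plain loops over (day, timestamp, lat, lon)
    points, arithmetic place lookup, inline haversine.  Mirrors the
    documented conventions: single-day origin = first event,
    destination = farthest-from-origin event (earliest among ties);
    cross-day = mean-center shift dated to the earlier day; zero
    distance yields nothing; one row per (entity, o, d, day) with the
    single-day row preferred.
    """
    out_rows: list[dict] = []
    for ent in sorted(itineraries):
        by_day: dict[date, list] = {}
        for day, ts, lat, lon in itineraries[ent]:
            by_day.setdefault(day, []).append((ts, lat, lon))
        chosen: dict[tuple, dict] = {}
        for day in sorted(by_day):
            pts = sorted(by_day[day])
            if len(pts) >= 2:
                _, o_lat, o_lon = pts[0]
                best_d, best = -1.0, None
                for ts, lat, lon in pts:
                    dist = _truth_haversine(o_lat, o_lon, lat, lon)
                    if dist > best_d:  # first strict maximum, as in the extractor
                        best_d, best = dist, (lat, lon)
                if best_d > 0:
                    o_pl = _truth_place(cfg, o_lat, o_lon, level)
                    d_pl = _truth_place(cfg, best[0], best[1], level)
                    chosen[(ent, o_pl, d_pl, day)] = {
                        "entity_id": ent, "o_place": o_pl, "d_place": d_pl, "day": day,
                        "o_lat": o_lat, "o_lon": o_lon, "d_lat": best[0], "d_lon": best[1],
                        "kind": "single_day", "weight": 1.0,
                    }
        for day in sorted(by_day):
            nxt = day + timedelta(days=1)
            if nxt not in by_day:
                continue
            lats1 = [p[1] for p in by_day[day]]
            lons1 = [p[2] for p in by_day[day]]
            lats2 = [p[1] for p in by_day[nxt]]
            lons2 = [p[2] for p in by_day[nxt]]
            o_lat, o_lon = sum(lats1) / len(lats1), sum(lons1) / len(lons1)
            d_lat, d_lon = sum(lats2) / len(lats2), sum(lons2) / len(lons2)
            if _truth_haversine(o_lat, o_lon, d_lat, d_lon) <= 0:
                continue
            o_pl = _truth_place(cfg, o_lat, o_lon, level)
            d_pl = _truth_place(cfg, d_lat, d_lon, level)
            key = (ent, o_pl, d_pl, day)
            if key not in chosen:  # single-day row wins the shared cell
                chosen[key] = {
                    "entity_id": ent, "o_place": o_pl, "d_place": d_pl, "day": day,
                    "o_lat": o_lat, "o_lon": o_lon, "d_lat": d_lat, "d_lon": d_lon,
                    "kind": "cross_day", "weight": 1.0,
                }
        out_rows.extend(chosen[k] for k in sorted(chosen, key=lambda k: (k[0], k[3], k[1], k[2])))
    if not out_rows:
        return pd.DataFrame(columns=FLOW_COLUMNS)
    return pd.DataFrame(out_rows, columns=FLOW_COLUMNS)


def _truth_cube_cells(flow_table: pd.DataFrame) -> dict:
    cells: dict[tuple, float] = {}
    for row in flow_table.itertuples(index=False):
        key = (row.o_place, row.d_place, row.day)
        cells[key] = cells.get(key, 0.0) + float(row.weight)
    return cells


# ---------------------------------------------------------------------------
# home-based records


def simulate_sdm(cfg: SynthConfig, geography: Geography | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Home-based origin records with device-count destination maps.

    Each day, ``sdm_records_per_day`` home block groups are sampled
    (without replacement within a day); each record gets
    1 + Poisson(sdm_dest_mean - 1) destination block groups with
    1 + Poisson(sdm_count_mean - 1) devices each.  The home cbg itself
    may be sampled as a destination (a self-loop).  Ground truth is a
    direct tally of the raw maps under code-prefix truncation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    all_cbgs = sorted(
        _codes_for_fine_cell(cfg, ix, iy)[0]
        for ix in range(cfg.fine_side)
        for iy in range(cfg.fine_side)
    )
    n_cbgs = len(all_cbgs)
    rows = []
    truth = GroundTruth()
    cells: dict[str, dict] = {lv: {} for lv in LEVELS}
    for dday in range(cfg.days):
        day = cfg.start_date + timedelta(days=dday)
        homes = rng.choice(n_cbgs, size=min(cfg.sdm_records_per_day, n_cbgs), replace=False)
        for hi in np.sort(homes):
            home = all_cbgs[int(hi)]
            n_dest = 1 + int(rng.poisson(max(cfg.sdm_dest_mean - 1.0, 0.0)))
            dest_idx = rng.choice(n_cbgs, size=min(n_dest, n_cbgs), replace=False)
            dest_map = {}
            for di in np.sort(dest_idx):
                dest = all_cbgs[int(di)]
                cnt = 1 + int(rng.poisson(max(cfg.sdm_count_mean - 1.0, 0.0)))
                dest_map[dest] = cnt
                truth.total_weight += cnt
                for lv in LEVELS:
                    n = _PREFIX[lv]
                    key = (home[:n], dest[:n], day)
                    cells[lv][key] = cells[lv].get(key, 0.0) + float(cnt)
            rows.append(
                {
                    "origin_census_block_group": home,
                    "destination_cbgs": json.dumps(dest_map, sort_keys=True),
                    "date_range_start": f"{day.isoformat()}T00:00:00-05:00",
                }
            )
    records = pd.DataFrame(
        rows, columns=["origin_census_block_group", "destination_cbgs", "date_range_start"]
    )
    truth.cube_cells = cells
    return records, truth


# ---------------------------------------------------------------------------
# planted epidemic dependence


def simulate_cases(
    cube,
    focal_place: str,
    flow_window: tuple[date, date],
    a: float | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    n_days: int = 10,
) -> pd.DataFrame:
    """Cumulative case counts with a planted linear link to outflows.

    For every place j (other than the focal place) appearing in the
    cube, the windowed outflow v[j] from the focal place is tallied by
    a direct scan of the cells; daily new cases are
    ``max(0, a * v[j] + Gaussian(0, noise_sd))``, accumulated over
    ``n_days`` starting the day after the window, so cumulative counts
    are non-decreasing.  With ``noise_sd = 0`` the cumulative count is
    exactly proportional to v[j] on every day.
    """
    a = 0.5 if a is None else a
    noise_sd = 0.0 if noise_sd is None else noise_sd
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    start, end = flow_window
    v: dict[str, float] = {}
    for row in cube.cells.itertuples(index=False):
        if row.o_place == focal_place and row.d_place != focal_place and start <= row.day <= end:
            v[row.d_place] = v.get(row.d_place, 0.0) + float(row.cnt)
    places = sorted(p for p in cube.places if p != focal_place)
    rows = []
    first_day = end + timedelta(days=1)
    cum = {j: 0.0 for j in places}
    for t in range(n_days):
        day = first_day + timedelta(days=t)
        for j in places:
            new = a * v.get(j, 0.0) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            cum[j] += max(0.0, new)
            rows.append({"place_id": j, "date": day, "cumulative_cases": cum[j]})
    return pd.DataFrame(rows, columns=["place_id", "date", "cumulative_cases"])


# ---------------------------------------------------------------------------
# fixture directory


def write_fixture_dir(cfg: SynthConfig, outdir) -> dict:
    """Write every pipeline input into a directory; returns the paths.

    Produces events.csv, sdm.csv, one GeoJSON per geography level, a
    child->parent hierarchy CSV per non-coarsest level, cases.csv (from
    the county-level event cube) and the ground-truth flow tables.
    Regeneration with the same config is byte-identical.
    """
    import os

    from .cube import build_cube

    os.makedirs(outdir, exist_ok=True)
    geo = make_geography(cfg)
    paths: dict[str, str] = {}
    for lv in LEVELS:
        p = os.path.join(outdir, f"geography_{lv}.geojson")
        geo.write_geojson(lv, p)
        paths[f"geography_{lv}"] = p
    for lv in ("cbg", "county"):
        p = os.path.join(outdir, f"hierarchy_{lv}.csv")
        with open(p, "w", newline="\n") as fh:
            for child in geo.places(lv):
                fh.write(f"{child},{geo.parent_of(child, lv)}\n")
        paths[f"hierarchy_{lv}"] = p
    events, ev_truth = simulate_events(cfg, geo)
    p = os.path.join(outdir, "events.csv")
    events.to_csv(p, index=False, lineterminator="\n")
    paths["events"] = p
    records, _ = simulate_sdm(cfg, geo)
    p = os.path.join(outdir, "sdm.csv")
    records.to_csv(p, index=False, lineterminator="\n")
    paths["sdm"] = p
    for lv in LEVELS:
        p = os.path.join(outdir, f"truth_flows_{lv}.csv")
        ev_truth.flow_tables[lv].to_csv(p, index=False, lineterminator="\n")
        paths[f"truth_flows_{lv}"] = p
    cube = build_cube(ev_truth.flow_tables["county"], "county", source="synthetic")
    if len(cube):
        d0, d1 = cube.day_range
        focal = sorted(cube.places)[0]
        window = (d0, min(d1, d0 + timedelta(days=1)))
        cases = simulate_cases(
            cube, focal, window, a=cfg.epi_coeff, noise_sd=cfg.epi_noise_sd, seed=cfg.seed
        )
        p = os.path.join(outdir, "cases.csv")
        cases.to_csv(p, index=False, lineterminator="\n")
        paths["cases"] = p
    return paths
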