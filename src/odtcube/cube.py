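"""The sparse origin-destination-time (ODT) cube and its query algebra.

An ODT cube aggregates entity-level flows at one geographic level into
sparse cells (origin place, destination place, day) -> count, where the
count sums entity weights (1 per entity for event-derived flows, device
counts for home-based records).  Each stored cell also carries the
weight-weighted mean center of the contributing flow origins and of the
flow destinations, which is what the export dialect ships for mapping.

The OLAP-style operations:

* roll-up (drill up): :func:`rollup_spatial` re-keys cells through the
  geography's parent links; :func:`rollup_temporal` re-bins days into
  ISO weeks, calendar months, or custom ranges.  Drill-down is
  recomputation from finer data — a cube cannot be refined below its
  own level.
* dice: :func:`dice` restricts to a subcube by origin/destination place
  sets and a closed date interval.
* slice: :func:`slice_od` (flows between places over a period),
  :func:`slice_ot` (outflows per origin-day), :func:`slice_dt` (inflows
  per destination-day).  The OD diagonal holds intra-place movements
  (origin = destination with positive movement distance).

Flow-direction conventions for a focal place: *inflow* sums cells into
the place from elsewhere, *outflow* sums cells out of it, *intraflow*
is the diagonal cell, and *in&out* = inflow + outflow (the diagonal is
excluded — intraflow is its own direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import LevelError, PlaceError
from .geography import Geography, rollup_series

CUBE_COLUMNS = ["o_place", "d_place", "day", "cnt", "o_lat", "o_lon", "d_lat", "d_lon"]

DIRECTIONS = ("inflow", "outflow", "intraflow", "in_and_out")


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "o_place": pd.Series(dtype=str),
            "d_place": pd.Series(dtype=str),
            "day": pd.Series(dtype=object),
            "cnt": pd.Series(dtype=float),
            "o_lat": pd.Series(dtype=float),
            "o_lon": pd.Series(dtype=float),
            "d_lat": pd.Series(dtype=float),
            "d_lon": pd.Series(dtype=float),
        }
    )


class ODTCube:
    """Sparse (origin, destination, day) count cube at one level.

    ``cells`` is a long-format table with one row per non-empty cell;
    stored counts are strictly positive and endpoint coordinates finite.
    Rows are kept in canonical (day, o_place, d_place) order so that
    equal cubes compare equal row-wise.
    """

    def __init__(self, cells: pd.DataFrame, level: str, source: str = "synthetic"):
        if len(cells) == 0:
            cells = _empty_cells()
        missing = [c for c in CUBE_COLUMNS if c not in cells.columns]
        if missing:
            raise ValueError(f"cube cells missing columns: {missing}")
        cells = cells[CUBE_COLUMNS].copy()
        if len(cells):
            if (cells["cnt"] <= 0).any():
                raise ValueError("stored cube cells must have positive counts")
            coords = cells[["o_lat", "o_lon", "d_lat", "d_lon"]].to_numpy(dtype=float)
            if not np.isfinite(coords).all():
                raise ValueError("cube endpoint coordinates must be finite")
        self.cells = cells.sort_values(
            ["day", "o_place", "d_place"], kind="mergesort"
        ).reset_index(drop=True)
        self.level = level
        self.source = source

    def __len__(self) -> int:
        return len(self.cells)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ODTCube):
            return NotImplemented
        return (
            self.level == other.level
            and self.source == other.source
            and self.cells.equals(other.cells)
        )

    def __repr__(self) -> str:
        return (
            f"ODTCube(level={self.level!r}, source={self.source!r}, "
            f"cells={len(self)}, total={self.total:g})"
        )

    @property
    def total(self) -> float:
        """Total flow mass (sum of all cell counts)."""
        return float(self.cells["cnt"].sum())

    @property
    def day_range(self) -> tuple[date, date] | None:
        """(min, max) day with any stored cell, or None for an empty cube."""
        if len(self.cells) == 0:
            return None
        return (self.cells["day"].min(), self.cells["day"].max())

    @property
    def places(self) -> set[str]:
        """Places appearing as origin or destination of any cell."""
        return set(self.cells["o_place"]) | set(self.cells["d_place"])

    def cell(self, o_place: str, d_place: str, day: date) -> float:
        """Count of one cell; 0 for an unstored (empty) cell."""
        m = (
            (self.cells["o_place"] == o_place)
            & (self.cells["d_place"] == d_place)
            & (self.cells["day"] == day)
        )
        return float(self.cells.loc[m, "cnt"].sum())


def _weighted_endpoint_agg(df: pd.DataFrame, keys: list[str], weight_col: str) -> pd.DataFrame:
    """Group by ``keys`` summing the weight and weight-averaging endpoints."""
    tmp = df.copy()
    w = tmp[weight_col].to_numpy(dtype=float)
    for c in ("o_lat", "o_lon", "d_lat", "d_lon"):
        tmp[f"_w{c}"] = tmp[c].to_numpy(dtype=float) * w
    g = tmp.groupby(keys, as_index=False, sort=True).agg(
        cnt=(weight_col, "sum"),
        _wo_lat=("_wo_lat", "sum"),
        _wo_lon=("_wo_lon", "sum"),
        _wd_lat=("_wd_lat", "sum"),
        _wd_lon=("_wd_lon", "sum"),
    )
    for c in ("o_lat", "o_lon", "d_lat", "d_lon"):
        g[c] = g[f"_w{c}"] / g["cnt"]
    return g[keys + ["cnt", "o_lat", "o_lon", "d_lat", "d_lon"]]


def build_cube(entity_flows: pd.DataFrame, level: str, source: str = "synthetic") -> ODTCube:
    """Aggregate an entity-flow table into the ODT cube.

    Cell count = sum of entity weights for that (origin, destination,
    day); cell endpoint coordinates = weight-weighted mean centers of
    the contributing flows' endpoint points.  All flows must already be
    keyed at ``level`` (mixed-level tables are a caller bug the cube
    cannot detect; see :func:`rollup_spatial` for level changes).
    """
    if len(entity_flows) == 0:
        return ODTCube(_empty_cells(), level, source)
    g = _weighted_endpoint_agg(entity_flows, ["o_place", "d_place", "day"], "weight")
    return ODTCube(g, level, source)


def rollup_spatial(cube: ODTCube, to_level: str, geography: Geography) -> ODTCube:
    """Re-key cells through parent links to a coarser level and sum.

    Identity when ``to_level`` equals the cube's level.  Total count is
    conserved; endpoint mean centers are re-averaged by count weight.
    """
    if to_level == cube.level:
        return ODTCube(cube.cells, cube.level, cube.source)
    if not geography.is_coarser(to_level, cube.level):
        raise LevelError(f"cannot roll a {cube.level!r} cube up to finer level {to_level!r}")
    if len(cube) == 0:
        return ODTCube(_empty_cells(), to_level, cube.source)
    df = cube.cells.copy()
    df["o_place"] = rollup_series(df["o_place"], cube.level, to_level, geography)
    df["d_place"] = rollup_series(df["d_place"], cube.level, to_level, geography)
    g = _weighted_endpoint_agg(df, ["o_place", "d_place", "day"], "cnt")
    return ODTCube(g, to_level, cube.source)


def _period_start(d: date, granularity: str) -> date:
    if granularity == "day":
        return d
    if granularity == "week":  # ISO week, labelled by its Monday
        return d - timedelta(days=d.isoweekday() - 1)
    if granularity == "month":
        return d.replace(day=1)
    raise ValueError(f"unknown granularity {granularity!r}")


def rollup_temporal(
    obj: "ODTCube | pd.DataFrame",
    granularity: str = "day",
    custom_ranges: list[tuple[date, date]] | None = None,
) -> pd.DataFrame:
    """Temporal aggregation of a cube (or any day-keyed count table).

    ``granularity`` is ``day`` (identity bins), ``week`` (ISO weeks
    labelled by their Monday), ``month`` (calendar months labelled by
    their first day) or ``custom`` with closed ``custom_ranges``
    labelled by each range's start; days covered by no custom range are
    dropped.  Returns a long table keyed by ``period`` with counts
    summed within each bin (endpoint coordinates, when present, are
    re-averaged by count weight).  An empty intersection with the data
    yields an empty table, not an error.
    """
    df = obj.cells if isinstance(obj, ODTCube) else obj
    if "day" not in df.columns or "cnt" not in df.columns:
        raise ValueError("temporal roll-up needs 'day' and 'cnt' columns")
    group_cols = [c for c in ("o_place", "d_place") if c in df.columns]
    has_coords = all(c in df.columns for c in ("o_lat", "o_lon", "d_lat", "d_lon"))
    if len(df) == 0:
        cols = group_cols + ["period", "cnt"] + (
            ["o_lat", "o_lon", "d_lat", "d_lon"] if has_coords else []
        )
        return pd.DataFrame({c: pd.Series(dtype=object if c == "period" else float) for c in cols})
    df = df.copy()
    if custom_ranges is not None:
        ranges = sorted(custom_ranges)
        def bin_of(d):
            for start, end in ranges:
                if start <= d <= end:
                    return start
            return None
        df["period"] = [bin_of(d) for d in df["day"]]
        df = df[df["period"].notna()]
    else:
        df["period"] = [_period_start(d, granularity) for d in df["day"]]
    if len(df) == 0:
        return rollup_temporal(df.drop(columns="period"), granularity)
    keys = group_cols + ["period"]
    if has_coords:
        out = _weighted_endpoint_agg(df, keys, "cnt")
    else:
        out = df.groupby(keys, as_index=False, sort=True)["cnt"].sum()
    return out.reset_index(drop=True)


def dice(
    cube: ODTCube,
    o_filter: set[str] | None = None,
    d_filter: set[str] | None = None,
    t_range: tuple[date, date] | None = None,
) -> ODTCube:
    """Subcube restricted by place sets and a closed date interval.

    ``None`` filters mean "all".  Dicing twice with intersected filters
    equals one dice with the intersection.
    """
    df = cube.cells
    mask = pd.Series(True, index=df.index)
    if o_filter is not None:
        mask &= df["o_place"].isin(set(o_filter))
    if d_filter is not None:
        mask &= df["d_place"].isin(set(d_filter))
    if t_range is not None:
        start, end = t_range
        if start > end:
            raise ValueError(f"t_range start {start} after end {end}")
        mask &= df["day"].apply(lambda d: start <= d <= end)
    return ODTCube(df[mask], cube.level, cube.source)


def slice_od(cube: ODTCube, t_range: tuple[date, date] | None = None) -> pd.DataFrame:
    """OD matrix: per-(origin, destination) totals over the date range.

    Long format with endpoint mean centers; the diagonal rows
    (o_place == d_place) are the intra-place movements.
    """
    sub = dice(cube, t_range=t_range) if t_range is not None else cube
    if len(sub) == 0:
        return _empty_cells().drop(columns="day")
    return _weighted_endpoint_agg(sub.cells, ["o_place", "d_place"], "cnt")


def slice_ot(cube: ODTCube) -> pd.DataFrame:
    """OT matrix: outflows per (origin place, day), summed over destinations."""
    if len(cube) == 0:
        return pd.DataFrame({"o_place": pd.Series(dtype=str), "day": pd.Series(dtype=object), "cnt": pd.Series(dtype=float)})
    return cube.cells.groupby(["o_place", "day"], as_index=False, sort=True)["cnt"].sum()


def slice_dt(cube: ODTCube) -> pd.DataFrame:
    """DT matrix: inflows per (destination place, day), summed over origins."""
    if len(cube) == 0:
        return pd.DataFrame({"d_place": pd.Series(dtype=str), "day": pd.Series(dtype=object), "cnt": pd.Series(dtype=float)})
    return cube.cells.groupby(["d_place", "day"], as_index=False, sort=True)["cnt"].sum()


def _check_place(cube: ODTCube, place: str, geography: Geography | None) -> None:
    if geography is not None:
        if place not in geography._polygons.get(cube.level, {}):
            raise PlaceError(f"unknown place {place!r} at level {cube.level!r}")
    elif place not in cube.places:
        raise PlaceError(
            f"place {place!r} has no cells in this {cube.level!r} cube "
            "(pass a geography to query a known-but-quiet place)"
        )


def place_series(
    cube: ODTCube,
    place: str,
    direction: str,
    geography: Geography | None = None,
) -> pd.Series:
    """Daily flow series for one place in one direction.

    inflow(day) sums cells (o, place, day) over o != place; outflow(day)
    sums (place, d, day) over d != place; intraflow(day) is the diagonal
    cell (place, place, day); in_and_out = inflow + outflow.  The index
    covers every day of the cube's day range (zeros filled); an empty
    cube yields an empty series.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    _check_place(cube, place, geography)
    rng = cube.day_range
    if rng is None:
        return pd.Series(dtype=float, name=direction)
    days = [rng[0] + timedelta(days=i) for i in range((rng[1] - rng[0]).days + 1)]
    df = cube.cells
    is_o = df["o_place"] == place
    is_d = df["d_place"] == place
    if direction == "inflow":
        sel = df[is_d & ~is_o]
    elif direction == "outflow":
        sel = df[is_o & ~is_d]
    elif direction == "intraflow":
        sel = df[is_o & is_d]
    else:  # in_and_out: diagonal excluded
        sel = df[is_o ^ is_d]
    s = sel.groupby("day")["cnt"].sum()
    out = pd.Series(0.0, index=pd.Index(days, name="day"), name=direction)
    out.loc[s.index] = s.to_numpy(dtype=float)
    return out


@dataclass
class PlaceFlows:
    """Per-counterpart totals for one focal place plus its intra-place mass."""

    place: str
    direction: str
    counterparts: pd.Series  # counterpart place -> count, diagonal excluded
    intra: float


def place_flows(
    cube: ODTCube,
    place: str,
    t_range: tuple[date, date] | None = None,
    direction: str = "in_and_out",
    geography: Geography | None = None,
) -> PlaceFlows:
    """Totals between a focal place and every other place over a period.

    The choropleth-map query: for each counterpart place, the flow count
    to (inflow), from (outflow) or to-and-from (in_and_out) the focal
    place within the closed date range.  The intra-place (diagonal) cell
    is excluded from counterpart totals and reported separately.
    """
    if direction not in ("inflow", "outflow", "in_and_out"):
        raise ValueError(f"direction must be inflow, outflow or in_and_out, got {direction!r}")
    _check_place(cube, place, geography)
    sub = dice(cube, t_range=t_range) if t_range is not None else cube
    df = sub.cells
    is_o = df["o_place"] == place
    is_d = df["d_place"] == place
    intra = float(df.loc[is_o & is_d, "cnt"].sum())
    parts = []
    if direction in ("inflow", "in_and_out"):
        inf = df[is_d & ~is_o].groupby("o_place")["cnt"].sum()
        inf.index.name = "place"
        parts.append(inf)
    if direction in ("outflow", "in_and_out"):
        outf = df[is_o & ~is_d].groupby("d_place")["cnt"].sum()
        outf.index.name = "place"
        parts.append(outf)
    if parts:
        tot = pd.concat(parts, axis=1).fillna(0.0).sum(axis=1).sort_index()
    else:
        tot = pd.Series(dtype=float)
    tot.name = "cnt"
    tot.index.name = "place"
    return PlaceFlows(place, direction, tot, intra)


def min_count_filter(obj, threshold: float):
    """Keep only entries with count strictly greater than ``threshold``.

    Works on a cube, a long table with a ``cnt`` column, or a series;
    mirrors the display rule used for dense device-derived flows (for
    example, "only flows with more than 20 aggregated devices").
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if isinstance(obj, ODTCube):
        return ODTCube(obj.cells[obj.cells["cnt"] > threshold], obj.level, obj.source)
    if isinstance(obj, pd.DataFrame):
        return obj[obj["cnt"] > threshold].reset_index(drop=True)
    if isinstance(obj, pd.Series):
        return obj[obj > threshold]
    raise TypeError(f"cannot min-count-filter a {type(obj).__name__}")
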