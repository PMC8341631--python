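"""Public file surfaces: the flow CSV dialect and query dispatch.

The flow export dialect is a flat CSV, one row per flow:

* daily mode: ``o_place,d_place,year,month,day,cnt,o_lat,o_lon,d_lat,d_lon``
* aggregated mode: the same without the date columns; the aggregation
  range is recorded in a leading ``#``-prefixed metadata line.

``cnt`` is the positive integer number of users/devices that moved
from origin to destination; the four coordinate columns are the mean
centers of the flow origins and flow destinations, written with fixed
6-decimal formatting so that write -> read -> write is byte-stable.
A cube saves and loads losslessly through the daily dialect.
"""

from __future__ import annotations

import io
import json
from datetime import date
from typing import Literal, Mapping

import pandas as pd
from pydantic import BaseModel, model_validator

from .analysis import SCENARIOS, scenario_tables
from .cube import ODTCube, min_count_filter, slice_od
from .errors import AvailabilityError, ExportError, FormatError
from .events import FLOW_COLUMNS
from .geography import Geography

DAILY_HEADER = ["o_place", "d_place", "year", "month", "day", "cnt", "o_lat", "o_lon", "d_lat", "d_lon"]
AGG_HEADER = ["o_place", "d_place", "cnt", "o_lat", "o_lon", "d_lat", "d_lon"]

_COORD_COLS = ("o_lat", "o_lon", "d_lat", "d_lon")


def _as_int_counts(cnt: pd.Series) -> pd.Series:
    vals = cnt.astype(float)
    rounded = vals.round()
    if ((vals - rounded).abs() > 1e-9).any():
        raise ExportError("cnt column contains non-integer counts")
    if (rounded <= 0).any():
        raise ExportError("cnt column must be strictly positive")
    return rounded.astype(int)


def write_flows(
    table: pd.DataFrame,
    path,
    mode: Literal["daily", "aggregated"],
    t_range: tuple[date, date] | None = None,
) -> None:
    """Write a flow table in the export dialect.

    Daily mode accepts either a ``day`` date column (split into
    year/month/day integers) or the three integer columns directly.
    Aggregated mode takes the OD-matrix shape; ``t_range``, when given,
    goes into the ``#`` metadata line.
    """
    df = table.copy()
    if mode == "daily":
        if "day" in df.columns and "year" not in df.columns:
            days = [d if isinstance(d, date) else pd.Timestamp(d).date() for d in df["day"]]
            df = df.drop(columns="day")
            df["year"] = [d.year for d in days]
            df["month"] = [d.month for d in days]
            df["day"] = [d.day for d in days]
        header = DAILY_HEADER
    elif mode == "aggregated":
        header = AGG_HEADER
    else:
        raise ExportError(f"mode must be 'daily' or 'aggregated', got {mode!r}")
    missing = [c for c in header if c not in df.columns]
    if missing:
        raise ExportError(f"{mode} export missing columns: {missing}")
    df = df[header].copy()
    df["cnt"] = _as_int_counts(df["cnt"])
    for c in _COORD_COLS:
        df[c] = df[c].astype(float).map(lambda v: f"{v:.6f}")
    buf = io.StringIO()
    if mode == "aggregated" and t_range is not None:
        buf.write(f"# t_range={t_range[0].isoformat()}..{t_range[1].isoformat()}\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_flows(path) -> tuple[pd.DataFrame, str]:
    """Read a flow CSV; mode auto-detected from the header.

    Daily files come back in the internal cube-cell shape (a ``day``
    date column); aggregated files in the OD-matrix shape.  The
    aggregation range from the ``#`` metadata line, if present, is in
    ``table.attrs["t_range"]``.
    """
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        meta = None
        if first.startswith("#"):
            meta = first[1:].strip()
            first = fh.readline()
        header = [c.strip() for c in first.rstrip("\n").split(",")]
        if header == DAILY_HEADER:
            mode = "daily"
        elif header == AGG_HEADER:
            mode = "aggregated"
        else:
            expected = set(DAILY_HEADER) | set(AGG_HEADER)
            bad = next((c for c in header if c not in expected), "<missing>")
            raise FormatError(f"unrecognized flow header; first bad column: {bad!r}")
        body = pd.read_csv(
            io.StringIO(first + fh.read()),
            dtype={"o_place": str, "d_place": str},
        )
    if (body["cnt"] <= 0).any():
        raise FormatError("cnt must be strictly positive")
    if mode == "daily":
        body["day"] = [date(y, m, d) for y, m, d in zip(body["year"], body["month"], body["day"])]
        body = body[["o_place", "d_place", "day", "cnt", *list(_COORD_COLS)]]
    else:
        body = body[AGG_HEADER]
        if meta and meta.startswith("t_range="):
            a, b = meta.split("=", 1)[1].split("..")
            body.attrs["t_range"] = (date.fromisoformat(a), date.fromisoformat(b))
    body["cnt"] = body["cnt"].astype(float)
    return body, mode


def save_cube(cube: ODTCube, path) -> None:
    """Persist a cube as a daily-dialect CSV (the public format)."""
    write_flows(cube.cells, path, mode="daily")


def load_cube(path, level: str, source: str = "synthetic") -> ODTCube:
    table, mode = read_flows(path)
    if mode != "daily":
        raise FormatError("a cube round-trips through the daily dialect only")
    return ODTCube(table, level, source)


def write_entity_flows(table: pd.DataFrame, path) -> None:
    """Persist an entity-flow table (internal schema, ISO dates)."""
    df = table[FLOW_COLUMNS].copy()
    df["day"] = [d.isoformat() for d in df["day"]]
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_entity_flows(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"entity_id": str, "o_place": str, "d_place": str})
    df["day"] = [date.fromisoformat(d) for d in df["day"]]
    df["weight"] = df["weight"].astype(float)
    return df[FLOW_COLUMNS]


class QuerySpec(BaseModel):
    """One portal-style query against a stored (source, level) cube.

    Serializable to JSON/YAML; validated for scenario/field consistency
    before any cube work happens.
    """

    source: str = "synthetic"
    level: str
    scenario: Literal["place_flows", "daily_movements", "od_matrix", "extract"]
    direction: Literal["inflow", "outflow", "intraflow", "in_and_out"] | None = None
    place: str | None = None
    bbox: tuple[float, float, float, float] | None = None
    t_range: tuple[date, date] | None = None
    aggregation: Literal["aggregated", "daily"] = "aggregated"
    min_count: float = 0.0

    @model_validator(mode="after")
    def _consistent(self):
        bad = []
        if self.scenario in ("place_flows", "daily_movements"):
            if not self.place:
                bad.append("place (required for this scenario)")
            if not self.direction:
                bad.append("direction (required for this scenario)")
            if self.scenario == "place_flows" and self.direction == "intraflow":
                bad.append("direction (intraflow is not a counterpart direction)")
        if self.place and self.bbox:
            bad.append("place/bbox (mutually exclusive)")
        if self.t_range and self.t_range[0] > self.t_range[1]:
            bad.append("t_range (start after end)")
        if self.min_count < 0:
            bad.append("min_count (must be non-negative)")
        if bad:
            raise ValueError("invalid query fields: " + "; ".join(bad))
        return self

    @classmethod
    def from_file(cls, path) -> "QuerySpec":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        return cls.model_validate(data)


def run_query(
    spec: QuerySpec,
    cube_store: Mapping[tuple[str, str], ODTCube],
    geography: Geography | None = None,
) -> pd.DataFrame:
    """Dispatch a validated query spec against a cube store.

    The store maps (source, level) to a cube.  ``od_matrix`` and
    aggregated ``extract`` queries return the OD-matrix shape ready for
    the aggregated exporter; daily ``extract`` returns cube cells for
    the daily exporter.  ``min_count`` keeps rows with cnt strictly
    above the threshold.
    """
    key = (spec.source, spec.level)
    if key not in cube_store:
        known = sorted(cube_store)
        raise AvailabilityError(f"no cube for (source, level) = {key}; available: {known}")
    cube = cube_store[key]
    if spec.scenario == "extract" and spec.aggregation == "aggregated":
        sub_q = spec.model_dump()
        sub_q["scenario"] = "extract"
        daily = scenario_tables(cube, sub_q, geography=geography)
        table = slice_od(ODTCube(daily, cube.level, cube.source))
    else:
        table = scenario_tables(cube, spec.model_dump(), geography=geography)
    if spec.min_count > 0 and "cnt" in table.columns:
        table = min_count_filter(table, spec.min_count)
    return table
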