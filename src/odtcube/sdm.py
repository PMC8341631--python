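"""Home-based mobility record ingestion.

A home-based record (social-distancing-metrics style) summarises one
census block group (cbg) on one day: the 12-digit FIPS code of the home
block group, a JSON map of destination cbg -> device count, and the
period start date.  The "entity" of the resulting 4D flow table is the
origin block group itself, and flows are weighted by device counts:
when block groups are aggregated to a coarser level (tract, county,
state) the weights sum, so a device visiting several block groups of
one county is counted once per visited block group — coarser-level
totals deliberately over-count distinct visitors, as the underlying
product does.

Flows are home-based: every flow's origin is the record's home cbg.
Self-loops (home cbg among the destination keys) are kept and become
intra-place weight after roll-up.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import date

import pandas as pd

from .errors import RecordError
from .events import FLOW_COLUMNS, empty_flow_table
from .geography import Geography, rollup_series

logger = logging.getLogger(__name__)

SDM_COLUMNS = ["origin_census_block_group", "destination_cbgs", "date_range_start"]


@dataclass(frozen=True)
class SDMRecord:
    """One home-based origin record."""

    origin_census_block_group: str
    destination_cbgs: dict[str, int]
    date_range_start: date


def _parse_date(raw: str) -> date:
    # date_range_start may carry a time / zone suffix; keep the date part
    return date.fromisoformat(str(raw).strip()[:10])


def parse_sdm_record(raw: dict | pd.Series, strict: bool = True) -> SDMRecord:
    """Parse one raw row into a typed record.

    The destination map arrives as a JSON object string.  In strict
    mode any malformed piece (bad FIPS length, non-positive count,
    unparseable map or date) raises :class:`RecordError` with row
    context; lenient mode is handled by :func:`parse_sdm_records`.
    """
    origin = str(raw["origin_census_block_group"]).strip()
    if len(origin) != 12 or not origin.isdigit():
        raise RecordError(f"origin cbg {origin!r} is not a 12-digit FIPS code")
    try:
        day = _parse_date(raw["date_range_start"])
    except ValueError as exc:
        raise RecordError(f"bad date_range_start {raw['date_range_start']!r}: {exc}") from None
    dest_raw = raw["destination_cbgs"]
    if isinstance(dest_raw, str):
        try:
            dest_map = json.loads(dest_raw)
        except json.JSONDecodeError as exc:
            raise RecordError(f"unparseable destination_cbgs for origin {origin}: {exc}") from None
    elif isinstance(dest_raw, dict):
        dest_map = dest_raw
    else:
        raise RecordError(f"destination_cbgs must be a JSON object, got {type(dest_raw).__name__}")
    dests: dict[str, int] = {}
    for k, v in dest_map.items():
        k = str(k)
        if len(k) != 12 or not k.isdigit():
            raise RecordError(f"destination key {k!r} (origin {origin}) is not a 12-digit FIPS code")
        if not float(v) == int(v) or int(v) < 1:
            raise RecordError(f"destination count {v!r} for {k} (origin {origin}) must be a positive integer")
        dests[k] = int(v)
    return SDMRecord(origin, dests, day)


def parse_sdm_records(rows, strict: bool = True) -> list[SDMRecord]:
    """Parse many rows; in lenient mode bad rows are logged and skipped."""
    records = []
    n_skipped = 0
    for i, row in enumerate(rows):
        try:
            records.append(parse_sdm_record(row, strict=strict))
        except RecordError as exc:
            if strict:
                raise RecordError(f"row {i}: {exc}") from None
            n_skipped += 1
            logger.warning("skipping row %d: %s", i, exc)
    if n_skipped:
        logger.info("parse_sdm_records skipped %d malformed rows", n_skipped)
    return records


def read_sdm_csv(path, strict: bool = True) -> list[SDMRecord]:
    """Read a record CSV; extra columns beyond the three used are ignored."""
    df = pd.read_csv(path, dtype={"origin_census_block_group": str})
    missing = [c for c in SDM_COLUMNS if c not in df.columns]
    if missing:
        raise RecordError(f"record table missing columns: {missing}")
    return parse_sdm_records((row for _, row in df[SDM_COLUMNS].iterrows()), strict=strict)


def sdm_entity_flows(
    records: list[SDMRecord],
    level: str,
    geography: Geography,
) -> pd.DataFrame:
    """Weighted entity-flow table at ``level`` from home-based records.

    One row per (record, destination): entity = home cbg, origin/
    destination rolled up from cbg to ``level``, day = period start,
    weight = device count.  Weights are *not* deduplicated across
    block groups that share a coarser parent — they sum.  Endpoint
    coordinates are the centroids of the level's places.
    """
    fine = geography.levels[0]
    rows: list[dict] = []
    for rec in records:
        for dest_cbg in sorted(rec.destination_cbgs):
            rows.append(
                {
                    "entity_id": rec.origin_census_block_group,
                    "_o_cbg": rec.origin_census_block_group,
                    "_d_cbg": dest_cbg,
                    "day": rec.date_range_start,
                    "weight": float(rec.destination_cbgs[dest_cbg]),
                }
            )
    if not rows:
        return empty_flow_table()
    df = pd.DataFrame(rows)
    df["o_place"] = rollup_series(df["_o_cbg"], fine, level, geography)
    df["d_place"] = rollup_series(df["_d_cbg"], fine, level, geography)
    cent: dict[str, tuple[float, float]] = {}
    for pid in pd.unique(pd.concat([df["o_place"], df["d_place"]])):
        cent[pid] = geography.centroid(level, pid)
    df["o_lat"] = [cent[p][0] for p in df["o_place"]]
    df["o_lon"] = [cent[p][1] for p in df["o_place"]]
    df["d_lat"] = [cent[p][0] for p in df["d_place"]]
    df["d_lon"] = [cent[p][1] for p in df["d_place"]]
    df["kind"] = "sdm"
    # several destination cbgs may share one coarser parent: their device
    # counts sum into a single flow row per (entity, o, d, day)
    out = (
        df[FLOW_COLUMNS]
        .groupby(
            ["entity_id", "o_place", "d_place", "day", "kind"], as_index=False, sort=False
        )
        .agg(
            o_lat=("o_lat", "first"),
            o_lon=("o_lon", "first"),
            d_lat=("d_lat", "first"),
            d_lon=("d_lon", "first"),
            weight=("weight", "sum"),
        )[FLOW_COLUMNS]
        .sort_values(["entity_id", "day", "o_place", "d_place"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out
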