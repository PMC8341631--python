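"""Entity-level daily OD flow extraction from geotagged event streams.

An event stream is a table (entity_id, lat, lon, timestamp, source) of
timestamped geolocated observations — one row per geotagged post of a
social-media user, say.  Two movement rules turn a user's events into at
most a handful of daily origin-destination flows:

* **single-day**: for a day with at least two events, the origin is the
  day's chronologically first event and the destination the event
  farthest (great-circle) from that initial location;
* **cross-day**: for two consecutive active days, the origin is the mean
  center of the first day's events and the destination the mean center
  of the second day's; the flow is dated to the earlier day (configurable).

Zero-distance "movements" are not movements and yield no flow.  Automated
(bot) accounts are removed beforehand by matching the posting-client
``source`` string against allow/deny rules.  The combined flows form the
entity-level 4D cube (entity, origin place, destination place, day); one
entity contributes at most once to a given cell, so aggregate counts are
counts of distinct moving entities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geography import Geography, haversine_km, mean_center

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["entity_id", "lat", "lon", "timestamp", "source"]

#: Schema shared by the event path (weight 1) and the home-based record
#: path (device-count weights): one row per 4D entity-cube cell.
FLOW_COLUMNS = [
    "entity_id",
    "o_place",
    "d_place",
    "day",
    "o_lat",
    "o_lon",
    "d_lat",
    "d_lon",
    "kind",
    "weight",
]


def empty_flow_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity_id": pd.Series(dtype=str),
            "o_place": pd.Series(dtype=str),
            "d_place": pd.Series(dtype=str),
            "day": pd.Series(dtype=object),
            "o_lat": pd.Series(dtype=float),
            "o_lon": pd.Series(dtype=float),
            "d_lat": pd.Series(dtype=float),
            "d_lon": pd.Series(dtype=float),
            "kind": pd.Series(dtype=str),
            "weight": pd.Series(dtype=float),
        }
    )


@dataclass(frozen=True)
class SourceRules:
    """Allow-list XOR deny-list over posting-client source strings."""

    allow: frozenset[str] | None = None
    deny: frozenset[str] | None = None

    def __post_init__(self):
        if self.allow is not None and self.deny is not None:
            raise ConfigurationError("specify either an allow-list or a deny-list, not both")

    @property
    def is_noop(self) -> bool:
        return self.allow is None and self.deny is None


def filter_sources(events: pd.DataFrame, rules: SourceRules | None) -> pd.DataFrame:
    """Restrict the stream per the source rules; removals are logged."""
    if rules is None or rules.is_noop:
        return events
    if rules.allow is not None:
        keep = events["source"].isin(rules.allow)
    else:
        keep = ~events["source"].isin(rules.deny)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_sources removed %d events", n_removed)
    return events[keep]


def assign_days(events: pd.DataFrame, utc_offset_hours: float = 0.0) -> pd.DataFrame:
    """Attach a calendar-day column (UTC date, optionally offset)."""
    out = events.copy()
    ts = pd.to_datetime(out["timestamp"], utc=True)
    if utc_offset_hours:
        ts = ts + pd.Timedelta(hours=utc_offset_hours)
    out["timestamp"] = ts
    out["day"] = [t.date() for t in ts]
    return out


def eligible_entity_days(
    events: pd.DataFrame,
) -> tuple[set[tuple[str, date]], set[tuple[str, tuple[date, date]]]]:
    """Entity-day eligibility for the two movement rules.

    ``(entity, day)`` is single-day-eligible iff the entity posted at
    least two events that day; ``(entity, (d, d+1))`` is cross-day
    eligible iff it posted at least one event on each of the two
    consecutive days.  Expects a ``day`` column (see :func:`assign_days`).
    """
    single: set[tuple[str, date]] = set()
    cross: set[tuple[str, tuple[date, date]]] = set()
    counts = events.groupby(["entity_id", "day"], sort=False).size()
    per_entity_days: dict[str, set[date]] = {}
    for (ent, d), n in counts.items():
        per_entity_days.setdefault(ent, set()).add(d)
        if n >= 2:
            single.add((ent, d))
    for ent, days in per_entity_days.items():
        for d in days:
            if d + timedelta(days=1) in days:
                cross.add((ent, (d, d + timedelta(days=1))))
    return single, cross


def _sorted_day_events(day_events: pd.DataFrame) -> pd.DataFrame:
    # stable deterministic order: time, then coordinates break exact ties
    return day_events.sort_values(
        ["timestamp", "lat", "lon"], kind="mergesort"
    ).reset_index(drop=True)


def single_day_flow(
    day_events: pd.DataFrame,
    geography: Geography,
    level: str,
) -> dict | None:
    """Single-day movement of one entity on one day, or ``None``.

    Origin point = location of the chronologically first event;
    destination point = the event location at maximum great-circle
    distance from that initial location (ties to the earliest event).
    ``None`` when the maximum distance is zero or either endpoint falls
    outside the geography.
    """
    ev = _sorted_day_events(day_events)
    if len(ev) < 2:
        return None
    o_lat, o_lon = float(ev.loc[0, "lat"]), float(ev.loc[0, "lon"])
    dists = haversine_km(o_lat, o_lon, ev["lat"].to_numpy(), ev["lon"].to_numpy())
    dmax = float(dists.max())
    if dmax <= 0.0:
        return None
    i = int(np.argmax(dists))  # argmax takes the first (earliest) maximal event
    d_lat, d_lon = float(ev.loc[i, "lat"]), float(ev.loc[i, "lon"])
    o_place = geography.assign(o_lat, o_lon, level)
    d_place = geography.assign(d_lat, d_lon, level)
    if o_place is None or d_place is None:
        return None
    return {
        "entity_id": str(ev.loc[0, "entity_id"]),
        "o_place": o_place,
        "d_place": d_place,
        "day": ev.loc[0, "day"],
        "o_lat": o_lat,
        "o_lon": o_lon,
        "d_lat": d_lat,
        "d_lon": d_lon,
        "kind": "single_day",
        "weight": 1.0,
    }


def cross_day_flow(
    events_day1: pd.DataFrame,
    events_day2: pd.DataFrame,
    geography: Geography,
    level: str,
    attribute_to: str = "start",
) -> dict | None:
    """Cross-day movement between two consecutive active days, or ``None``.

    Origin point = mean center of the first day's event coordinates,
    destination point = mean center of the second day's.  ``None`` when
    the mean-center shift is zero or either center is unassigned.  The
    flow is dated to the earlier day (``attribute_to="start"``, default)
    or the later one (``"end"``).
    """
    if attribute_to not in ("start", "end"):
        raise ConfigurationError(f"attribute_to must be 'start' or 'end', got {attribute_to!r}")
    if len(events_day1) == 0 or len(events_day2) == 0:
        return None
    o_lat, o_lon = mean_center(list(zip(events_day1["lat"], events_day1["lon"])))
    d_lat, d_lon = mean_center(list(zip(events_day2["lat"], events_day2["lon"])))
    from .geography import great_circle_distance

    if great_circle_distance((o_lat, o_lon), (d_lat, d_lon)) <= 0.0:
        return None
    o_place = geography.assign(o_lat, o_lon, level)
    d_place = geography.assign(d_lat, d_lon, level)
    if o_place is None or d_place is None:
        return None
    day = events_day1["day"].iloc[0] if attribute_to == "start" else events_day2["day"].iloc[0]
    return {
        "entity_id": str(events_day1["entity_id"].iloc[0]),
        "o_place": o_place,
        "d_place": d_place,
        "day": day,
        "o_lat": o_lat,
        "o_lon": o_lon,
        "d_lat": d_lat,
        "d_lon": d_lon,
        "kind": "cross_day",
        "weight": 1.0,
    }


def extract_entity_flows(
    events: pd.DataFrame,
    geography: Geography,
    level: str,
    rules: SourceRules | None = None,
    utc_offset_hours: float = 0.0,
    cross_day_attribution: str = "start",
) -> pd.DataFrame:
    """Full event-stream extraction into the 4D entity-flow table.

    Applies source filtering, calendar-day assignment, the eligibility
    predicates and both movement rules, then deduplicates so that each
    (entity, origin place, destination place, day) cell appears at most
    once — a single-day and a cross-day flow landing in the same cell
    collapse to one presence (the single-day flow is kept, carrying its
    event-point endpoints).  Output row order is deterministic and
    independent of input row order.
    """
    if len(events) == 0:
        return empty_flow_table()
    ev = filter_sources(events, rules)
    if len(ev) == 0:
        return empty_flow_table()
    ev = assign_days(ev, utc_offset_hours)
    single_elig, cross_elig = eligible_entity_days(ev)

    single_by_ent: dict[str, list] = {}
    for ent, d in single_elig:
        single_by_ent.setdefault(ent, []).append(d)
    cross_by_ent: dict[str, list] = {}
    for ent, pair in cross_elig:
        cross_by_ent.setdefault(ent, []).append(pair)

    flows: list[dict] = []
    n_unassigned = 0
    for ent, ent_events in ev.groupby("entity_id", sort=True):
        by_day = {d: g for d, g in ent_events.groupby("day", sort=True)}
        for d in sorted(single_by_ent.get(ent, [])):
            f = single_day_flow(by_day[d], geography, level)
            if f is not None:
                flows.append(f)
            elif len(by_day[d]) >= 2:
                n_unassigned += 1
        for d1, d2 in sorted(cross_by_ent.get(ent, [])):
            f = cross_day_flow(
                by_day[d1], by_day[d2], geography, level, attribute_to=cross_day_attribution
            )
            if f is not None:
                flows.append(f)
    if n_unassigned:
        logger.info("extract_entity_flows: %d candidate flows dropped (zero distance or unassigned endpoint)", n_unassigned)
    if not flows:
        return empty_flow_table()
    table = pd.DataFrame(flows, columns=FLOW_COLUMNS)
    # presence-based dedup at the 4D-cell grain: single_day wins over cross_day
    table["_prio"] = (table["kind"] != "single_day").astype(int)
    table = (
        table.sort_values(["entity_id", "day", "o_place", "d_place", "_prio"], kind="mergesort")
        .drop_duplicates(subset=["entity_id", "o_place", "d_place", "day"], keep="first")
        .drop(columns="_prio")
        .reset_index(drop=True)
    )
    return table


def read_events_csv(path, sep: str = ",") -> pd.DataFrame:
    """Read an event table (entity_id, lat, lon, timestamp, source).

    Gzip is handled transparently by the ``.gz`` suffix.
    """
    df = pd.read_csv(path, sep=sep, dtype={"entity_id": str, "source": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"event table missing columns: {missing}")
    return df[EVENT_COLUMNS]
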