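"""Multi-level geographies and point-to-place assignment.

A :class:`Geography` holds, for each level of an ordered ladder (finest
first, e.g. ``cbg < county < state``), the place polygons in lon/lat
WGS84 degrees plus parent links to the next-coarser level.  The public
API surface speaks (lat, lon); GeoJSON files are lon/lat as the format
requires, and conversion is the reader's/writer's job.

Point-in-polygon assignment counts the polygon boundary as inside; when
two polygons both claim a boundary point the place earliest in sorted
place-id order wins, so assignment is reproducible.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point, shape, mapping
from shapely.strtree import STRtree

from .errors import CoordinateError, EmptyInputError, HierarchyError, LevelError

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Place:
    """One place at one geographic level.

    ``centroid`` is (lat, lon) in degrees and lies inside the place
    polygon (representative point for odd shapes).
    """

    place_id: str
    name: str
    level: str
    centroid: tuple[float, float]


def _check_coords(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise CoordinateError(f"coordinates out of range: lat={lat}, lon={lon}")


def great_circle_distance(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine distance in kilometres between two (lat, lon) points.

    Uses a spherical Earth of radius 6371 km.  Symmetric, non-negative
    and zero iff the points coincide.
    """
    lat1, lon1 = p1
    lat2, lon2 = p2
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def haversine_km(lat1, lon1, lat2, lon2):
    """Vectorised haversine (kilometres) over numpy-broadcastable arrays."""
    phi1 = np.radians(np.asarray(lat1, dtype=float))
    phi2 = np.radians(np.asarray(lat2, dtype=float))
    dphi = phi2 - phi1
    dlmb = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def mean_center(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> tuple[float, float]:
    """(Weighted) arithmetic mean of latitudes and of longitudes.

    Arithmetic in lon/lat degrees: adequate for the small-extent,
    mid-latitude geographies this toolkit targets; near the antimeridian
    the arithmetic mean is meaningless (see the methods note).
    """
    pts = list(points)
    if not pts:
        raise EmptyInputError("mean_center of an empty point set")
    lats = np.array([p[0] for p in pts], dtype=float)
    lons = np.array([p[1] for p in pts], dtype=float)
    if weights is None:
        return float(lats.mean()), float(lons.mean())
    w = np.asarray(list(weights), dtype=float)
    if w.shape != lats.shape:
        raise ValueError("weights length must match points length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise EmptyInputError("mean_center weights sum to zero")
    return float((lats * w).sum() / tot), float((lons * w).sum() / tot)


class Geography:
    """Places with polygons at named levels plus the level hierarchy.

    Parameters
    ----------
    levels:
        Level names ordered finest first (e.g. ``("cbg", "county", "state")``).
    polygons:
        ``{level: {place_id: shapely geometry in lon/lat degrees}}``.
    parents:
        ``{level: {place_id: parent place_id at the next-coarser level}}``;
        the coarsest level needs no entry.
    names:
        Optional ``{level: {place_id: display name}}``.
    """

    def __init__(
        self,
        levels: Sequence[str],
        polygons: Mapping[str, Mapping[str, object]],
        parents: Mapping[str, Mapping[str, str]] | None = None,
        names: Mapping[str, Mapping[str, str]] | None = None,
    ):
        self.levels = tuple(levels)
        if len(set(self.levels)) != len(self.levels):
            raise LevelError("duplicate level names in ladder")
        self._polygons = {lv: dict(polygons.get(lv, {})) for lv in self.levels}
        self._parents = {lv: dict((parents or {}).get(lv, {})) for lv in self.levels}
        self._names = {lv: dict((names or {}).get(lv, {})) for lv in self.levels}
        self._trees: dict[str, tuple[STRtree, list[str]]] = {}

    # -- level ladder ------------------------------------------------------

    def level_index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise LevelError(f"unknown level {level!r}; ladder is {self.levels}") from None

    def is_coarser(self, a: str, b: str) -> bool:
        """True iff level ``a`` is strictly coarser than ``b``."""
        return self.level_index(a) > self.level_index(b)

    def places(self, level: str) -> list[str]:
        self.level_index(level)
        return sorted(self._polygons[level])

    def polygon(self, level: str, place_id: str):
        return self._polygons[level][place_id]

    def name(self, level: str, place_id: str) -> str:
        return self._names[level].get(place_id, place_id)

    def place(self, level: str, place_id: str) -> Place:
        return Place(place_id, self.name(level, place_id), level, self.centroid(level, place_id))

    def centroid(self, level: str, place_id: str) -> tuple[float, float]:
        """(lat, lon) of a point guaranteed inside the place polygon."""
        poly = self._polygons[level][place_id]
        c = poly.centroid
        if not poly.covers(c):
            c = poly.representative_point()
        return (c.y, c.x)

    def parent_of(self, place_id: str, level: str) -> str:
        try:
            return self._parents[level][place_id]
        except KeyError:
            raise HierarchyError(
                f"place {place_id!r} at level {level!r} has no parent link"
            ) from None

    # -- spatial assignment ------------------------------------------------

    def _tree(self, level: str) -> tuple[STRtree, list[str]]:
        if level not in self._trees:
            ids = self.places(level)
            tree = STRtree([self._polygons[level][pid] for pid in ids])
            self._trees[level] = (tree, ids)
        return self._trees[level]

    def assign(self, lat: float, lon: float, level: str | None = None) -> str | None:
        """Id of the place whose polygon covers the point, else ``None``.

        ``level`` defaults to the finest level.  Boundary points count as
        inside; ties go to the smallest place id.
        """
        _check_coords(lat, lon)
        level = level or self.levels[0]
        self.level_index(level)
        tree, ids = self._tree(level)
        pt = Point(lon, lat)
        hits = [ids[i] for i in tree.query(pt, predicate="covered_by")]
        if not hits:
            return None
        return min(hits)

    # -- I/O ---------------------------------------------------------------

    def to_geojson(self, level: str) -> dict:
        """FeatureCollection for one level (lon/lat order, RFC 7946)."""
        feats = []
        for pid in self.places(level):
            props = {"place_id": pid, "name": self.name(level, pid)}
            if pid in self._parents[level]:
                props["parent_id"] = self._parents[level][pid]
            feats.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": mapping(self._polygons[level][pid]),
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, level: str, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_geojson(level), fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_geojson(
        cls,
        level_files: Mapping[str, object],
        levels: Sequence[str],
        hierarchy_csv: Mapping[str, object] | None = None,
    ) -> "Geography":
        """Build from one GeoJSON FeatureCollection per level.

        ``level_files`` maps level name to a path or an already-parsed
        FeatureCollection dict.  Parent links come from each feature's
        ``parent_id`` property, optionally overridden per level by a
        two-column (child_id, parent_id) CSV in ``hierarchy_csv``.
        """
        polygons: dict[str, dict] = {}
        parents: dict[str, dict] = {}
        names: dict[str, dict] = {}
        for lv in levels:
            if lv not in level_files:
                continue
            src = level_files[lv]
            if isinstance(src, (str,)) or hasattr(src, "__fspath__"):
                with open(src, encoding="utf-8") as fh:
                    fc = json.load(fh)
            else:
                fc = src
            polygons[lv], parents[lv], names[lv] = {}, {}, {}
            for feat in fc["features"]:
                props = feat.get("properties", {})
                pid = str(props["place_id"])
                polygons[lv][pid] = shape(feat["geometry"])
                names[lv][pid] = str(props.get("name", pid))
                if "parent_id" in props and props["parent_id"] is not None:
                    parents[lv][pid] = str(props["parent_id"])
        if hierarchy_csv:
            for lv, path in hierarchy_csv.items():
                with open(path, encoding="utf-8") as fh:
                    parents[lv] = {row[0]: row[1] for row in csv.reader(fh) if row}
        return cls(levels, polygons, parents, names)


def assign_place(lat: float, lon: float, geography: Geography, level: str | None = None) -> str | None:
    """Functional alias of :meth:`Geography.assign`."""
    return geography.assign(lat, lon, level)


def rollup_place(place_id: str, from_level: str, to_level: str, geography: Geography) -> str:
    """Ancestor of ``place_id`` at ``to_level`` via parent links.

    Identity when the two levels coincide.  For FIPS-style nested codes
    the result agrees with code-prefix truncation, but the hierarchy
    links are authoritative.
    """
    i, j = geography.level_index(from_level), geography.level_index(to_level)
    if j < i:
        raise LevelError(f"cannot roll up from {from_level!r} to finer level {to_level!r}")
    pid = place_id
    for k in range(i, j):
        pid = geography.parent_of(pid, geography.levels[k])
    return pid


def rollup_series(place_ids: Iterable[str], from_level: str, to_level: str, geography: Geography) -> list[str]:
    """Vector roll-up with a memo; same contract as :func:`rollup_place`."""
    memo: dict[str, str] = {}
    out = []
    for pid in place_ids:
        if pid not in memo:
            memo[pid] = rollup_place(pid, from_level, to_level, geography)
        out.append(memo[pid])
    return out
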