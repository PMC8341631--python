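"""Downstream mobility analyses on top of the cube algebra.

Two published-style analyses plus the tabular backends of the four
standard query scenarios:

* **Mobility reduction rate.** For monthly flow masses M_i and a
  baseline month's mass M_base, the reduction rate of month i is
  R_i = (M_i - M_base) / M_base — dimensionless, 0 at the baseline,
  negative for a reduction (R = -0.5 means mobility halved).
* **Outflow-case correlation.** Fix a focal place and a short flow
  window (e.g. the two days before a lockdown).  The flow vector
  v[j] is the summed outflow from the focal place to every other place
  j during the window.  For each evaluation day, correlate v against
  that day's cumulative confirmed case counts across places (Pearson by
  default; Spearman available).  Places reporting cases but absent
  from the sparse flow vector count as zero flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cube import ODTCube, dice, place_flows, place_series, slice_od
from .errors import BaselineError
from .geography import Geography

logger = logging.getLogger(__name__)

SCENARIOS = ("place_flows", "daily_movements", "od_matrix", "extract")


@dataclass
class ReductionSeries:
    """Per-period mobility change rates relative to a baseline period."""

    baseline: object
    baseline_mass: float
    masses: dict = field(default_factory=dict)  # period -> M_i
    rates: dict = field(default_factory=dict)  # period -> R_i

    def as_frame(self) -> pd.DataFrame:
        periods = sorted(self.masses)
        return pd.DataFrame(
            {
                "period": periods,
                "mass": [self.masses[p] for p in periods],
                "rate": [self.rates[p] for p in periods],
            }
        )


def reduction_rate(monthly_mass: Mapping, baseline_month) -> ReductionSeries:
    """Change rate of each period's flow mass against a baseline period.

    R_i = (M_i - M_base) / M_base.  The baseline period must be present
    with positive mass; its own rate is exactly 0.  Invariant under a
    uniform rescaling of all masses.
    """
    if baseline_month not in monthly_mass:
        raise BaselineError(f"baseline period {baseline_month!r} not in the mass table")
    m_base = float(monthly_mass[baseline_month])
    if m_base <= 0:
        raise BaselineError(f"baseline period {baseline_month!r} has non-positive mass {m_base}")
    series = ReductionSeries(baseline=baseline_month, baseline_mass=m_base)
    for period, m in monthly_mass.items():
        series.masses[period] = float(m)
        series.rates[period] = (float(m) - m_base) / m_base
    return series


@dataclass
class CorrelationSeries:
    """Daily flow-case correlation for one focal place."""

    focal_place: str
    flow_window: tuple[date, date]
    method: str
    table: pd.DataFrame  # columns: day, r, n

    @property
    def peak(self) -> tuple[date, float] | None:
        valid = self.table.dropna(subset=["r"])
        if len(valid) == 0:
            return None
        row = valid.loc[valid["r"].idxmax()]
        return row["day"], float(row["r"])


def outflow_case_correlation(
    cube: ODTCube,
    focal_place: str,
    flow_window: tuple[date, date],
    cases: pd.DataFrame,
    eval_days: list[date] | None = None,
    method: str = "pearson",
    geography: Geography | None = None,
) -> CorrelationSeries:
    """Correlate windowed outflows from a focal place with case counts.

    ``cases`` is a long table (place_id, date, cumulative_cases).  For
    each evaluation day the correlation pairs, across destination
    places j != focal, the fixed window outflow total v[j] with that
    day's cumulative cases; places in the case table with no stored
    flow cell enter with v[j] = 0.  Days with fewer than 3 paired
    places, or with a constant vector on either side, yield a missing
    r (logged), never an exception.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    pf = place_flows(cube, focal_place, t_range=flow_window, direction="outflow",
                     geography=geography)
    v_flow = pf.counterparts  # destination place -> windowed outflow
    cases = cases.copy()
    cases["date"] = [d if isinstance(d, date) else pd.Timestamp(d).date() for d in cases["date"]]
    cases["place_id"] = cases["place_id"].astype(str)
    if eval_days is None:
        eval_days = sorted(cases["date"].unique())
    rows = []
    for day in eval_days:
        day_cases = (
            cases[(cases["date"] == day) & (cases["place_id"] != focal_place)]
            .set_index("place_id")["cumulative_cases"]
            .astype(float)
        )
        places = sorted(day_cases.index)
        x = np.array([float(v_flow.get(p, 0.0)) for p in places])
        y = day_cases.loc[places].to_numpy()
        n = len(places)
        if n < 3:
            logger.warning("day %s: only %d paired places; correlation undefined", day, n)
            r = np.nan
        elif np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("day %s: constant vector; correlation undefined", day)
            r = np.nan
        elif method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        else:
            r = float(stats.spearmanr(x, y).statistic)
        rows.append({"day": day, "r": r, "n": n})
    return CorrelationSeries(focal_place, flow_window, method, pd.DataFrame(rows))


def _bbox_places(cube_level: str, geography: Geography, bbox: tuple[float, float, float, float]) -> set[str]:
    """Places whose centroid falls inside a (min_lat, min_lon, max_lat, max_lon) box."""
    lat0, lon0, lat1, lon1 = bbox
    out = set()
    for pid in geography.places(cube_level):
        lat, lon = geography.centroid(cube_level, pid)
        if lat0 <= lat <= lat1 and lon0 <= lon <= lon1:
            out.add(pid)
    return out


def scenario_tables(
    cube: ODTCube,
    query: Mapping,
    geography: Geography | None = None,
) -> pd.DataFrame:
    """Flat table for one of the four standard query scenarios.

    ``query`` carries ``scenario`` plus its parameters:

    * ``place_flows`` — totals between ``place`` and all counterparts
      over ``t_range`` in ``direction`` (choropleth backend);
    * ``daily_movements`` — daily series for ``place`` in ``direction``
      (time-series backend);
    * ``od_matrix`` — period-aggregated OD matrix, optionally windowed
      by ``t_range`` and restricted to a ``bbox`` area of interest;
    * ``extract`` — the diced daily subcube itself, ready for the
      daily-mode exporter.

    A ``bbox`` (min_lat, min_lon, max_lat, max_lon) selects the places
    whose centroid falls inside the box and requires a geography.
    """
    if hasattr(query, "model_dump"):
        query = query.model_dump()
    scenario = query.get("scenario")
    if scenario not in SCENARIOS:
        raise ValueError(f"invalid query: scenario must be one of {SCENARIOS}, got {scenario!r}")
    t_range = query.get("t_range")
    bbox = query.get("bbox")
    aoi: set[str] | None = None
    if bbox is not None:
        if geography is None:
            raise ValueError("invalid query: bbox selection requires a geography")
        aoi = _bbox_places(cube.level, geography, tuple(bbox))

    if scenario == "place_flows":
        bad = [f for f in ("place", "direction") if not query.get(f)]
        if bad:
            raise ValueError(f"invalid place_flows query: missing fields {bad}")
        pf = place_flows(cube, query["place"], t_range=t_range,
                         direction=query["direction"], geography=geography)
        out = pf.counterparts.rename("cnt").reset_index()
        out.insert(0, "focal_place", pf.place)
        out.attrs["intra"] = pf.intra
        return out
    if scenario == "daily_movements":
        bad = [f for f in ("place", "direction") if not query.get(f)]
        if bad:
            raise ValueError(f"invalid daily_movements query: missing fields {bad}")
        sub = dice(cube, t_range=t_range) if t_range else cube
        s = place_series(sub, query["place"], query["direction"], geography=geography)
        out = s.rename("cnt").reset_index()
        out.insert(0, "place", query["place"])
        return out
    if scenario == "od_matrix":
        sub = dice(cube, o_filter=aoi, d_filter=aoi, t_range=t_range)
        return slice_od(sub)
    # extract: the daily subcube as a flat table
    sub = dice(cube, o_filter=aoi, d_filter=aoi, t_range=t_range)
    return sub.cells.copy()
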