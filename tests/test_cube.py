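from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from odtcube.cube import (
    ODTCube,
    build_cube,
    dice,
    min_count_filter,
    place_flows,
    place_series,
    rollup_spatial,
    rollup_temporal,
    slice_dt,
    slice_od,
    slice_ot,
)
from odtcube.errors import LevelError, PlaceError
from odtcube.sdm import sdm_entity_flows
from odtcube.synth import SynthConfig, make_geography
from conftest import make_random_cube

D = lambda d: date(2020, 3, d)


def flow_row(ent, o, d, day, w=1.0, o_lat=38.5, o_lon=-97.5, d_lat=38.6, d_lon=-97.4):
    return {
        "entity_id": ent, "o_place": o, "d_place": d, "day": day,
        "o_lat": o_lat, "o_lon": o_lon, "d_lat": d_lat, "d_lon": d_lon,
        "kind": "single_day", "weight": w,
    }


class TestBuildCube:
    def test_three_entities_one_cell(self):
        flows = pd.DataFrame([flow_row(f"e{i}", "A", "B", D(1)) for i in range(3)])
        cube = build_cube(flows, "county")
        assert len(cube) == 1 and cube.cell("A", "B", D(1)) == 3.0

    def test_empty_flow_table_gives_empty_cube(self):
        cube = build_cube(pd.DataFrame(), "county")
        assert len(cube) == 0 and cube.day_range is None

    def test_matches_nested_loop_accumulation(self, rng):
        """Aggregation equals an independent nested-loop tally."""
        flows = pd.DataFrame(
            [
                flow_row(
                    f"e{int(rng.integers(10))}",
                    f"P{int(rng.integers(4))}",
                    f"P{int(rng.integers(4))}",
                    D(1 + int(rng.integers(3))),
                    w=float(rng.integers(1, 5)),
                    o_lat=38 + float(rng.random()),
                )
                for _ in range(200)
            ]
        )
        cube = build_cube(flows, "county")
        expected: dict[tuple, float] = {}
        wlat: dict[tuple, float] = {}
        for r in flows.itertuples():
            k = (r.o_place, r.d_place, r.day)
            expected[k] = expected.get(k, 0.0) + r.weight
            wlat[k] = wlat.get(k, 0.0) + r.weight * r.o_lat
        assert len(cube) == len(expected)
        for k, v in expected.items():
            assert cube.cell(*k) == pytest.approx(v)
        row = cube.cells.set_index(["o_place", "d_place", "day"])
        for k in expected:
            assert row.loc[k, "o_lat"] == pytest.approx(wlat[k] / expected[k])


class TestRollup:
    GEO = make_geography(SynthConfig(seed=0))

    def test_sibling_cells_sum_under_parent(self):
        geo = self.GEO
        cbgs = geo.places("cbg")
        a1 = cbgs[0]
        a2 = next(c for c in cbgs if c[:5] == a1[:5] and c != a1)
        b1 = next(c for c in cbgs if c[:2] != a1[:2])
        flows = pd.DataFrame(
            [flow_row("x", a1, b1, D(1), w=2.0), flow_row("y", a2, b1, D(1), w=3.0)]
        )
        cube = rollup_spatial(build_cube(flows, "cbg"), "county", geo)
        assert cube.cell(a1[:5], b1[:5], D(1)) == 5.0
        assert cube.total == 5.0

    def test_rollup_to_own_level_is_identity(self, rng):
        cube = make_random_cube(rng)
        same = rollup_spatial(cube, "county", self.GEO)
        assert same == cube

    def test_downward_rollup_rejected(self, rng):
        with pytest.raises(LevelError):
            rollup_spatial(make_random_cube(rng), "cbg", self.GEO)

    def test_two_path_equality_weighted_flows(self, sdm_and_truth, geo):
        """cbg cube rolled to county = cube built from county flows (counts)."""
        records, _ = sdm_and_truth
        from odtcube.sdm import parse_sdm_records

        recs = parse_sdm_records((r for _, r in records.iterrows()))
        up = rollup_spatial(build_cube(sdm_entity_flows(recs, "cbg", geo), "cbg"), "county", geo)
        direct = build_cube(sdm_entity_flows(recs, "county", geo), "county")
        pd.testing.assert_frame_equal(
            up.cells[["o_place", "d_place", "day", "cnt"]],
            direct.cells[["o_place", "d_place", "day", "cnt"]],
        )

    def test_mass_conserved(self, rng):
        cube = make_random_cube(rng, n_places=10, n_cells=80)
        geo = self.GEO
        # remap places onto real county codes so parent links exist
        counties = geo.places("county")
        mapping = {p: counties[i % len(counties)] for i, p in enumerate(sorted(cube.places))}
        cells = cube.cells.copy()
        cells["o_place"] = cells["o_place"].map(mapping)
        cells["d_place"] = cells["d_place"].map(mapping)
        cube = build_cube(
            cells.rename(columns={"cnt": "weight"}).assign(entity_id="e", kind="sdm"),
            "county",
        )
        up = rollup_spatial(cube, "state", geo)
        assert up.total == pytest.approx(cube.total)


class TestTemporalRollup:
    def test_one_iso_week_sums_to_seven(self):
        # 2020-03-02 is a Monday: seven unit cells in one ISO week
        rows = [flow_row("e", "A", "B", D(2 + i)) for i in range(7)]
        cube = build_cube(pd.DataFrame(rows), "county")
        weekly = rollup_temporal(cube, "week")
        assert len(weekly) == 1
        assert weekly.loc[0, "period"] == D(2) and weekly.loc[0, "cnt"] == 7.0

    def test_single_day_cube_totals_unchanged_at_any_granularity(self, rng):
        cube = make_random_cube(rng, n_days=1, n_cells=10)
        for g in ("day", "week", "month"):
            out = rollup_temporal(cube, g)
            assert out["cnt"].sum() == pytest.approx(cube.total)

    def test_monthly_totals_match_date_filter_oracle(self, rng):
        cube = make_random_cube(rng, n_days=70, n_cells=300, n_places=5)
        monthly = rollup_temporal(cube, "month")
        for period in monthly["period"].unique():
            nxt = (period.replace(day=28) + timedelta(days=4)).replace(day=1)
            mask = cube.cells["day"].apply(lambda d: period <= d < nxt)
            expected = cube.cells.loc[mask, "cnt"].sum()
            got = monthly.loc[monthly["period"] == period, "cnt"].sum()
            assert got == pytest.approx(expected)

    def test_custom_ranges_drop_uncovered_days(self, rng):
        cube = make_random_cube(rng, n_days=10, n_cells=60)
        ranges = [(D(1), D(3)), (D(6), D(8))]
        out = rollup_temporal(cube, custom_ranges=ranges)
        covered = cube.cells["day"].apply(
            lambda d: any(a <= d <= b for a, b in ranges)
        )
        assert out["cnt"].sum() == pytest.approx(cube.cells.loc[covered, "cnt"].sum())
        assert set(out["period"]) <= {D(1), D(6)}

    def test_empty_intersection_gives_empty_result(self, rng):
        cube = make_random_cube(rng, n_days=3)
        out = rollup_temporal(cube, custom_ranges=[(date(2021, 1, 1), date(2021, 1, 5))])
        assert len(out) == 0


class TestDice:
    def test_all_filters_identity(self, rng):
        cube = make_random_cube(rng)
        assert dice(cube) == cube
        assert dice(cube, t_range=cube.day_range) == cube

    def test_absent_place_filter_gives_empty_cube(self, rng):
        cube = make_random_cube(rng)
        assert len(dice(cube, o_filter={"nowhere"})) == 0

    def test_matches_predicate_scan(self, rng):
        """Random filters vs a row-wise predicate scan."""
        for _ in range(20):
            cube = make_random_cube(rng, n_cells=50)
            places = sorted(cube.places)
            o_f = set(rng.choice(places, size=3, replace=False))
            d_f = set(rng.choice(places, size=4, replace=False))
            t0 = D(1 + int(rng.integers(3)))
            t1 = t0 + timedelta(days=int(rng.integers(4)))
            sub = dice(cube, o_f, d_f, (t0, t1))
            expected = [
                r
                for r in cube.cells.itertuples(index=False)
                if r.o_place in o_f and r.d_place in d_f and t0 <= r.day <= t1
            ]
            assert len(sub) == len(expected)
            assert sub.total == pytest.approx(sum(r.cnt for r in expected))

    def test_dice_composition_equals_intersection(self, rng):
        cube = make_random_cube(rng, n_cells=60)
        places = sorted(cube.places)
        f1, f2 = set(places[:5]), set(places[2:7])
        twice = dice(dice(cube, o_filter=f1), o_filter=f2)
        once = dice(cube, o_filter=f1 & f2)
        assert twice == once

    def test_invalid_range_rejected(self, rng):
        with pytest.raises(ValueError):
            dice(make_random_cube(rng), t_range=(D(5), D(2)))


class TestSlices:
    def test_single_cell_appears_in_all_slices(self):
        cube = build_cube(pd.DataFrame([flow_row("e", "A", "B", D(3), w=4.0)]), "county")
        od, ot, dt = slice_od(cube), slice_ot(cube), slice_dt(cube)
        assert od.set_index(["o_place", "d_place"]).loc[("A", "B"), "cnt"] == 4.0
        assert ot.set_index(["o_place", "day"]).loc[("A", D(3)), "cnt"] == 4.0
        assert dt.set_index(["d_place", "day"]).loc[("B", D(3)), "cnt"] == 4.0

    def test_total_mass_identical_across_slices(self, rng):
        for _ in range(10):
            cube = make_random_cube(rng, n_cells=int(rng.integers(5, 60)))
            t = cube.total
            assert slice_od(cube)["cnt"].sum() == pytest.approx(t)
            assert slice_ot(cube)["cnt"].sum() == pytest.approx(t)
            assert slice_dt(cube)["cnt"].sum() == pytest.approx(t)

    def test_pure_diagonal_cube_mass_is_all_on_diagonal(self):
        rows = [flow_row("e", "A", "A", D(i), w=2.0) for i in range(1, 4)]
        cube = build_cube(pd.DataFrame(rows), "county")
        od = slice_od(cube)
        diag = od[od.o_place == od.d_place]
        assert diag["cnt"].sum() == cube.total

    def test_od_respects_date_window(self, rng):
        cube = make_random_cube(rng, n_days=8, n_cells=50)
        window = (D(2), D(4))
        od = slice_od(cube, t_range=window)
        assert od["cnt"].sum() == pytest.approx(dice(cube, t_range=window).total)


class TestPlaceQueries:
    def worked_cube(self):
        rows = [
            flow_row("e1", "A", "B", D(1), w=2.0),
            flow_row("e2", "B", "A", D(1), w=3.0),
            flow_row("e3", "B", "B", D(1), w=5.0),
        ]
        return build_cube(pd.DataFrame(rows), "county")

    def test_directions_on_worked_cube(self):
        cube = self.worked_cube()
        assert place_series(cube, "B", "inflow")[D(1)] == 2.0
        assert place_series(cube, "B", "outflow")[D(1)] == 3.0
        assert place_series(cube, "B", "intraflow")[D(1)] == 5.0
        assert place_series(cube, "B", "in_and_out")[D(1)] == 5.0  # diagonal excluded

    def test_quiet_place_gives_zero_series(self):
        geo = make_geography(SynthConfig(seed=0))
        counties = geo.places("county")
        rows = [flow_row("e", counties[0], counties[1], D(1))]
        cube = build_cube(pd.DataFrame(rows), "county")
        s = place_series(cube, counties[2], "inflow", geography=geo)
        assert (s == 0).all()

    def test_unknown_place_rejected(self):
        with pytest.raises(PlaceError):
            place_series(self.worked_cube(), "Z", "inflow")

    def test_series_match_scan_oracle(self, rng):
        for _ in range(10):
            cube = make_random_cube(rng, n_cells=40)
            place = sorted(cube.places)[0]
            for direction in ("inflow", "outflow", "intraflow", "in_and_out"):
                s = place_series(cube, place, direction)
                for day in s.index:
                    exp = 0.0
                    for r in cube.cells.itertuples(index=False):
                        if r.day != day:
                            continue
                        o, d = r.o_place == place, r.d_place == place
                        if direction == "inflow" and d and not o:
                            exp += r.cnt
                        elif direction == "outflow" and o and not d:
                            exp += r.cnt
                        elif direction == "intraflow" and o and d:
                            exp += r.cnt
                        elif direction == "in_and_out" and (o != d):
                            exp += r.cnt
                    assert s[day] == pytest.approx(exp)

    def test_place_flows_single_cell_inflow(self):
        cube = build_cube(pd.DataFrame([flow_row("e", "A", "B", D(1), w=4.0)]), "county")
        pf = place_flows(cube, "B", direction="inflow")
        assert dict(pf.counterparts) == {"A": 4.0} and pf.intra == 0.0

    def test_place_flows_in_and_out_is_elementwise_sum(self, rng):
        cube = make_random_cube(rng, n_cells=50)
        place = sorted(cube.places)[1]
        both = place_flows(cube, place, direction="in_and_out").counterparts
        inf = place_flows(cube, place, direction="inflow").counterparts
        outf = place_flows(cube, place, direction="outflow").counterparts
        combined = inf.add(outf, fill_value=0.0).sort_index()
        pd.testing.assert_series_equal(both, combined, check_names=False)

    def test_in_and_out_series_is_inflow_plus_outflow(self, rng):
        cube = make_random_cube(rng, n_cells=50)
        place = sorted(cube.places)[0]
        lhs = place_series(cube, place, "in_and_out")
        rhs = place_series(cube, place, "inflow") + place_series(cube, place, "outflow")
        pd.testing.assert_series_equal(lhs, rhs, check_names=False)

    def test_cross_operation_consistency(self, rng):
        """slice_ot of the origin-diced cube = outflow + intraflow series."""
        cube = make_random_cube(rng, n_cells=60)
        place = sorted(cube.places)[0]
        ot = slice_ot(dice(cube, o_filter={place}))
        ot_series = ot.set_index("day")["cnt"]
        decomposed = place_series(cube, place, "outflow") + place_series(cube, place, "intraflow")
        decomposed = decomposed[decomposed > 0]
        pd.testing.assert_series_equal(
            ot_series.sort_index(), decomposed.sort_index(), check_names=False
        )


class TestMinCountFilter:
    def test_zero_threshold_drops_nothing(self, rng):
        cube = make_random_cube(rng)
        assert min_count_filter(cube, 0) == cube

    def test_threshold_is_strict(self):
        rows = [flow_row("e", "A", "B", D(1), w=20.0), flow_row("e", "A", "C", D(1), w=21.0)]
        cube = build_cube(pd.DataFrame(rows), "county")
        kept = min_count_filter(cube, 20)
        assert len(kept) == 1 and kept.cell("A", "C", D(1)) == 21.0

    def test_matches_predicate_scan(self, rng):
        cube = make_random_cube(rng, n_cells=70)
        thr = 10
        kept = min_count_filter(cube.cells, thr)
        assert set(map(tuple, kept[["o_place", "d_place"]].values)) == {
            (r.o_place, r.d_place)
            for r in cube.cells.itertuples(index=False)
            if r.cnt > thr
        }
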