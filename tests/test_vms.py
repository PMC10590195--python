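from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
import shapely

from trawlkit.errors import ConfigError
from trawlkit.geometry import haversine_km
from trawlkit.vms import (
    GridSpec,
    allocate_landings,
    assign_trip_codes,
    classify_fishing,
    clean_pings,
    fishing_time,
    interpolate_track_10min,
    process_fleet,
    rasterize_effort,
)

T0 = datetime(2021, 5, 1, 6, 0, tzinfo=timezone.utc)


def ping_frame(rows):
    return pd.DataFrame(rows, columns=["vessel_id", "timestamp", "lat", "lon", "speed"])


def two_ping_trip(minutes=60, lat=(0.0, 0.0), lon=(0.0, 1.0), speed=3.0):
    df = ping_frame(
        [("V1", T0, lat[0], lon[0], speed),
         ("V1", T0 + timedelta(minutes=minutes), lat[1], lon[1], speed)]
    )
    return assign_trip_codes(df)


class TestCleanPings:
    def test_exact_duplicates_collapsed(self):
        df = ping_frame([("V1", T0, 40.0, 2.0, 3.0), ("V1", T0, 40.0, 2.0, 3.0)])
        assert len(clean_pings(df)) == 1

    def test_on_land_points_removed(self):
        land = shapely.box(0.0, 0.0, 1.0, 1.0)
        df = ping_frame([("V1", T0, 0.5, 0.5, 3.0),
                         ("V1", T0 + timedelta(hours=1), 2.0, 2.0, 3.0)])
        out = clean_pings(df, land_polygons=land)
        assert len(out) == 1
        assert out["lat"].iloc[0] == 2.0

    def test_empty_input(self):
        assert clean_pings(ping_frame([])).empty


class TestTripCodes:
    def test_two_dates_two_codes(self):
        df = ping_frame([("V1", T0, 40.0, 2.0, 3.0),
                         ("V1", T0 + timedelta(days=1), 40.0, 2.0, 3.0)])
        assert assign_trip_codes(df)["trip_code"].nunique() == 2

    def test_two_vessels_two_codes(self):
        df = ping_frame([("V1", T0, 40.0, 2.0, 3.0), ("V2", T0, 40.0, 2.0, 3.0)])
        assert assign_trip_codes(df)["trip_code"].nunique() == 2

    def test_same_vessel_day_shares_code(self):
        df = ping_frame(
            [("V1", T0 + timedelta(minutes=10 * i), 40.0, 2.0, 3.0) for i in range(54)]
        )
        assert assign_trip_codes(df)["trip_code"].nunique() == 1


class TestInterpolation:
    def test_hour_gap_yields_five_interior_points(self):
        out = interpolate_track_10min(two_ping_trip(60))
        assert len(out) == 7
        assert (out["origin"] == "interpolated").sum() == 5

    def test_midpoint_linearity(self):
        out = interpolate_track_10min(two_ping_trip(60, lon=(0.0, 1.0)))
        mid = out[out["timestamp"] == T0 + timedelta(minutes=30)]
        assert mid["lon"].iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert mid["lat"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_idempotent_on_10min_mesh(self):
        once = interpolate_track_10min(two_ping_trip(60))
        twice = interpolate_track_10min(once)
        assert len(twice) == len(once)
        pd.testing.assert_frame_equal(
            twice.reset_index(drop=True), once.reset_index(drop=True)
        )

    def test_single_ping_unchanged(self):
        df = assign_trip_codes(ping_frame([("V1", T0, 40.0, 2.0, 3.0)]))
        out = interpolate_track_10min(df)
        assert len(out) == 1

    def test_interpolated_points_collinear(self):
        # linear coordinate model: interpolated lon proportional to elapsed time
        out = interpolate_track_10min(two_ping_trip(60, lon=(0.0, 1.0)))
        elapsed = (out["timestamp"] - T0).dt.total_seconds()
        np.testing.assert_allclose(out["lon"], elapsed / 3600.0, atol=1e-9)

    def test_interpolated_speed_recomputed_over_mesh(self):
        out = interpolate_track_10min(two_ping_trip(60, lon=(0.0, 1.0)))
        interp = out[out["origin"] == "interpolated"]
        seg_km = haversine_km(0.0, 0.0, 0.0, 1.0 / 6.0)
        expected_kn = seg_km / (10.0 / 60.0) / 1.852
        np.testing.assert_allclose(interp["speed"], expected_kn, rtol=1e-6)


class TestClassification:
    @staticmethod
    def flat_bathy(depth):
        return lambda lat, lon: np.full(np.shape(lat), float(depth))

    def test_steaming_speed_not_fishing(self):
        df = ping_frame([("V1", T0, 40.0, 2.0, 10.0)])
        out = classify_fishing(df, bathymetry=self.flat_bathy(300))
        assert not out["is_fishing"].iloc[0]

    def test_too_deep_not_fishing(self):
        df = ping_frame([("V1", T0, 40.0, 2.0, 3.0)])
        out = classify_fishing(df, bathymetry=self.flat_bathy(2000))
        assert not out["is_fishing"].iloc[0]

    def test_inside_both_filters_is_fishing(self):
        df = ping_frame([("V1", T0, 40.0, 2.0, 3.0)])
        out = classify_fishing(df, speed_range_kn=(1.0, 4.5),
                               bathymetry=self.flat_bathy(300))
        assert out["is_fishing"].iloc[0]

    def test_missing_bathymetry_not_fishing(self):
        df = ping_frame([("V1", T0, 40.0, 2.0, 3.0)])
        out = classify_fishing(df, bathymetry=self.flat_bathy(np.nan))
        assert not out["is_fishing"].iloc[0]

    def test_monotone_in_filter_width(self):
        rng = np.random.default_rng(2)
        df = ping_frame(
            [("V1", T0 + timedelta(minutes=10 * i), 40.0, 2.0, float(s))
             for i, s in enumerate(rng.uniform(0, 12, 50))]
        )
        bathy = self.flat_bathy(300)
        narrow = classify_fishing(df, speed_range_kn=(2.0, 4.0), bathymetry=bathy)
        wide = classify_fishing(df, speed_range_kn=(1.0, 6.0), bathymetry=bathy)
        assert (wide["is_fishing"] | ~narrow["is_fishing"]).all()

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigError):
            classify_fishing(ping_frame([]), speed_range_kn=(5.0, 1.0))


class TestFishingTime:
    def make_trip(self, n_fishing):
        df = ping_frame(
            [("V1", T0 + timedelta(minutes=10 * i), 40.0, 2.0, 3.0)
             for i in range(max(n_fishing, 1))]
        )
        df = assign_trip_codes(df)
        df["is_fishing"] = [True] * n_fishing + [False] * (len(df) - n_fishing)
        return df

    def test_twelve_pings_two_hours(self):
        assert fishing_time(self.make_trip(12)) == pytest.approx(2.0)

    def test_no_fishing_is_zero(self):
        assert fishing_time(self.make_trip(0)) == 0.0

    def test_over_daily_limit_warns_not_truncates(self, caplog):
        with caplog.at_level("WARNING", logger="trawlkit.vms"):
            hours = fishing_time(self.make_trip(80))
        assert hours == pytest.approx(80 / 6.0)
        assert any("12 h" in rec.message for rec in caplog.records)


class TestAllocation:
    def make_classified_trip(self, n_fishing):
        df = self.trip = assign_trip_codes(ping_frame(
            [("V1", T0 + timedelta(minutes=10 * i), 40.0, 2.0, 3.0) for i in range(10)]
        ))
        df["is_fishing"] = [True] * n_fishing + [False] * (10 - n_fishing)
        return df

    def landings(self, rows):
        return pd.DataFrame(rows, columns=["species_code", "weight_kg", "revenue_eur"])

    def test_equal_split_conserves_total(self):
        trip = self.make_classified_trip(10)
        alloc, issues = allocate_landings(trip, self.landings([("HKE", 100.0, 500.0)]))
        assert issues == []
        assert (alloc["weight_kg"] == 10.0).all()
        assert alloc["weight_kg"].sum() == pytest.approx(100.0, rel=1e-12)

    def test_two_species_split_independently(self):
        trip = self.make_classified_trip(4)
        alloc, _ = allocate_landings(
            trip, self.landings([("HKE", 100.0, 0.0), ("MUT", 40.0, 0.0)])
        )
        per = alloc.groupby("species_code")["weight_kg"].first()
        assert per["HKE"] == pytest.approx(25.0)
        assert per["MUT"] == pytest.approx(10.0)

    def test_zero_fishing_pings_is_unallocated_issue(self):
        trip = self.make_classified_trip(0)
        alloc, issues = allocate_landings(trip, self.landings([("HKE", 100.0, 0.0)]))
        assert alloc.empty
        assert len(issues) == 1 and "unallocated" in issues[0]


class TestRasterization:
    def test_single_cell_trip(self):
        # 12 fishing pings (2 h) all inside one 1-km cell
        df = assign_trip_codes(ping_frame(
            [("V1", T0 + timedelta(minutes=10 * i), 40.0001, 2.0001, 3.0)
             for i in range(12)]
        ))
        df["is_fishing"] = True
        spec = GridSpec(40.0, 40.1, 2.0, 2.1, cell_size_km=1.0)
        grid = rasterize_effort(df, pd.DataFrame(
            columns=["ping_index", "species_code", "weight_kg", "revenue_eur"]), spec)
        assert grid.effort.sum() == pytest.approx(2.0)
        assert (grid.effort > 0).sum() == 1

    def test_empty_pings_all_zero(self):
        spec = GridSpec(40.0, 40.1, 2.0, 2.1)
        grid = rasterize_effort(
            pd.DataFrame(columns=["vessel_id", "timestamp", "lat", "lon", "speed",
                                  "is_fishing"]),
            pd.DataFrame(columns=["ping_index", "species_code", "weight_kg",
                                  "revenue_eur"]),
            spec,
        )
        assert grid.effort.sum() == 0 and grid.landings.sum() == 0

    def test_grid_conserves_mass_and_revenue(self):
        rng = np.random.default_rng(9)
        df = assign_trip_codes(ping_frame(
            [("V1", T0 + timedelta(minutes=10 * i),
              40.0 + rng.uniform(0, 0.08), 2.0 + rng.uniform(0, 0.08), 3.0)
             for i in range(30)]
        ))
        df["is_fishing"] = True
        alloc, issues = allocate_landings(
            df, pd.DataFrame([("HKE", 123.4, 567.8)],
                             columns=["species_code", "weight_kg", "revenue_eur"])
        )
        assert issues == []
        spec = GridSpec(40.0, 40.1, 2.0, 2.1, cell_size_km=1.0)
        grid = rasterize_effort(df, alloc, spec)
        assert grid.landings.sum() * grid.cell_area_km2 == pytest.approx(123.4, rel=1e-9)
        assert grid.revenue.sum() == pytest.approx(567.8, rel=1e-9)

    def test_rpue_masked_without_effort(self):
        spec = GridSpec(40.0, 40.1, 2.0, 2.1)
        grid = rasterize_effort(
            pd.DataFrame(columns=["vessel_id", "timestamp", "lat", "lon", "speed",
                                  "is_fishing"]),
            pd.DataFrame(columns=["ping_index", "species_code", "weight_kg",
                                  "revenue_eur"]),
            spec,
        )
        assert np.isnan(grid.rpue).all()


class TestFleetPipeline:
    def test_end_to_end_conservation(self):
        """Total kg and EUR in the grid equal the allocatable landings for a
        randomized synthetic fleet of 100 trips."""
        from trawlkit.simulate import (
            SimulationConfig, land_polygon, simulate_fleet_day, synthetic_bathymetry,
        )
        from datetime import date

        config = SimulationConfig(seed=3)
        rng_master = np.random.default_rng(3)
        pings, landings = [], []
        for v in range(10):
            for d in range(10):
                p, l = simulate_fleet_day(
                    config, date(2021, 4, 1 + d), f"FV{v:02d}",
                    np.random.default_rng(1000 + v * 10 + d),
                )
                pings.append(p)
                landings.append(l)
        pings = pd.concat(pings, ignore_index=True).drop(columns=["truth_fishing"])
        landings = pd.concat(landings, ignore_index=True)
        classified, alloc, issues = process_fleet(
            pings, landings, bathymetry=synthetic_bathymetry,
            land_polygons=land_polygon(),
        )
        assert issues == []
        assert alloc["weight_kg"].sum() == pytest.approx(
            landings["weight_kg"].sum(), rel=1e-9
        )
        fishing = classified[classified["is_fishing"].fillna(False).astype(bool)]
        spec = GridSpec(
            float(fishing["lat"].min()) - 0.02, float(fishing["lat"].max()) + 0.02,
            float(fishing["lon"].min()) - 0.02, float(fishing["lon"].max()) + 0.02,
            cell_size_km=1.0,
        )
        grid = rasterize_effort(classified, alloc, spec)
        assert grid.landings.sum() * grid.cell_area_km2 == pytest.approx(
            landings["weight_kg"].sum(), rel=1e-9
        )
        assert grid.revenue.sum() == pytest.approx(
            landings["revenue_eur"].sum(), rel=1e-9
        )
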