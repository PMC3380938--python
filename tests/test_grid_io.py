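"""Grid geometry, sample-table I/O and covariate attachment."""

import numpy as np
import pandas as pd
import pytest

from lgcpindex import (GridSpec, haversine_km, read_samples, write_samples,
                       assign_cells, attach_thermocline, validate_samples,
                       make_covariate_field, read_field, write_field)
from lgcpindex.data import SchemaError


@pytest.mark.parametrize("a, b, expected", [
    ((55.0, 3.0), (55.0, 3.0), 0.0),
    ((55.0, 0.0), (56.0, 0.0), 111.19),      # one degree of latitude
    ((0.0, 0.0), (0.0, 1.0), 111.19),        # one degree of longitude at the equator
])
def test_haversine_known_distances(a, b, expected):
    assert haversine_km(*a, *b) == pytest.approx(expected, abs=0.01)


def test_haversine_symmetry_and_triangle_inequality():
    rng = np.random.default_rng(42)
    lat = rng.uniform(45, 65, (200, 3))
    lon = rng.uniform(-10, 10, (200, 3))
    d01 = haversine_km(lat[:, 0], lon[:, 0], lat[:, 1], lon[:, 1])
    d10 = haversine_km(lat[:, 1], lon[:, 1], lat[:, 0], lon[:, 0])
    d12 = haversine_km(lat[:, 1], lon[:, 1], lat[:, 2], lon[:, 2])
    d02 = haversine_km(lat[:, 0], lon[:, 0], lat[:, 2], lon[:, 2])
    np.testing.assert_allclose(d01, d10, rtol=1e-12)
    assert (d02 <= d01 + d12 + 1e-6).all()


class TestCellAssignment:
    def test_centroid_maps_to_own_cell(self, small_grid):
        clat, clon = small_grid.centroids()
        np.testing.assert_array_equal(small_grid.cell_of(clat, clon),
                                      np.arange(small_grid.n_cells))

    def test_shared_edge_goes_to_upper_cell(self, small_grid):
        # half-open convention: the boundary belongs to the cell whose lower
        # edge it lies on
        g = small_grid
        edge_lat = g.lat0 + g.dlat          # boundary between rows 0 and 1
        cell = g.cell_of(edge_lat, g.lon0 + 0.1)
        assert cell == 1 * g.nlon + 0

    def test_random_points_close_to_assigned_centroid(self, small_grid):
        g = small_grid
        rng = np.random.default_rng(7)
        lat = rng.uniform(g.lat0, g.lat_max - 1e-9, 100)
        lon = rng.uniform(g.lon0, g.lon_max - 1e-9, 100)
        cell = g.cell_of(lat, lon)
        clat, clon = g.centroids()
        d = haversine_km(lat, lon, clat[cell], clon[cell])
        # brute-force bound: half the cell diagonal
        half_diag = 0.5 * haversine_km(g.lat0, g.lon0,
                                       g.lat0 + g.dlat, g.lon0 + g.dlon)
        assert (d <= half_diag + 1e-9).all()
        # and the assigned centroid is the nearest in grid-scaled coordinates
        du = np.abs(lat[:, None] - clat[None, :]) / g.dlat \
            + np.abs(lon[:, None] - clon[None, :]) / g.dlon
        np.testing.assert_array_equal(cell, du.argmin(axis=1))

    def test_idempotent_and_outside_excluded(self, small_grid, sample_factory):
        rng = np.random.default_rng(0)
        df = sample_factory(30, small_grid, (2000, 2001), rng)
        df.loc[0, "lat"] = small_grid.lat_max + 1.0
        with pytest.warns(UserWarning, match="outside the grid"):
            a1 = assign_cells(df, small_grid)
        assert len(a1) == 29
        a2 = assign_cells(a1, small_grid)
        pd.testing.assert_frame_equal(a1, a2)


class TestSampleIO:
    def test_round_trip_preserves_fields(self, small_grid, sample_factory, tmp_path):
        rng = np.random.default_rng(3)
        df = sample_factory(25, small_grid, (1990, 1995), rng)
        df.loc[3, "thermocline_depth_m"] = np.nan
        path = tmp_path / "samples.csv"
        write_samples(df, path)
        back = read_samples(path, lat_bounds=(small_grid.lat0, small_grid.lat_max),
                            lon_bounds=(small_grid.lon0, small_grid.lon_max))
        for col in ("sample_id", "year", "day_of_year", "hour", "count"):
            np.testing.assert_array_equal(back[col].to_numpy(), df[col].to_numpy())
        for col in ("lat", "lon"):
            np.testing.assert_allclose(back[col], df[col], atol=1e-9)
        assert np.isnan(back.loc[3, "thermocline_depth_m"])

    def test_three_row_file_parses(self, tmp_path):
        path = tmp_path / "ok.csv"
        path.write_text("sample_id,lat,lon,year,day_of_year,hour,count\n"
                        "a,55.0,2.0,1990,150,10,0\n"
                        "b,55.3,2.5,1990,151,11,2\n"
                        "c,55.6,3.0,1991,152,12,1\n")
        df = read_samples(path)
        assert len(df) == 3
        assert df["count"].tolist() == [0, 2, 1]

    def test_invalid_rows_rejected_with_reason(self):
        df = pd.DataFrame({
            "sample_id": ["a", "b", "c", "d"],
            "lat": [55.0, 55.0, 70.0, 55.0],
            "lon": [2.0, 2.0, 2.0, 2.0],
            "year": [1990] * 4,
            "day_of_year": [150, 150, 150, 400],
            "hour": [10] * 4,
            "count": [1, -1, 1, 1],
        })
        good, rejected = validate_samples(df)
        assert len(good) == 1 and good.loc[0, "sample_id"] == "a"
        reasons = dict(zip(rejected["sample_id"], rejected["reason"]))
        assert "negative count" in reasons["b"]
        assert "latitude" in reasons["c"]
        assert "day_of_year" in reasons["d"]

    def test_non_integer_count_rejected(self):
        df = pd.DataFrame({"sample_id": ["a"], "lat": [55.0], "lon": [2.0],
                           "year": [1990], "day_of_year": [100], "hour": [1],
                           "count": [1.5]})
        good, rejected = validate_samples(df)
        assert len(good) == 0 and "non-integer" in rejected["reason"].iloc[0]

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="count"):
            validate_samples(pd.DataFrame({"sample_id": ["a"], "lat": [55.0],
                                           "lon": [2.0], "year": [1990],
                                           "day_of_year": [100], "hour": [1]}))


class TestThermoclineAttachment:
    def _field(self, grid, values_fn, months=((2000, 6),)):
        lats = np.arange(grid.lat0, grid.lat_max + 1e-9, 0.1)
        lons = np.arange(grid.lon0, grid.lon_max + 1e-9, 1.0 / 6.0)
        LA, LO = np.meshgrid(lats, lons, indexing="ij")
        vals = np.stack([values_fn(LA, LO) for _ in months])
        return make_covariate_field(vals, lats, lons, list(months))

    def test_constant_field(self, small_grid, sample_factory):
        rng = np.random.default_rng(1)
        df = sample_factory(20, small_grid, (2000, 2000), rng).drop(
            columns="thermocline_depth_m")
        df["day_of_year"] = 160    # June
        field = self._field(small_grid, lambda la, lo: np.full_like(la, 20.0))
        out = attach_thermocline(df, field)
        np.testing.assert_allclose(out["thermocline_depth_m"], 20.0)

    def test_masked_cell_gives_missing_not_zero(self, small_grid, sample_factory):
        rng = np.random.default_rng(2)
        df = sample_factory(5, small_grid, (2000, 2000), rng)
        df["day_of_year"] = 160
        field = self._field(small_grid, lambda la, lo: np.full_like(la, np.nan))
        out = attach_thermocline(df, field)
        assert out["thermocline_depth_m"].isna().all()

    def test_nearest_node_close_to_linear_gradient(self, small_grid, sample_factory):
        rng = np.random.default_rng(3)
        df = sample_factory(50, small_grid, (2000, 2000), rng)
        df["day_of_year"] = 160
        slope = 10.0          # metres per degree latitude
        field = self._field(small_grid, lambda la, lo: 15.0 + slope * (la - 53.0))
        out = attach_thermocline(df, field)
        exact = 15.0 + slope * (out["lat"] - 53.0)
        # nearest node in a 0.1 deg grid: error at most one grid-step of gradient
        assert (np.abs(out["thermocline_depth_m"] - exact) <= slope * 0.1 + 1e-9).all()

    def test_missing_year_raises(self, small_grid, sample_factory):
        rng = np.random.default_rng(4)
        df = sample_factory(5, small_grid, (2001, 2001), rng)
        field = self._field(small_grid, lambda la, lo: np.full_like(la, 20.0))
        with pytest.raises(ValueError, match="2001"):
            attach_thermocline(df, field)


def test_field_netcdf_round_trip(small_grid, tmp_path):
    lats = np.arange(small_grid.lat0, small_grid.lat_max, 0.1)
    lons = np.arange(small_grid.lon0, small_grid.lon_max, 1 / 6)
    vals = np.random.default_rng(0).uniform(5, 80, (2, len(lats), len(lons)))
    fld = make_covariate_field(vals, lats, lons, [(2000, 1), (2000, 2)])
    path = tmp_path / "thc.nc"
    write_field(fld, path)
    back = read_field(path)
    np.testing.assert_allclose(back.values, vals, rtol=1e-12)
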