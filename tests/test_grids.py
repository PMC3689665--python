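import json
import math

import numpy as np
import pytest
from shapely.geometry import box

from phyloconserve.grids import (
    CellLayer,
    EARTH_RADIUS,
    behrmann_forward,
    behrmann_inverse,
    cell_size_from_degrees,
    layer_correlation,
    make_grid,
    mean_metric_layer,
    rasterize_ranges,
    read_ranges_csv,
    read_ranges_geojson,
    richness_layer,
    write_ascii_grid,
    write_layer_csv,
    write_ranges_csv,
    GridSpec,
)


class TestProjection:
    def test_forward_inverse_roundtrip(self, rng):
        lon = rng.uniform(-180, 180, 100)
        lat = rng.uniform(-89, 89, 100)
        x, y = behrmann_forward(lon, lat)
        lon2, lat2 = behrmann_inverse(x, y)
        assert np.allclose(lon, lon2, atol=1e-9)
        assert np.allclose(lat, lat2, atol=1e-9)

    def test_equal_area_property(self):
        # projected area of a lon/lat quad is proportional to its
        # spherical area: d(area) = R^2 dlon dsin(lat), independent of
        # the band's latitude
        def projected_area(lon0, lon1, lat0, lat1):
            x0, y0 = behrmann_forward(lon0, lat0)
            x1, y1 = behrmann_forward(lon1, lat1)
            return (x1 - x0) * (y1 - y0)

        a_eq = projected_area(0, 1, 0, 1)
        # same spherical area placed at 60N: dsin must match
        lat0 = 60.0
        lat1 = math.degrees(
            math.asin(math.sin(math.radians(61)) )
        )
        s0, s1 = math.sin(math.radians(0)), math.sin(math.radians(1))
        t0 = math.sin(math.radians(60))
        lat_hi = math.degrees(math.asin(t0 + (s1 - s0)))
        a_60 = projected_area(0, 1, lat0, lat_hi)
        assert a_60 == pytest.approx(a_eq, rel=1e-9)

    def test_cell_size_quarter_degree(self):
        # ~27.75-27.8 km of equatorial arc
        assert cell_size_from_degrees(0.25) == pytest.approx(
            EARTH_RADIUS * math.radians(0.25)
        )
        assert 27_500 < cell_size_from_degrees(0.25) < 28_100


class TestMakeGrid:
    def test_ten_degrees_gives_40_columns(self):
        grid = make_grid((0.0, 0.0, 10.0, 1.0), cell_size_deg=0.25)
        # Behrmann compresses longitude by cos(30 deg): 10 deg of
        # longitude = 10 cos(30) deg of equatorial arc = 34.64 cells
        assert grid.n_cols == math.ceil(10 * math.cos(math.radians(30)) / 0.25)

    def test_pure_equatorial_extent_40_cells(self):
        # a 10-degree stretch of equatorial arc is exactly 40 cells wide:
        # measure in projected x at the equator
        cell = cell_size_from_degrees(0.25)
        x0, _ = behrmann_forward(0.0, 0.0)
        x1 = float(x0) + 40 * cell
        lon1, _ = behrmann_inverse(x1, 0.0)
        grid = make_grid((0.0, 0.0, float(lon1), 1.0), cell_size_deg=0.25)
        assert grid.n_cols == 40

    def test_invalid_extent(self):
        with pytest.raises(ValueError, match="inverted"):
            make_grid((10, 0, 5, 1))

    def test_invalid_cell_size(self):
        with pytest.raises(ValueError):
            make_grid((0, 0, 1, 1), cell_size_deg=0.0)
        with pytest.raises(ValueError, match="cell_size"):
            GridSpec(0, 0, -1.0, 2, 2)

    def test_tiling_covers_extent(self):
        extent = (-10.0, -5.0, 23.0, 17.0)
        grid = make_grid(extent, 0.25)
        x0, y0 = behrmann_forward(extent[0], extent[1])
        x1, y1 = behrmann_forward(extent[2], extent[3])
        width = grid.n_cols * grid.cell_size
        height = grid.n_rows * grid.cell_size
        assert width >= float(x1) - float(x0)
        assert height >= float(y1) - float(y0)
        assert width - grid.cell_size < float(x1) - float(x0) + 1e-6
        assert height - grid.cell_size < float(y1) - float(y0) + 1e-6


class TestRasterize:
    def test_rectangle_covering_2x3_centers(self):
        grid = make_grid((0.0, 0.0, 3.0, 3.0), 0.25)
        # rectangle spanning exactly the centers of rows 1-2, cols 2-4
        x_lo, y_lo = grid.cell_center(1, 2)
        x_hi, y_hi = grid.cell_center(2, 4)
        eps = grid.cell_size * 0.01
        lon_lo, lat_lo = behrmann_inverse(x_lo - eps, y_lo - eps)
        lon_hi, lat_hi = behrmann_inverse(x_hi + eps, y_hi + eps)
        occ = rasterize_ranges(
            {"sp": [(float(lon_lo), float(lat_lo), float(lon_hi), float(lat_hi))]},
            grid,
        )
        assert occ.cells_of("sp") == {
            (r, c) for r in (1, 2) for c in (2, 3, 4)
        }

    def test_empty_range_set(self):
        grid = make_grid((0, 0, 2, 2), 0.25)
        occ = rasterize_ranges({"sp": []}, grid)
        assert occ.cells_of("sp") == set()

    def test_identical_ranges_identical_cells(self):
        grid = make_grid((0, 0, 5, 5), 0.25)
        rect = (1.0, 1.0, 3.0, 2.0)
        occ = rasterize_ranges({"a": [rect], "b": [rect]}, grid)
        assert occ.cells_of("a") == occ.cells_of("b") != set()

    def test_polygon_agrees_with_rectangle(self):
        grid = make_grid((0, 0, 5, 5), 0.5)
        rect = (0.7, 1.1, 3.3, 2.9)
        occ_rect = rasterize_ranges({"sp": [rect]}, grid)
        occ_poly = rasterize_ranges({"sp": [box(*rect)]}, grid)
        assert occ_rect.cells_of("sp") == occ_poly.cells_of("sp")

    def test_monotone_under_enlargement(self, rng):
        grid = make_grid((-10, -10, 10, 10), 0.5)
        for _ in range(20):
            lon0, lat0 = rng.uniform(-9, 5, 2)
            w, h = rng.uniform(0.5, 3, 2)
            small = (lon0, lat0, lon0 + w, lat0 + h)
            big = (lon0 - 1, lat0 - 1, lon0 + w + 1, lat0 + h + 1)
            cells_small = rasterize_ranges({"s": [small]}, grid).cells_of("s")
            cells_big = rasterize_ranges({"s": [big]}, grid).cells_of("s")
            assert cells_small <= cells_big

    def test_invalid_rectangle_named(self):
        grid = make_grid((0, 0, 2, 2), 0.25)
        with pytest.raises(ValueError, match="spX"):
            rasterize_ranges({"spX": [(3.0, 1.0, 1.0, 2.0)]}, grid)


class TestLayers:
    @pytest.fixture
    def occ(self):
        grid = make_grid((0, 0, 5, 5), 1.0)
        occ = rasterize_ranges(
            {
                "A": [(0.0, 0.0, 5.0, 5.0)],
                "B": [(0.0, 0.0, 3.0, 3.0)],
                "C": [(0.0, 0.0, 3.0, 1.5)],
            },
            grid,
        )
        return occ

    def test_richness_counts(self, occ):
        layer = richness_layer(occ)
        assert max(layer.values.values()) == 3.0
        # double-counting identity
        total = sum(layer.values.values())
        per_species = sum(len(occ.cells_of(s)) for s in ("A", "B", "C"))
        assert total == per_species

    def test_unoccupied_cells_missing(self):
        grid = make_grid((0, 0, 4, 4), 1.0)
        occ = rasterize_ranges({"A": []}, grid)
        assert richness_layer(occ).values == {}

    def test_mean_metric(self, occ):
        layer = mean_metric_layer(occ, {"A": 2.0, "B": 4.0, "C": 6.0})
        three_way = [rc for rc, s in occ.cells.items() if len(s) == 3]
        assert layer.values[three_way[0]] == pytest.approx(4.0)
        only_a = [rc for rc, s in occ.cells.items() if s == {"A"}]
        assert layer.values[only_a[0]] == 2.0

    def test_mean_metric_missing_species_error(self, occ):
        with pytest.raises(KeyError, match="C"):
            mean_metric_layer(occ, {"A": 1.0, "B": 2.0})

    def test_constant_metric_constant_layer(self, occ):
        layer = mean_metric_layer(occ, {"A": 1.0, "B": 1.0, "C": 1.0})
        rich = richness_layer(occ)
        assert set(layer.values) == set(rich.values)
        assert all(v == 1.0 for v in layer.values.values())


class TestLayerCorrelation:
    def _layer(self, grid, data):
        return CellLayer(grid, data)

    def test_identity(self):
        grid = GridSpec(0, 0, 1000.0, 10, 10)
        vals = {(r, c): float(r * 10 + c + 1) for r in range(5) for c in range(5)}
        a = self._layer(grid, vals)
        r, p, n = layer_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert n == 25

    def test_antisymmetry(self):
        grid = GridSpec(0, 0, 1000.0, 10, 10)
        vals = {(r, c): float(r + c) for r in range(5) for c in range(5)}
        neg = {k: -v + 7.0 for k, v in vals.items()}
        r, _, _ = layer_correlation(self._layer(grid, vals), self._layer(grid, neg))
        assert r == pytest.approx(-1.0)

    def test_planted_correlation(self, rng):
        grid = GridSpec(0, 0, 1000.0, 50, 50)
        rho = 0.5
        cells = [(r, c) for r in range(50) for c in range(40)]
        z1 = rng.standard_normal(len(cells))
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(len(cells))
        a = self._layer(grid, dict(zip(cells, z1)))
        b = self._layer(grid, dict(zip(cells, z2)))
        r, p, n = layer_correlation(a, b)
        assert n == 2000
        assert r == pytest.approx(0.5, abs=0.05)
        assert p < 1e-10

    def test_min_richness_filter(self):
        grid = GridSpec(0, 0, 1000.0, 4, 4)
        cells = [(0, 0), (0, 1), (0, 2), (0, 3), (1, 0)]
        a = self._layer(grid, {c: float(i) for i, c in enumerate(cells)})
        b = self._layer(grid, {c: float(i**2) for i, c in enumerate(cells)})
        rich = self._layer(grid, {c: (3.0 if c[0] == 0 else 1.0) for c in cells})
        _, _, n = layer_correlation(a, b, min_richness=2, richness=rich)
        assert n == 4

    def test_too_few_cells(self):
        grid = GridSpec(0, 0, 1000.0, 4, 4)
        a = self._layer(grid, {(0, 0): 1.0, (0, 1): 2.0})
        with pytest.raises(ValueError, match="shared cells"):
            layer_correlation(a, a)

    def test_zero_variance(self):
        grid = GridSpec(0, 0, 1000.0, 4, 4)
        flat = self._layer(grid, {(0, c): 1.0 for c in range(4)})
        vary = self._layer(grid, {(0, c): float(c) for c in range(4)})
        with pytest.raises(ValueError, match="variance"):
            layer_correlation(flat, vary)

    def test_grid_mismatch(self):
        a = self._layer(GridSpec(0, 0, 1000.0, 4, 4), {(0, 0): 1.0})
        b = self._layer(GridSpec(0, 0, 2000.0, 4, 4), {(0, 0): 1.0})
        with pytest.raises(ValueError, match="different grids"):
            layer_correlation(a, b)


class TestIO:
    def test_ranges_csv_roundtrip(self, tmp_path):
        ranges = {"sp1": [(-10.0, 0.0, 10.0, 5.0)], "sp2": [(100.0, -3.0, 120.0, 2.0)]}
        path = tmp_path / "r.csv"
        write_ranges_csv(ranges, path)
        back = read_ranges_csv(path)
        assert back == ranges

    def test_antimeridian_rectangle_split(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "species,min_lon,min_lat,max_lon,max_lat\nsp,170,-5,-170,5\n"
        )
        back = read_ranges_csv(path)
        assert back["sp"] == [(170.0, -5.0, 180.0, 5.0), (-180.0, -5.0, -170.0, 5.0)]

    def test_out_of_range_coordinates(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "species,min_lon,min_lat,max_lon,max_lat\nsp,0,-95,10,5\n"
        )
        with pytest.raises(ValueError, match="latitude"):
            read_ranges_csv(path)

    def test_geojson_reader(self, tmp_path):
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"species": "sp1"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[0, 0], [4, 0], [4, 3], [0, 3], [0, 0]]
                        ],
                    },
                }
            ],
        }
        path = tmp_path / "r.geojson"
        path.write_text(json.dumps(gj))
        ranges = read_ranges_geojson(path)
        assert list(ranges) == ["sp1"]
        assert ranges["sp1"][0].bounds == (0.0, 0.0, 4.0, 3.0)

    def test_ascii_grid_format(self, tmp_path):
        grid = GridSpec(0.0, 0.0, 100.0, 2, 3)
        layer = CellLayer(grid, {(0, 0): 1.5, (1, 2): 2.0})
        path = tmp_path / "layer.asc"
        write_ascii_grid(layer, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "ncols 3"
        assert lines[1] == "nrows 2"
        assert lines[5].startswith("NODATA_value")
        # north-to-south: first data row is grid row 1
        assert lines[6].split() == ["-9999", "-9999", "2"]
        assert lines[7].split() == ["1.5", "-9999", "-9999"]

    def test_layer_csv(self, tmp_path):
        grid = GridSpec(0.0, 0.0, 100.0, 2, 2)
        layer = CellLayer(grid, {(1, 0): 3.25})
        path = tmp_path / "layer.csv"
        write_layer_csv(layer, path)
        assert path.read_text() == "row,col,value\n1,0,3.25\n"
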