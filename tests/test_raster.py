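"""Raster I/O, friction surfaces and 16-direction cost accumulation."""

import math

import numpy as np
import pandas as pd
import pytest

from cropspread.raster import (
    NODATA,
    ClassRaster,
    GridTransform,
    RasterFormatError,
    accumulate_cost,
    load_class_raster,
    lonlat_to_xy,
    sample_surface,
    write_class_raster,
    xy_to_lonlat,
)
from cropspread.reference import reference_distances


def _uniform_raster(n_rows=7, n_cols=7, cell_size=1.0, n_classes=1):
    classes = np.zeros((n_rows, n_cols), dtype=np.int32)
    tr = GridTransform(0.0, 0.0, cell_size, n_rows, n_cols)
    return ClassRaster(classes=classes, transform=tr,
                       legend=[f"c{k}" for k in range(n_classes)],
                       raw_ids=list(range(n_classes)))


def _random_raster(rng, max_side=10, max_classes=5, p_nodata=0.0):
    n_rows = int(rng.integers(2, max_side + 1))
    n_cols = int(rng.integers(2, max_side + 1))
    k = int(rng.integers(1, max_classes + 1))
    classes = rng.integers(0, k, size=(n_rows, n_cols)).astype(np.int32)
    if p_nodata > 0:
        classes[rng.random((n_rows, n_cols)) < p_nodata] = NODATA
    tr = GridTransform(0.0, 0.0, float(rng.uniform(0.5, 30.0)), n_rows, n_cols)
    return ClassRaster(classes=classes, transform=tr,
                       legend=[f"c{i}" for i in range(k)], raw_ids=list(range(k)))


def _random_origin(rng, raster):
    valid = np.argwhere(raster.classes != NODATA)
    return tuple(valid[rng.integers(len(valid))])


class TestAsciiIO:
    def test_write_load_round_trip(self, tmp_path, small_world):
        raster, _ = small_world
        write_class_raster(tmp_path / "r.asc", raster, legend_path=tmp_path / "l.csv")
        loaded = load_class_raster(tmp_path / "r.asc", legend_path=tmp_path / "l.csv")
        np.testing.assert_array_equal(loaded.classes, raster.classes)
        assert loaded.legend == raster.legend
        assert loaded.cell_size == raster.cell_size

    def test_single_class_raster(self, tmp_path):
        write_class_raster(tmp_path / "r.asc", _uniform_raster())
        loaded = load_class_raster(tmp_path / "r.asc")
        assert loaded.n_classes == 1

    def test_id_absent_from_legend_rejected(self, tmp_path):
        write_class_raster(tmp_path / "r.asc", _uniform_raster())
        pd.DataFrame({"class_id": [99], "label": ["other"]}).to_csv(
            tmp_path / "l.csv", index=False)
        with pytest.raises(RasterFormatError, match="absent from legend"):
            load_class_raster(tmp_path / "r.asc", legend_path=tmp_path / "l.csv")

    def test_non_integer_cells_rejected(self, tmp_path):
        path = tmp_path / "r.asc"
        path.write_text("ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
                        "NODATA_value -1\n0.5 1\n")
        with pytest.raises(RasterFormatError, match="integer"):
            load_class_raster(path)

    def test_truncated_grid_rejected(self, tmp_path):
        path = tmp_path / "r.asc"
        path.write_text("ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
                        "NODATA_value -1\n0 1 0\n")
        with pytest.raises(RasterFormatError, match="expected 6 cells"):
            load_class_raster(path)


class TestAccumulateCost:
    @pytest.mark.parametrize(
        "target,expected",
        [((3, 4), 1.0), ((4, 4), math.sqrt(2.0)), ((2, 5), math.sqrt(5.0))],
        ids=["orthogonal", "diagonal", "knight"],
    )
    def test_single_edge_geometry(self, target, expected):
        raster = _uniform_raster(7, 7, cell_size=1.0)
        surface = accumulate_cost(raster, np.array([1.0]), (3, 3))
        assert surface.dist[target] == pytest.approx(expected, rel=1e-12)

    def test_origin_distance_is_zero(self):
        raster = _uniform_raster()
        surface = accumulate_cost(raster, np.array([1.0]), (2, 2))
        assert surface.dist[2, 2] == 0.0

    def test_half_cost_halves_distance(self):
        raster = _uniform_raster(6, 9, cell_size=2.0)
        d1 = accumulate_cost(raster, np.array([1.0]), (3, 1)).dist
        d05 = accumulate_cost(raster, np.array([0.5]), (3, 1)).dist
        np.testing.assert_allclose(d05, 0.5 * d1, rtol=1e-12)

    def test_homogeneity_in_costs(self):
        rng = np.random.default_rng(11)
        raster = _random_raster(rng)
        costs = rng.uniform(0.1, 4.0, raster.n_classes)
        origin = _random_origin(rng, raster)
        d = accumulate_cost(raster, costs, origin).dist
        d3 = accumulate_cost(raster, 3.0 * costs, origin).dist
        np.testing.assert_allclose(d3, 3.0 * d, rtol=1e-12)

    def test_raising_one_class_cost_never_decreases_distance(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            raster = _random_raster(rng)
            costs = rng.uniform(0.1, 3.0, raster.n_classes)
            origin = _random_origin(rng, raster)
            d = accumulate_cost(raster, costs, origin).dist
            bumped = costs.copy()
            bumped[rng.integers(raster.n_classes)] += rng.uniform(0.1, 2.0)
            d2 = accumulate_cost(raster, bumped, origin).dist
            assert np.all(d2 >= d - 1e-9)

    def test_knight_moves_never_lengthen_paths(self):
        """16-direction distances are <= 8-direction distances."""
        import networkx as nx

        rng = np.random.default_rng(17)
        for _ in range(5):
            raster = _random_raster(rng, max_side=8)
            costs = rng.uniform(0.1, 3.0, raster.n_classes)
            origin = _random_origin(rng, raster)
            d16 = accumulate_cost(raster, costs, origin).dist
            # 8-neighbour graph built explicitly
            g = nx.Graph()
            moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                     if (dr, dc) != (0, 0)]
            for r in range(raster.n_rows):
                for c in range(raster.n_cols):
                    for dr, dc in moves:
                        r2, c2 = r + dr, c + dc
                        if 0 <= r2 < raster.n_rows and 0 <= c2 < raster.n_cols:
                            w = (math.hypot(dr, dc) * raster.cell_size *
                                 (costs[raster.classes[r, c]]
                                  + costs[raster.classes[r2, c2]]) / 2)
                            g.add_edge((r, c), (r2, c2), weight=w)
            d8 = nx.single_source_dijkstra_path_length(g, origin)
            for (r, c), dist8 in d8.items():
                assert d16[r, c] <= dist8 + 1e-9

    def test_matches_reference_with_nodata_holes(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            raster = _random_raster(rng, p_nodata=0.2)
            costs = rng.uniform(0.05, 5.0, raster.n_classes)
            origin = _random_origin(rng, raster)
            d = accumulate_cost(raster, costs, origin).dist
            ref = reference_distances(raster, costs, origin)
            np.testing.assert_allclose(d, ref, rtol=1e-9)

    def test_origin_on_nodata_rejected(self):
        raster = _uniform_raster()
        raster.classes[0, 0] = NODATA
        with pytest.raises(ValueError, match="nodata"):
            accumulate_cost(raster, np.array([1.0]), (0, 0))

    def test_cost_below_floor_rejected(self):
        raster = _uniform_raster()
        with pytest.raises(ValueError, match="costs"):
            accumulate_cost(raster, np.array([0.001]), (2, 2))


class TestSampleSurface:
    def _surface(self, cost=2.0):
        raster = _uniform_raster(5, 9, cell_size=1.0)
        return accumulate_cost(raster, np.array([cost]), (2, 0))

    def test_site_at_origin_center_has_zero_distance(self):
        surface = self._surface()
        sites = pd.DataFrame({"x": [0.5], "y": [2.5]})
        out = sample_surface(surface, sites)
        assert out.loc[0, "D_km"] == 0.0

    def test_three_orthogonal_cells_uniform_cost_two(self):
        surface = self._surface(cost=2.0)
        sites = pd.DataFrame({"x": [3.5], "y": [2.5]})
        out = sample_surface(surface, sites)
        assert out.loc[0, "D_km"] == pytest.approx(6.0, rel=1e-12)

    def test_same_cell_same_distance(self):
        surface = self._surface()
        sites = pd.DataFrame({"x": [4.2, 4.8], "y": [1.3, 1.7]})
        out = sample_surface(surface, sites)
        assert out.loc[0, "D_km"] == out.loc[1, "D_km"]

    def test_outside_extent_flagged_not_fatal(self):
        surface = self._surface()
        sites = pd.DataFrame({"x": [50.0, 0.5], "y": [2.5, 2.5]})
        out = sample_surface(surface, sites)
        assert out.loc[0, "D_status"] == "outside_extent"
        assert np.isnan(out.loc[0, "D_km"])
        assert out.loc[1, "D_status"] == "ok"


def test_equirectangular_round_trip():
    lon = np.array([40.0, 75.0])
    lat = np.array([35.0, 15.0])
    x, y = lonlat_to_xy(lon, lat, lon0=38.0, lat0=30.0)
    lon2, lat2 = xy_to_lonlat(x, y, lon0=38.0, lat0=30.0)
    np.testing.assert_allclose(lon2, lon, rtol=1e-12)
    np.testing.assert_allclose(lat2, lat, rtol=1e-12)
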