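import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from soundlur import features as feat
from soundlur._grid import RasterGrid


from _oracles import (  # noqa: E402  (oracles live beside the tests)
    oracle_distance,
    oracle_line_length,
    oracle_point_count,
    oracle_raster_mean,
)


class TestLineLength:
    def test_half_segment_inside(self):
        line = LineString([(0, 0), (1000, 0)])
        got = feat.line_length_in_buffer([line], (0, 0), 500)
        assert got == pytest.approx(500.0, rel=1e-4)

    def test_no_lines_zero(self):
        far = LineString([(5000, 5000), (6000, 5000)])
        assert feat.line_length_in_buffer([far], (0, 0), 500) == 0.0
        assert feat.line_length_in_buffer([], (0, 0), 500) == 0.0

    def test_nonpositive_radius_raises(self):
        with pytest.raises(ValueError):
            feat.line_length_in_buffer([], (0, 0), 0)

    def test_random_segments_match_sampling_oracle(self, rng):
        for _ in range(20):
            center = tuple(rng.uniform(0, 1000, 2))
            radius = rng.choice([50, 100, 200, 500])
            lines = [
                LineString(rng.uniform(-200, 1200, (2, 2))) for _ in range(3)
            ]
            got = feat.line_length_in_buffer(lines, center, radius)
            want = oracle_line_length(lines, center, radius)
            assert got == pytest.approx(want, rel=5e-3, abs=0.5)


class TestPointCount:
    def test_boundary_inclusive(self):
        pts = [Point(499.9, 0), Point(500.1, 0)]
        assert feat.point_count_in_buffer(pts, (0, 0), 500) == 1
        assert feat.point_count_in_buffer([Point(0, 500)], (0, 0), 500) == 1

    def test_center_counted(self):
        assert feat.point_count_in_buffer([Point(10, 10)], (10, 10), 50) == 1

    def test_random_points_match_exhaustive(self, rng):
        pts = [Point(x, y) for x, y in rng.uniform(0, 1000, (1000, 2))]
        for _ in range(10):
            center = tuple(rng.uniform(0, 1000, 2))
            r = rng.choice([50, 100, 200, 500])
            assert feat.point_count_in_buffer(pts, center, r) == oracle_point_count(
                pts, center, r
            )


class TestRasterMean:
    def test_constant_grid(self):
        grid = RasterGrid(np.full((20, 20), 0.2), 0, 0, 50)
        assert feat.raster_mean_in_buffer(grid, (500, 500), 200) == pytest.approx(0.2)

    def test_tiny_radius_on_cell_center_picks_that_cell(self):
        vals = np.arange(400.0).reshape(20, 20)
        grid = RasterGrid(vals, 0, 0, 50)
        # center of cell (3, 4) is (225, 175); radius below half cell pitch
        got = feat.raster_mean_in_buffer(grid, (225.0, 175.0), 20)
        assert got == vals[3, 4]

    def test_empty_disk_flagged(self):
        grid = RasterGrid(np.zeros((4, 4)), 0, 0, 50)
        with pytest.raises(feat.EmptyBufferError):
            feat.raster_mean_in_buffer(grid, (-500.0, -500.0), 50)

    def test_checkerboard_matches_enumeration(self, rng):
        vals = np.indices((40, 40)).sum(axis=0) % 2
        grid = RasterGrid(vals.astype(float), 0, 0, 50)
        for _ in range(10):
            center = tuple(rng.uniform(200, 1800, 2))
            r = rng.choice([100, 200, 500])
            got = feat.raster_mean_in_buffer(grid, center, r)
            assert got == pytest.approx(oracle_raster_mean(grid, center, r), abs=1e-12)


class TestLandcoverComposition:
    def test_uniform_disk(self):
        grid = RasterGrid(
            np.full((20, 20), 2, dtype=int), 0, 0, 50, ("a", "b", "cbi", "d")
        )
        shares = feat.landcover_composition_in_buffer(grid, (500, 500), 200)
        assert shares["cbi"] == 1.0
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_half_half_stripe(self):
        vals = np.zeros((40, 40), dtype=int)
        vals[:, 20:] = 3  # vertical split exactly through x=1000
        grid = RasterGrid(vals, 0, 0, 50, ("formal_residential", "b", "c", "other"))
        shares = feat.landcover_composition_in_buffer(grid, (1000.0, 1000.0), 500)
        enum = {}
        for cls_code, cls in enumerate(grid.classes):
            n = 0
            tot = 0
            for i in range(40):
                for j in range(40):
                    x, y = grid.center_of(i, j)
                    if (x - 1000) ** 2 + (y - 1000) ** 2 <= 500**2:
                        tot += 1
                        n += int(vals[i, j] == cls_code)
            enum[cls] = n / tot
        for cls in grid.classes:
            assert shares[cls] == pytest.approx(enum[cls], abs=1e-12)
        assert shares["formal_residential"] == pytest.approx(0.5, abs=0.05)

    def test_shares_sum_to_one(self, small_rasters, rng):
        for _ in range(10):
            center = tuple(rng.uniform(100, 1900, 2))
            shares = feat.landcover_composition_in_buffer(
                small_rasters.land_cover, center, 200
            )
            assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)


class TestDistanceToMajorRoad:
    def test_perpendicular_distance(self):
        road = LineString([(-1e4, 0), (1e4, 0)])
        assert feat.distance_to_nearest_major_road((0, 100), [road]) == pytest.approx(100.0)

    def test_on_road_zero(self):
        road = LineString([(0, 0), (100, 0)])
        assert feat.distance_to_nearest_major_road((50, 0), [road]) == 0.0

    def test_no_major_roads_raises(self):
        with pytest.raises(ValueError):
            feat.distance_to_nearest_major_road((0, 0), [])

    def test_random_sites_match_densified_oracle(self, rng):
        lines = [LineString(rng.uniform(0, 2000, (3, 2))) for _ in range(4)]
        for _ in range(10):
            center = tuple(rng.uniform(0, 2000, 2))
            got = feat.distance_to_nearest_major_road(center, lines)
            assert got == pytest.approx(oracle_distance(center, lines), abs=0.5)


class TestBuildFeatureMatrix:
    def test_column_arithmetic(self, small_rasters, small_vectors):
        specs = [
            feat.PredictorSpec("road_major_len", "roads", "length_sum", "major", (50, 100, 200, 500)),
            feat.PredictorSpec("ndvi_mean", "ndvi", "raster_mean", None, (50, 100, 200, 500)),
            feat.PredictorSpec("dist_major_road", "roads", "distance_nearest", "major"),
        ]
        targets = pd.DataFrame({"site_id": ["a", "b"], "x": [500.0, 900.0], "y": [500.0, 1100.0]})
        m = feat.build_feature_matrix(targets, small_rasters, small_vectors, specs)
        assert m.shape == (2, 9)
        assert list(m.columns)[:4] == [f"road_major_len@{r}" for r in (50, 100, 200, 500)]

    def test_empty_buffer_count_is_zero(self, small_rasters, small_vectors):
        specs = [feat.PredictorSpec("bus_station_n", "pois", "count", "bus_station", (50,))]
        targets = pd.DataFrame({"site_id": ["far"], "x": [25.0], "y": [25.0]})
        m = feat.build_feature_matrix(targets, small_rasters, small_vectors, specs)
        assert m.iloc[0, 0] >= 0  # defined, not NaN

    def test_matrix_matches_per_op_calls(self, small_rasters, small_vectors, rng):
        targets = pd.DataFrame(
            {
                "site_id": [f"s{k}" for k in range(5)],
                "x": rng.uniform(300, 1700, 5),
                "y": rng.uniform(300, 1700, 5),
            }
        )
        m = feat.build_feature_matrix(targets, small_rasters, small_vectors)
        major = small_vectors.roads_by_class("major")
        for _, row in targets.iterrows():
            center = (row["x"], row["y"])
            sid = row["site_id"]
            assert m.loc[sid, "road_major_len@200"] == pytest.approx(
                feat.line_length_in_buffer(major, center, 200), rel=1e-9
            )
            assert m.loc[sid, "ndvi_mean@100"] == pytest.approx(
                feat.raster_mean_in_buffer(small_rasters.ndvi, center, 100)
            )
            assert m.loc[sid, "dist_major_road"] == pytest.approx(
                feat.distance_to_nearest_major_road(center, major), abs=1e-9
            )
            assert m.loc[sid, "bus_station_n@500"] == feat.point_count_in_buffer(
                small_vectors.pois_by_kind("bus_station"), center, 500
            )

    def test_missing_layer_named_in_error(self, small_rasters, small_vectors):
        specs = [feat.PredictorSpec("x", "nope", "raster_mean", None, (50,))]
        targets = pd.DataFrame({"site_id": ["a"], "x": [500.0], "y": [500.0]})
        with pytest.raises(KeyError, match="nope"):
            feat.build_feature_matrix(targets, small_rasters, small_vectors, specs)

    def test_site_equals_cell_center_features(self, small_rasters, small_vectors):
        # a site placed exactly on a grid-cell center gets identical features
        center = small_rasters.ndvi.center_of(10, 14)
        t1 = pd.DataFrame({"site_id": ["s"], "x": [center[0]], "y": [center[1]]})
        t2 = pd.DataFrame({"cell_id": [0], "x": [center[0]], "y": [center[1]]})
        m1 = feat.build_feature_matrix(t1, small_rasters, small_vectors)
        m2 = feat.build_feature_matrix(
            t2, small_rasters, small_vectors, id_column="cell_id"
        )
        np.testing.assert_array_equal(m1.to_numpy(), m2.to_numpy())


class TestProperties:
    def test_monotonicity_in_radius(self, small_rasters, small_vectors, rng):
        lines = small_vectors.roads_by_class("all")
        pts = small_vectors.pois_by_kind("all")
        for _ in range(5):
            center = tuple(rng.uniform(0, 2000, 2))
            lengths = [
                feat.line_length_in_buffer(lines, center, r) for r in (50, 100, 200, 500)
            ]
            counts = [
                feat.point_count_in_buffer(pts, center, r) for r in (50, 100, 200, 500)
            ]
            assert lengths == sorted(lengths)
            assert counts == sorted(counts)

    def test_translation_invariance(self, rng):
        shift = np.array([123.4, -56.7])
        lines = [LineString(rng.uniform(0, 1000, (2, 2))) for _ in range(3)]
        pts = [Point(x, y) for x, y in rng.uniform(0, 1000, (50, 2))]
        center = (400.0, 600.0)
        moved_lines = [
            LineString(np.asarray(line.coords) + shift) for line in lines
        ]
        moved_pts = [Point(p.x + shift[0], p.y + shift[1]) for p in pts]
        moved_center = (center[0] + shift[0], center[1] + shift[1])
        assert feat.line_length_in_buffer(lines, center, 200) == pytest.approx(
            feat.line_length_in_buffer(moved_lines, moved_center, 200), rel=1e-9
        )
        assert feat.point_count_in_buffer(pts, center, 200) == feat.point_count_in_buffer(
            moved_pts, moved_center, 200
        )


def test_default_inventory_declares_periods():
    specs = feat.default_predictor_specs()
    names = {s.name for s in specs}
    assert {"road_major_len", "ndvi_mean", "pop_mean", "dist_major_road", "elevation"} <= names
    school = next(s for s in specs if s.name == "school_n")
    assert school.period == "day"
    assert all(s.period in ("day", "night", "both") for s in specs)


def test_spec_validation():
    with pytest.raises(ValueError):
        feat.PredictorSpec("bad", "roads", "length_sum", "major", (75,))
    with pytest.raises(ValueError):
        feat.PredictorSpec("bad", "roads", "distance_nearest", "major", (50,))
    with pytest.raises(ValueError):
        feat.PredictorSpec("bad", "ndvi", "raster_mean", None, ())
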