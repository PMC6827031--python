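import numpy as np
import pytest

from pikasdm import covariates as cov
from pikasdm.raster_core import GridSpec, Layer


def spec_of(n, cell=1.0):
    return GridSpec(0.0, n * cell, cell, n, n)


class TestSlopeAspect:
    def test_constant_dem_flat(self):
        spec = spec_of(5)
        slope, aspect = cov.slope_aspect(Layer("dem", "continuous", np.full((5, 5), 42.0)), spec)
        np.testing.assert_allclose(slope.values, 0.0)
        np.testing.assert_allclose(aspect.values, cov.FLAT_ASPECT)

    def test_unit_plane_gives_45_degrees(self):
        spec = spec_of(5)
        xs, _ = spec.cell_centers()
        slope, aspect = cov.slope_aspect(Layer("dem", "continuous", xs.copy()), spec)
        # z = x: gradient 1 eastward; interior slope atan(1) = 45 deg,
        # downhill azimuth west = 270 deg
        np.testing.assert_allclose(slope.values[1:-1, 1:-1], 45.0)
        np.testing.assert_allclose(aspect.values[1:-1, 1:-1], 270.0)

    def test_matches_brute_force_horn_kernel(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(5, 5)) * 3
        spec = spec_of(5, cell=2.0)
        slope, aspect = cov.slope_aspect(Layer("dem", "continuous", z), spec)
        zp = np.pad(z, 1, mode="edge")
        for r in range(5):
            for c in range(5):
                w = zp[r : r + 3, c : c + 3]
                dzdx = ((w[0, 2] + 2 * w[1, 2] + w[2, 2]) - (w[0, 0] + 2 * w[1, 0] + w[2, 0])) / (8 * 2.0)
                dzdy = ((w[0, 0] + 2 * w[0, 1] + w[0, 2]) - (w[2, 0] + 2 * w[2, 1] + w[2, 2])) / (8 * 2.0)
                exp_slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
                assert slope.values[r, c] == pytest.approx(exp_slope, abs=1e-12)
                exp_aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360
                assert aspect.values[r, c] == pytest.approx(exp_aspect, abs=1e-12)

    def test_too_small_grid_rejected(self):
        with pytest.raises(Exception, match="3x3"):
            cov.slope_aspect(Layer("dem", "continuous", np.zeros((2, 2))), spec_of(2))

    def test_derive_terrain_orders_agree_on_plane(self):
        # both derivation orders are exact on a plane, so they must agree
        fine = spec_of(12, cell=0.5)
        coarse = GridSpec(1.0, 5.0, 1.0, 4, 4)
        xs, ys = fine.cell_centers()
        dem = Layer("dem", "continuous", 0.2 * xs + 0.1 * ys)
        s1, a1 = cov.derive_terrain(dem, fine, coarse, "derive_then_resample")
        s2, a2 = cov.derive_terrain(dem, fine, coarse, "resample_then_derive")
        # interiors only: edge cells feel the replicate-padding differently
        np.testing.assert_allclose(s1.values[1:-1, 1:-1], s2.values[1:-1, 1:-1],
                                   atol=1e-9)
        np.testing.assert_allclose(a1.values[1:-1, 1:-1], a2.values[1:-1, 1:-1],
                                   atol=1e-9)
        expected = np.degrees(np.arctan(np.hypot(0.2, 0.1)))
        assert s2.values[1, 1] == pytest.approx(expected)


class TestTwi:
    def test_trough_accumulation_monotone_downstream(self):
        # single-cell-wide inclined trough along the middle column
        spec = spec_of(5)
        z = np.full((5, 5), 10.0)
        for r in range(5):
            z[r, 2] = 5.0 - r  # deepens southward
            z[r, 0] = z[r, 4] = 20.0
        twi = cov.twi(Layer("dem", "continuous", z), spec)
        trough = twi.values[:, 2]
        assert np.all(np.diff(trough) > 0)  # downstream cells accumulate more

    def test_ridge_cell_closed_form(self):
        # uniform plane: every interior cell receives nothing on the high edge
        spec = spec_of(4, cell=2.0)
        xs, _ = spec.cell_centers()
        dem = Layer("dem", "continuous", xs * 0.5)  # z = x/2
        twi = cov.twi(dem, spec)
        acc = cov.d8_flow_accumulation(dem, spec)
        slope, _ = cov.slope_aspect(dem, spec)
        r, c = 1, 3  # east (high) edge interior cell: no upstream cells
        assert acc[r, c] == 0
        expected = np.log((1 * 2.0) / np.tan(np.radians(slope.values[r, c])))
        assert twi.values[r, c] == pytest.approx(expected, rel=1e-12)

    def test_hand_traced_diagonal_plane(self):
        # z = r + c: interior cells flow to their NW diagonal neighbor
        # (drop 2/sqrt(2) beats the straight drops of 1); top-row cells flow
        # west and left-column cells flow north (their only descents), so
        # every path ends at the (0,0) corner.  Tracing each cell by hand:
        #   row 3 and column 3 are local ridges (nothing upstream);
        #   (2,2)<-{(3,3)}, (1,1)<-{(2,2)+}, (1,2)<-{(2,3)}, (0,2)<-{(0,3),(1,3)},
        #   (0,1)<-{(0,2)+,(1,2)+}, (1,0)/(2,0) mirror by symmetry,
        #   (0,0) drains all 15 remaining cells.
        spec = spec_of(4)
        z = np.add.outer(np.arange(4.0), np.arange(4.0))
        acc = cov.d8_flow_accumulation(Layer("dem", "continuous", z), spec)
        expected = np.array(
            [
                [15.0, 5.0, 2.0, 0.0],
                [5.0, 2.0, 1.0, 0.0],
                [2.0, 1.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        np.testing.assert_array_equal(acc, expected)
        twi = cov.twi(Layer("dem", "continuous", z), spec)
        slope, _ = cov.slope_aspect(Layer("dem", "continuous", z), spec)
        tan_b = np.maximum(np.tan(np.radians(slope.values)), 0.001)
        np.testing.assert_allclose(twi.values, np.log((expected + 1) * 1.0 / tan_b))

    def test_twi_monotone_in_accumulation_and_slope(self):
        # fixed slope, larger contributing area -> larger TWI; and vice versa
        a = np.array([1.0, 2.0, 5.0])
        tan_b = 0.1
        vals = np.log(a / tan_b)
        assert np.all(np.diff(vals) > 0)
        slopes = np.array([0.05, 0.1, 0.2])
        vals2 = np.log(2.0 / slopes)
        assert np.all(np.diff(vals2) < 0)


class TestDistance:
    def test_on_feature_center_zero(self):
        spec = spec_of(5)
        road = cov.VectorFeatureSet("polylines", [np.array([[0.0, 2.5], [5.0, 2.5]])], "road")
        d = cov.euclidean_distance(road, spec)
        np.testing.assert_allclose(d.values[2, :], 0.0, atol=1e-12)

    def test_point_feature_adjacent_and_diagonal(self):
        spec = spec_of(5)
        pt = cov.VectorFeatureSet("points", [np.array([[2.5, 2.5]])], "resident")
        d = cov.euclidean_distance(pt, spec)
        assert d.values[2, 2] == pytest.approx(0.0)
        assert d.values[2, 3] == pytest.approx(1.0)
        assert d.values[1, 3] == pytest.approx(np.sqrt(2))

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(2)
        spec = spec_of(20)
        verts = np.column_stack([rng.uniform(0, 20, 6), rng.uniform(0, 20, 6)])
        road = cov.VectorFeatureSet("polylines", [verts], "road")
        d = cov.euclidean_distance(road, spec)
        # dense sampling every 2e-3 units along each segment
        samples = []
        for p, q in zip(verts[:-1], verts[1:]):
            L = np.hypot(*(q - p))
            t = np.linspace(0, 1, max(int(L / 2e-3), 2))
            samples.append(p[None, :] + t[:, None] * (q - p)[None, :])
        samples = np.vstack(samples)
        xs, ys = spec.cell_centers()
        for r in range(0, 20, 3):
            for c in range(0, 20, 3):
                oracle = np.min(np.hypot(samples[:, 0] - xs[r, c], samples[:, 1] - ys[r, c]))
                if oracle >= 0.5:  # sampling error bound (step/2)^2 / (2 d) < 1e-6
                    assert abs(d.values[r, c] - oracle) < 1e-6

    def test_lipschitz_between_adjacent_centers(self):
        rng = np.random.default_rng(9)
        spec = spec_of(15)
        verts = np.column_stack([rng.uniform(0, 15, 5), rng.uniform(0, 15, 5)])
        d = cov.euclidean_distance(cov.VectorFeatureSet("polylines", [verts], "r"), spec).values
        assert np.max(np.abs(np.diff(d, axis=0))) <= spec.cell_size * np.sqrt(2) + 1e-12
        assert np.max(np.abs(np.diff(d, axis=1))) <= spec.cell_size * np.sqrt(2) + 1e-12

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cov.VectorFeatureSet("points", [], "none")

    def test_geojson_and_csv_round_trip(self, tmp_path):
        road = cov.VectorFeatureSet(
            "polylines",
            [np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 1.5]])],
            "road",
        )
        road.to_geojson(tmp_path / "road.geojson")
        back = cov.VectorFeatureSet.from_geojson(tmp_path / "road.geojson")
        np.testing.assert_allclose(back.coordinates[0], road.coordinates[0])
        (tmp_path / "road.csv").write_text(
            "feature_id,vertex_index,x,y\n1,0,0.0,1.0\n1,1,2.0,3.0\n1,2,4.0,1.5\n"
        )
        from_csv = cov.VectorFeatureSet.from_csv(tmp_path / "road.csv", "polylines")
        np.testing.assert_allclose(from_csv.coordinates[0], road.coordinates[0])


class TestBufferMask:
    def test_tiny_radius_hits_one_cell(self):
        spec = spec_of(5)
        pt = cov.VectorFeatureSet("points", [np.array([[2.5, 2.5]])], "resident")
        mask = cov.buffer_mask(pt, spec, radius=0.4)
        assert mask.values.sum() == 1 and mask.values[2, 2] == 1

    def test_huge_radius_covers_grid(self):
        spec = spec_of(5)
        pt = cov.VectorFeatureSet("points", [np.array([[2.5, 2.5]])], "resident")
        np.testing.assert_array_equal(cov.buffer_mask(pt, spec, 100.0).values, 1.0)

    def test_equals_thresholded_distance(self):
        spec = spec_of(20)
        road = cov.VectorFeatureSet("polylines", [np.array([[0.0, 10.0], [20.0, 10.0]])], "road")
        mask = cov.buffer_mask(road, spec, radius=10.0)
        d = cov.euclidean_distance(road, spec)
        np.testing.assert_array_equal(mask.values, (d.values <= 10.0).astype(float))


class TestTimeSeries:
    def _cube(self, series, spec=None):
        series = np.asarray(series, dtype=float)
        spec = spec or spec_of(2)
        vals = np.tile(series[:, None, None], (1, spec.n_rows, spec.n_cols))
        return cov.TimeSeriesCube(spec, np.arange(len(series)), vals)

    def test_polynomial_reproduced_exactly(self):
        t = np.arange(9, dtype=float)
        series = 2.0 - 1.5 * t + 0.3 * t**2
        out = cov.savitzky_golay(self._cube(series), window=5, order=2)
        np.testing.assert_allclose(out.values, self._cube(series).values, atol=1e-10)

    def test_constant_series_unchanged(self):
        out = cov.savitzky_golay(self._cube(np.full(7, 3.3)), window=5, order=2)
        np.testing.assert_allclose(out.values, 3.3)

    def test_noise_variance_reduced_about_truth(self):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 2 * np.pi, 46)
        truth = np.sin(t)
        noisy = truth + rng.normal(0, 0.3, size=t.size)
        out = cov.savitzky_golay(self._cube(noisy), window=7, order=2)
        resid_in = ((noisy - truth) ** 2).mean()
        resid_out = ((out.values[:, 0, 0] - truth) ** 2).mean()
        assert resid_out < resid_in

    def test_window_order_preconditions(self):
        cube = self._cube(np.arange(9.0))
        with pytest.raises(ValueError, match="odd"):
            cov.savitzky_golay(cube, window=4, order=2)
        with pytest.raises(ValueError, match="order"):
            cov.savitzky_golay(cube, window=5, order=5)

    def test_stats_arithmetic(self):
        cube = self._cube([2.0, 4.0, 6.0])
        mean, mx, mn, std = cov.series_stats(cube, basename="evi")
        assert mean.name == "evi_mean" and std.name == "evi_std"
        np.testing.assert_allclose(mean.values, 4.0)
        np.testing.assert_allclose(mx.values, 6.0)
        np.testing.assert_allclose(mn.values, 2.0)
        np.testing.assert_allclose(std.values, np.sqrt(8.0 / 3.0))  # population divisor

    def test_stats_constant_and_nodata(self):
        spec = spec_of(2)
        vals = np.tile(np.array([5.0, 5.0, 5.0])[:, None, None], (1, 2, 2))
        vals[:, 0, 0] = np.nan  # an all-nodata cell
        cube = cov.TimeSeriesCube(spec, np.arange(3), vals)
        mean, mx, mn, std = cov.series_stats(cube)
        assert std.values[1, 1] == 0.0
        assert all(np.isnan(l.values[0, 0]) for l in (mean, mx, mn, std))

    def test_stats_match_brute_force_loop(self):
        rng = np.random.default_rng(8)
        spec = spec_of(3)
        vals = rng.normal(size=(6, 3, 3))
        cube = cov.TimeSeriesCube(spec, np.arange(6), vals)
        mean, mx, mn, std = cov.series_stats(cube)
        for r in range(3):
            for c in range(3):
                s = vals[:, r, c]
                assert mean.values[r, c] == pytest.approx(s.mean())
                assert std.values[r, c] == pytest.approx(s.std(ddof=0))
                assert mn.values[r, c] <= mean.values[r, c] <= mx.values[r, c]
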