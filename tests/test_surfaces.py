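"""Surface models: lowest-point filtering, TIN rasterization, DSM/DTM/CHM."""

import numpy as np
import pytest

from grasshh.surfaces import (
    DegenerateGeometryError,
    GridGeometryError,
    PointCloud,
    RasterGrid,
    build_chm,
    build_dsm,
    build_dtm,
    filter_lowest_points,
    grid_for_bounds,
    tin_interpolate,
)
from grasshh.synthetic import SceneParams, sample_point_cloud


class TestFilterLowestPoints:
    def test_keeps_minimum_z_in_cell(self):
        cloud = PointCloud(np.array([[0.2, 0.2, 0.40], [0.3, 0.3, 0.10]]))
        out = filter_lowest_points(cloud, 0.5)
        assert len(out) == 1
        assert out.z[0] == 0.10

    def test_one_point_per_cell_is_identity(self):
        cloud = PointCloud(np.array([[0.2, 0.2, 1.0], [0.7, 0.2, 2.0], [0.2, 0.7, 3.0]]))
        out = filter_lowest_points(cloud, 0.5)
        np.testing.assert_array_equal(out.xyz, cloud.xyz)

    def test_matches_brute_force_per_cell_minimum(self, rng):
        """1000 uniform points: survivor set equals a per-cell min scan."""
        xyz = np.column_stack(
            [rng.uniform(0, 5, 1000), rng.uniform(0, 5, 1000), rng.uniform(0, 1, 1000)]
        )
        cloud = PointCloud(xyz)
        out = filter_lowest_points(cloud, 0.5)

        cells = {}
        for p in xyz:
            key = (int(np.floor(p[0] / 0.5)), int(np.floor(p[1] / 0.5)))
            if key not in cells or p[2] < cells[key][2]:
                cells[key] = p
        assert len(out) == len(cells)
        expected = np.array(sorted(map(tuple, cells.values())))
        got = np.array(sorted(map(tuple, out.xyz)))
        np.testing.assert_allclose(got, expected)

    def test_output_subset_of_input(self, rng):
        xyz = np.column_stack([rng.uniform(0, 3, 200)] * 2 + [rng.uniform(0, 1, 200)])
        cloud = PointCloud(xyz)
        out = filter_lowest_points(cloud, 0.5)
        in_set = {tuple(p) for p in cloud.xyz}
        assert all(tuple(p) in in_set for p in out.xyz)

    def test_z_tie_broken_by_smallest_x_then_y(self):
        cloud = PointCloud(
            np.array([[0.4, 0.1, 1.0], [0.1, 0.4, 1.0], [0.1, 0.2, 1.0]])
        )
        out = filter_lowest_points(cloud, 0.5)
        np.testing.assert_allclose(out.xyz[0], [0.1, 0.2, 1.0])

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            filter_lowest_points(PointCloud(np.empty((0, 3))), 0.5)


class TestTinInterpolate:
    @pytest.mark.parametrize("resolution", [0.10, 0.25, 0.50])
    def test_reproduces_plane_exactly(self, plane_cloud, resolution):
        """Barycentric interpolation of points on a plane is exact in-hull."""
        grid = grid_for_bounds(plane_cloud.bounds(), resolution)
        out = tin_interpolate(plane_cloud, grid)
        gx, gy = out.center_mesh()
        expected = 0.3 * gx - 0.1 * gy + 2.0
        mask = out.valid_mask()
        assert mask.sum() > 100
        np.testing.assert_allclose(out.values[mask], expected[mask], atol=1e-9)

    def test_grid_outside_hull_is_all_nodata(self, plane_cloud):
        grid = RasterGrid(origin=(100.0, 110.0), cell_size=0.5,
                          values=np.full((10, 10), np.nan))
        out = tin_interpolate(plane_cloud, grid)
        assert not out.valid_mask().any()

    def test_matches_brute_force_barycentric(self, rng):
        """Random probes agree with point-in-triangle + barycentric weights
        computed by hand over an independent triangulation."""
        from scipy.spatial import Delaunay

        xyz = np.column_stack(
            [rng.uniform(0, 4, 50), rng.uniform(0, 4, 50), rng.uniform(0, 1, 50)]
        )
        cloud = PointCloud(xyz)
        grid = grid_for_bounds(cloud.bounds(), 0.25)
        out = tin_interpolate(cloud, grid)
        gx, gy = out.center_mesh()

        tri = Delaunay(xyz[:, :2])
        rows, cols = np.nonzero(out.valid_mask())
        pick = rng.choice(len(rows), size=min(20, len(rows)), replace=False)
        for r, c in zip(rows[pick], cols[pick]):
            p = np.array([gx[r, c], gy[r, c]])
            s = tri.find_simplex(p)
            assert s >= 0
            verts = tri.simplices[s]
            a, b, cc = xyz[verts, :2]
            T = np.column_stack([b - a, cc - a])
            lam12 = np.linalg.solve(T, p - a)
            lam = np.array([1 - lam12.sum(), *lam12])
            expected = lam @ xyz[verts, 2]
            assert out.values[r, c] == pytest.approx(expected, abs=1e-8)

    def test_too_few_points_rejected(self):
        cloud = PointCloud(np.array([[0, 0, 0], [1, 1, 1]], dtype=float))
        grid = grid_for_bounds((0, 0, 1, 1), 0.5)
        with pytest.raises(DegenerateGeometryError):
            tin_interpolate(cloud, grid)

    def test_collinear_points_rejected(self):
        cloud = PointCloud(
            np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        )
        grid = grid_for_bounds((0, 0, 3, 3), 0.5)
        with pytest.raises(DegenerateGeometryError):
            tin_interpolate(cloud, grid)


class TestDsmDtmChm:
    def test_dsm_flat_canopy(self, rng):
        xyz = np.column_stack(
            [rng.uniform(0, 5, 2000), rng.uniform(0, 5, 2000), np.full(2000, 0.5)]
        )
        dsm = build_dsm(PointCloud(xyz), 0.5)
        mask = dsm.valid_mask()
        assert dsm.band == "DSM"
        np.testing.assert_allclose(dsm.values[mask], 0.5, atol=1e-9)

    def test_dsm_uses_per_cell_maximum(self):
        """A low point sharing a cell with a high point does not dent the DSM."""
        pts = []
        for cx in np.arange(0.25, 3.0, 0.5):
            for cy in np.arange(0.25, 3.0, 0.5):
                pts.append([cx, cy, 0.6])
        pts.append([1.25, 1.25, 0.1])  # extra low point in an interior cell
        dsm = build_dsm(PointCloud(np.array(pts)), 0.5)
        mask = dsm.valid_mask()
        np.testing.assert_allclose(dsm.values[mask], 0.6, atol=1e-9)

    def test_dtm_tracks_tilted_ground_under_canopy(self):
        """Tilted ground + 0.5 m canopy, 20% ground strikes: the DTM follows
        the ground at nearly all in-hull cells."""
        params = SceneParams(
            extent=(0, 0, 10, 10),
            ground_coeffs=(0.05, 0.0, 1.0),
            vegetation_mean_height=0.5,
            vegetation_height_sd=0.0,
            ground_fraction=0.2,
            point_density=700,
            vertical_noise_sd=0.0,
            seed=7,
        )
        cloud = sample_point_cloud(params)
        dtm = build_dtm(cloud, 0.25)
        gx, gy = dtm.center_mesh()
        expected = 0.05 * gx + 1.0
        mask = dtm.valid_mask()
        err = np.abs(dtm.values[mask] - expected[mask])
        assert np.mean(err < 0.02) > 0.95

    def test_plane_cloud_dtm_equals_plane(self, plane_cloud):
        dtm = build_dtm(plane_cloud, 0.25)
        gx, gy = dtm.center_mesh()
        mask = dtm.valid_mask()
        np.testing.assert_allclose(
            dtm.values[mask], (0.3 * gx - 0.1 * gy + 2.0)[mask], atol=1e-9
        )

    @pytest.mark.parametrize(
        "dsm_val, dtm_val, clamp, expected",
        [(1.2, 1.0, True, 0.2), (0.9, 1.0, True, 0.0), (0.9, 1.0, False, -0.1)],
    )
    def test_chm_difference_and_clamping(self, dsm_val, dtm_val, clamp, expected):
        geom = dict(origin=(0.0, 1.0), cell_size=0.5)
        dsm = RasterGrid(values=np.full((2, 2), dsm_val), band="DSM", **geom)
        dtm = RasterGrid(values=np.full((2, 2), dtm_val), band="DTM", **geom)
        chm = build_chm(dsm, dtm, clamp_negative=clamp)
        assert chm.band == "CHM"
        np.testing.assert_allclose(chm.values, expected)

    def test_chm_nodata_propagates(self):
        geom = dict(origin=(0.0, 1.0), cell_size=0.5)
        dsm = RasterGrid(values=np.array([[np.nan, 1.2]]), band="DSM", **geom)
        dtm = RasterGrid(values=np.array([[1.0, 1.0]]), band="DTM", **geom)
        chm = build_chm(dsm, dtm)
        assert np.isnan(chm.values[0, 0])
        assert chm.values[0, 1] == pytest.approx(0.2)

    def test_chm_geometry_mismatch_rejected(self):
        dsm = RasterGrid(origin=(0.0, 1.0), cell_size=0.5, values=np.zeros((2, 2)))
        dtm = RasterGrid(origin=(0.0, 1.0), cell_size=0.25, values=np.zeros((2, 2)))
        with pytest.raises(GridGeometryError):
            build_chm(dsm, dtm)


class TestEndToEnd:
    def test_constant_canopy_height_recovery(self):
        """Noise-free flat scene with 0.5 m sward: the mean CHM over in-hull
        cells observing both strike types is 0.5 within a millimeter at
        every resolution."""
        from grasshh.experiments import both_strike_mask

        params = SceneParams(
            extent=(0, 0, 10, 2),
            vegetation_mean_height=0.5,
            vegetation_height_sd=0.0,
            ground_fraction=0.15,
            point_density=700,
            vertical_noise_sd=0.0,
            seed=11,
        )
        cloud = sample_point_cloud(params)
        for res in (0.10, 0.25, 0.50):
            grid = grid_for_bounds(cloud.bounds(), res)
            chm = build_chm(
                build_dsm(cloud, res, grid=grid), build_dtm(cloud, res, grid=grid)
            )
            mask = chm.valid_mask() & both_strike_mask(cloud, grid, 0.5)
            assert abs(np.mean(chm.values[mask]) - 0.5) < 1e-3

    def test_resolution_consistency(self):
        """5x5 block means of the 10 cm CHM approximate the 50 cm CHM."""
        params = SceneParams(
            extent=(0, 0, 10, 5),
            vegetation_mean_height=0.3,
            vegetation_height_sd=0.08,
            correlation_length=1.0,
            ground_fraction=0.15,
            point_density=700,
            vertical_noise_sd=0.0,
            seed=3,
        )
        cloud = sample_point_cloud(params)
        grids = {
            res: grid_for_bounds(cloud.bounds(), res, snap=0.5) for res in (0.10, 0.50)
        }
        chms = {
            res: build_chm(
                build_dsm(cloud, res, grid=g),
                build_dtm(cloud, res, grid=g),
            )
            for res, g in grids.items()
        }
        fine, coarse = chms[0.10], chms[0.50]
        nr, nc = coarse.n_rows, coarse.n_cols
        fine_vals = fine.values[: nr * 5, : nc * 5]
        block = fine_vals.reshape(nr, 5, nc, 5).mean(axis=(1, 3))
        both = np.isfinite(block) & coarse.valid_mask()
        assert both.sum() > 20
        mad = np.mean(np.abs(block[both] - coarse.values[both]))
        assert mad < 0.02
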