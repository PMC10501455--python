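"""Point-cloud sampling, PCA frame, projection and silhouette extraction."""

import numpy as np
import pytest
from scipy import stats

from dentamorph import (BinaryMask, DegenerateShapeError, FitBounds,
                        ParameterError, PointCloud3D, SASchedule,
                        fit_sinusoid_sa, inferior_silhouette, pca_frame,
                        project_to_plane, sample_point_cloud,
                        silhouette_from_mask, voxel_center_cloud)
from dentamorph.shapesim import SimShapeSpec, sample_shape_points

from conftest import make_ball


def plain_cuboid_mask():
    spec = SimShapeSpec(amplitude_mm=0.0, frequency_bpm=0.1)
    from dentamorph import simulate_dentated_cuboid
    return simulate_dentated_cuboid(spec)


class TestSamplePointCloud:
    def test_all_points_inside_foreground(self, dentated_mask):
        cloud = sample_point_cloud(dentated_mask, 5000, seed=1)
        iv = np.rint((cloud.points - dentated_mask.origin_mm)
                     / dentated_mask.spacing_mm).astype(int)
        assert dentated_mask.data[tuple(iv.T)].all()
        assert len(cloud.points) == 5000

    def test_deterministic_given_seed(self, dentated_mask):
        a = sample_point_cloud(dentated_mask, 1000, seed=5)
        b = sample_point_cloud(dentated_mask, 1000, seed=5)
        assert np.array_equal(a.points, b.points)

    def test_ball_centroid_within_three_standard_errors(self):
        mask = make_ball(12, 32, spacing=1.0)
        cloud = sample_point_cloud(mask, 50_000, seed=2)
        center = mask.origin_mm + np.array(mask.shape) / 2 - 0.5
        # sd of a coordinate in a ball of radius R is R/sqrt(5)
        se = (12 / np.sqrt(5)) / np.sqrt(len(cloud.points))
        assert np.all(np.abs(cloud.points.mean(axis=0) - center) < 3 * se)

    def test_occupancy_uniform_over_octants(self):
        data = np.zeros((24, 16, 12), dtype=np.uint8)
        data[2:22, 2:14, 2:10] = 1
        mask = BinaryMask(data=data, spacing_mm=1.0)
        cloud = sample_point_cloud(mask, 40_000, seed=3)
        mid = mask.origin_mm + np.array([11.5, 7.5, 5.5])
        octant = ((cloud.points > mid) * [1, 2, 4]).sum(axis=1)
        counts = np.bincount(octant, minlength=8)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_sparse_foreground_recommends_voxel_centers(self):
        data = np.zeros((128, 128, 128), dtype=np.uint8)
        data[0, 0, 0] = 1
        data[127, 127, 127] = 1
        mask = BinaryMask(data=data, spacing_mm=1.0)
        with pytest.raises(ParameterError, match="voxel_center"):
            sample_point_cloud(mask, 100, seed=0)


class TestPCAFrame:
    def test_cuboid_axes_recovered_within_two_degrees(self):
        cloud = voxel_center_cloud(plain_cuboid_mask())
        frame = pca_frame(cloud, inferior_hint=(0, 0, -1),
                          anterior_hint=(1, 0, 0))
        for vec, expect in [(frame.e1, [1, 0, 0]), (frame.e2, [0, 1, 0]),
                            (frame.e3, [0, 0, -1])]:
            angle = np.degrees(np.arccos(np.clip(abs(vec @ expect), -1, 1)))
            assert angle <= 2.0
        assert frame.e3 @ np.array([0, 0, -1]) > 0
        assert np.allclose(np.cross(frame.e3, frame.e1), frame.e2)

    def test_rotation_equivariance(self):
        spec = SimShapeSpec(amplitude_mm=0.3, frequency_bpm=0.2)
        pts = sample_shape_points(spec, 20_000, seed=4)
        theta = np.deg2rad(25)
        R = np.array([[np.cos(theta), 0, np.sin(theta)],
                      [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        f0 = pca_frame(PointCloud3D(points=pts), inferior_hint=(0, 0, -1),
                       anterior_hint=(1, 0, 0))
        f1 = pca_frame(PointCloud3D(points=pts @ R.T),
                       inferior_hint=R @ [0, 0, -1],
                       anterior_hint=R @ [1, 0, 0])
        for e0, e1 in [(f0.e1, f1.e1), (f0.e2, f1.e2), (f0.e3, f1.e3)]:
            assert abs((R @ e0) @ e1) > 1 - 1e-6

    def test_isotropic_ball_triggers_degenerate_warning(self, caplog):
        mask = make_ball(10, 26)
        cloud = sample_point_cloud(mask, 20_000, seed=6)
        with caplog.at_level("WARNING", logger="dentamorph"):
            pca_frame(cloud, inferior_hint=(0, 0, -1))
        assert any("near-isotropic" in r.message for r in caplog.records)

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(0)
        pts = rng.random((500, 3))
        pts[:, 2] = 0.0
        with pytest.raises(DegenerateShapeError):
            pca_frame(PointCloud3D(points=pts), inferior_hint=(0, 0, -1))


class TestProjection:
    def test_points_in_plane_are_unchanged(self):
        spec = SimShapeSpec(amplitude_mm=0.2, frequency_bpm=0.1)
        pts = sample_shape_points(spec, 20_000, seed=7)
        frame = pca_frame(PointCloud3D(points=pts), inferior_hint=(0, 0, -1),
                          anterior_hint=(1, 0, 0))
        in_plane = frame.mean_mm + np.outer(np.linspace(-5, 5, 20), frame.e1) \
            + np.outer(np.linspace(-2, 2, 20), frame.e3)
        uv = project_to_plane(PointCloud3D(points=in_plane), frame)
        assert np.allclose(uv[:, 0], np.linspace(-5, 5, 20), atol=1e-9)
        assert np.allclose(uv[:, 1], np.linspace(-2, 2, 20), atol=1e-9)

    def test_projection_is_a_contraction(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(200, 3)) * [10, 4, 2]
        frame = pca_frame(PointCloud3D(points=pts), inferior_hint=(0, 0, -1))
        uv = project_to_plane(PointCloud3D(points=pts), frame)
        i, j = rng.integers(0, 200, 50), rng.integers(0, 200, 50)
        d3 = np.linalg.norm(pts[i] - pts[j], axis=1)
        d2 = np.linalg.norm(uv[i] - uv[j], axis=1)
        assert np.all(d2 <= d3 + 1e-9)

    def test_cuboid_projected_extents(self):
        cloud = voxel_center_cloud(plain_cuboid_mask())
        frame = pca_frame(cloud, inferior_hint=(0, 0, -1),
                          anterior_hint=(1, 0, 0))
        uv = project_to_plane(cloud, frame)
        assert np.ptp(uv[:, 0]) == pytest.approx(40.0, abs=0.5)
        assert np.ptp(uv[:, 1]) == pytest.approx(10.0, abs=0.5)


class TestSilhouette:
    def test_flat_bottom_gives_constant_silhouette(self):
        sil = silhouette_from_mask(plain_cuboid_mask(), 50_000, seed=8,
                                   bin_width_mm=0.2, trim_fraction=0.1,
                                   deterministic=True)
        assert np.ptp(sil.y_mm) <= 0.2

    def test_silhouette_matches_analytic_face(self, dentated_spec,
                                              dentated_mask):
        """The extracted silhouette reproduces b + A sin(2 pi F x + phi)
        with RMS error at most one fine voxel."""
        cloud = sample_point_cloud(dentated_mask, 200_000, seed=9)
        frame = pca_frame(cloud,
                          inferior_hint=dentated_mask.direction_vector("inferior"),
                          anterior_hint=dentated_mask.direction_vector("anterior"))
        uv = project_to_plane(cloud, frame)
        sil = inferior_silhouette(uv, 0.2, 0.1)
        x_world = sil.x_mm + frame.mean_mm @ frame.e1
        expect = dentated_spec.inferior_height(x_world)
        resid = (sil.y_mm - expect) - np.mean(sil.y_mm - expect)
        assert np.sqrt(np.mean(resid ** 2)) <= dentated_spec.voxel_mm

    def test_trim_arithmetic(self, dentated_mask):
        """trim_fraction 0.4 on a 40 mm shape keeps ~8 mm; wide bins then
        leave fewer than 10 and raise."""
        sil = silhouette_from_mask(dentated_mask, 50_000, seed=10,
                                   bin_width_mm=0.2, trim_fraction=0.4)
        assert np.ptp(sil.x_mm) <= 8.5
        with pytest.raises(ParameterError):
            silhouette_from_mask(dentated_mask, 50_000, seed=10,
                                 bin_width_mm=1.0, trim_fraction=0.4)

    def test_deterministic_and_sampled_modes_agree(self, coarse_mask):
        """Voxel-centre and rejection-sampling extraction give fitted
        amplitude and frequency within 2 % of each other."""
        fits = []
        for det in (False, True):
            sil = silhouette_from_mask(coarse_mask, 200_000, seed=11,
                                       bin_width_mm=0.2, trim_fraction=0.1,
                                       deterministic=det)
            fits.append(fit_sinusoid_sa(sil, FitBounds(), SASchedule(seed=2)))
        samp, det = fits
        assert abs(samp.A_mm - det.A_mm) / det.A_mm <= 0.02
        assert abs(samp.f_bpm - det.f_bpm) / det.f_bpm <= 0.02

    def test_pipeline_reproducible_given_seed(self, dentated_mask):
        a = silhouette_from_mask(dentated_mask, 30_000, seed=12,
                                 bin_width_mm=0.2, trim_fraction=0.1)
        b = silhouette_from_mask(dentated_mask, 30_000, seed=12,
                                 bin_width_mm=0.2, trim_fraction=0.1)
        assert np.array_equal(a.x_mm, b.x_mm)
        assert np.array_equal(a.y_mm, b.y_mm)


class TestRotationInvariance:
    @staticmethod
    def rotated_mask(spec, R, center):
        """Voxelize the rotated continuous shape exactly (no resampling)."""
        h = spec.voxel_mm
        pad = 14.0
        lo = np.array([-pad, -pad, -spec.amplitude_mm - pad])
        hi = np.array([spec.length_mm + pad, spec.width_mm + pad,
                       spec.height_mm + pad])
        n = np.ceil((hi - lo) / h).astype(int)
        axes = [lo[k] + (np.arange(n[k]) + 0.5) * h for k in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        local = (pts - center) @ R + center     # world -> shape coordinates
        fg = spec.contains(local).reshape(tuple(n))
        return BinaryMask(data=fg.astype(np.uint8), spacing_mm=h,
                          origin_mm=lo + h / 2, axes=("A", "R", "S"))

    def test_mask_rotation_stable_to_voxel_tolerance(self, coarse_spec,
                                                     coarse_mask):
        """Rigidly rotating the shape before voxelization changes the
        fitted frequency by < 2 % and the amplitude by less than a
        quarter voxel (re-voxelization noise)."""
        theta = np.deg2rad(15)
        R = np.array([[np.cos(theta), 0, np.sin(theta)],
                      [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        center = np.array([20.0, 10.0, 5.0])
        rot = self.rotated_mask(coarse_spec, R, center)
        hint = R @ np.array([0, 0, -1.0])
        sil_r = silhouette_from_mask(rot, 200_000, seed=13, bin_width_mm=0.2,
                                     trim_fraction=0.1, inferior_hint=hint)
        sil_0 = silhouette_from_mask(coarse_mask, 200_000, seed=13,
                                     bin_width_mm=0.2, trim_fraction=0.1)
        fit_r = fit_sinusoid_sa(sil_r, FitBounds(), SASchedule(seed=3))
        fit_0 = fit_sinusoid_sa(sil_0, FitBounds(), SASchedule(seed=3))
        assert abs(fit_r.f_bpm - fit_0.f_bpm) / fit_0.f_bpm <= 0.02
        assert abs(fit_r.A_mm - fit_0.A_mm) <= 0.25 * coarse_spec.voxel_mm

    def test_cloud_rotation_leaves_fit_within_two_percent(self, coarse_spec):
        """Rotating the continuous point cloud (PCA equivariance) leaves
        fitted amplitude and frequency within 2 %."""
        pts = sample_shape_points(coarse_spec, 200_000, seed=14)
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), 0, np.sin(theta)],
                      [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        results = []
        for p, hint_i, hint_a in [
                (pts, (0, 0, -1), (1, 0, 0)),
                (pts @ R.T, R @ [0, 0, -1], R @ [1, 0, 0])]:
            frame = pca_frame(PointCloud3D(points=p), inferior_hint=hint_i,
                              anterior_hint=hint_a)
            uv = project_to_plane(PointCloud3D(points=p), frame)
            sil = inferior_silhouette(uv, 0.1, 0.1)
            results.append(fit_sinusoid_sa(sil, FitBounds(),
                                           SASchedule(seed=4)))
        a, b = results
        assert abs(a.A_mm - b.A_mm) / a.A_mm <= 0.02
        assert abs(a.f_bpm - b.f_bpm) / a.f_bpm <= 0.02
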