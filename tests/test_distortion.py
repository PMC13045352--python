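import numpy as np
import pytest

from exmkit.distortion import (
    DistortionField3D,
    FlowParams,
    farneback_flow,
    radial_component_map,
    resection_flow_3d,
    rmse_vs_length_scale,
)
from exmkit.fixtures import PSFModel, render_volume


def linear_radial_field(alpha, shape=(64, 64, 64), voxel=25.0):
    c = np.array([shape[0] * voxel / 2] * 3)
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * voxel for n in shape], indexing="ij")
    vec = alpha * np.stack([g - ci for g, ci in zip(grids, c)])
    return DistortionField3D(vec, (voxel,) * 3), c


class TestFarnebackFlow:
    def test_identical_planes_zero_flow_on_mask(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(100, 1100, (150, 3))
        vol = render_volume(pts, 1.0, PSFModel(50.0, 50.0), (8, 60, 60), (150.0, 20.0, 20.0))
        img = vol.data[4]
        f = farneback_flow(img, img, (20.0, 20.0))
        mags_px = np.hypot(*f.flow)[f.valid] / 20.0
        assert mags_px.mean() < 0.05

    def test_flow_reported_in_nm(self):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.standard_normal((80, 80)), 3)
        moving = np.roll(base, -2, axis=1)
        f = farneback_flow(base, moving, (40.0, 40.0))
        inner = f.flow[:, 20:-20, 20:-20]
        assert abs(inner[1].mean() - (-2 * 40.0)) < 0.2 * 40.0

    def test_zero_variance_plane_raises(self):
        with pytest.raises(ValueError, match="structure"):
            farneback_flow(np.zeros((32, 32)), np.zeros((32, 32)), (10.0, 10.0))


class TestResectionFusion:
    def test_identical_volumes_near_zero_field(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(100, 1180, (400, 3))
        vol = render_volume(pts, 1.0, PSFModel(60.0, 90.0), (64, 64, 64), (20.0,) * 3)
        field = resection_flow_3d(vol, vol, FlowParams(levels=2, iterations=2))
        assert field.magnitude[field.valid].mean() < 1.0  # nm

    def test_fused_x_component_is_mean_of_plane_estimates(self):
        # when dx_a and dx_b are forced equal (identical volumes), fused dx
        # equals either component exactly; verified on the zero field
        rng = np.random.default_rng(3)
        pts = rng.uniform(100, 1180, (200, 3))
        vol = render_volume(pts, 1.0, PSFModel(60.0, 90.0), (32, 64, 64), (40.0, 20.0, 20.0))
        field = resection_flow_3d(vol, vol, FlowParams(levels=1, iterations=1))
        np.testing.assert_allclose(field.vectors[2][field.valid], 0.0, atol=0.5)

    def test_axial_shear_recovered(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(120, 1160, (900, 3))
        shift = np.array([30.0, 0.0, 0.0])  # pure dz
        psf = PSFModel(60.0, 90.0)
        pre = render_volume(pts, 1.0, psf, (64, 64, 64), (20.0,) * 3)
        post = render_volume(pts + shift, 1.0, psf, (64, 64, 64), (20.0,) * 3,
                             allow_clipping=True)
        field = resection_flow_3d(pre, post, FlowParams(levels=2, winsize=21, iterations=4))
        m = field.valid
        assert abs(field.vectors[0][m].mean() - 30.0) < 6.0  # dz within 20%
        assert abs(field.vectors[1][m].mean()) < 5.0
        assert abs(field.vectors[2][m].mean()) < 5.0


class TestRmseCurve:
    def test_zero_field_gives_zero_rmse(self):
        field = DistortionField3D(np.zeros((3, 32, 32, 32)), (50.0,) * 3)
        curve = rmse_vs_length_scale(field, [100, 300, 900], n_pairs=300, seed=0)
        np.testing.assert_allclose(curve.rmse_nm, 0.0)

    def test_uniform_shift_is_invisible_to_pair_differences(self):
        vec = np.zeros((3, 32, 32, 32))
        vec[2] = 40.0
        field = DistortionField3D(vec, (50.0,) * 3)
        curve = rmse_vs_length_scale(field, [100, 400], n_pairs=300, seed=1)
        np.testing.assert_allclose(curve.rmse_nm, 0.0)
        # the raw-magnitude variant does see it
        raw = rmse_vs_length_scale(field, [100, 400], n_pairs=300, seed=1, raw_magnitude=True)
        np.testing.assert_allclose(raw.rmse_nm, 40.0, rtol=1e-6)

    def test_linear_radial_field_percent_is_alpha(self):
        field, _ = linear_radial_field(0.03)
        scales = [50, 100, 250, 500, 1000]
        curve = rmse_vs_length_scale(field, scales, n_pairs=1500, seed=2)
        assert np.all(np.abs(curve.percent - 3.0) < 0.3)

    def test_scaling_field_scales_rmse_linearly(self):
        f1, _ = linear_radial_field(0.02)
        f2 = DistortionField3D(3.0 * f1.vectors, f1.voxel_size)
        c1 = rmse_vs_length_scale(f1, [200, 600], n_pairs=800, seed=3)
        c2 = rmse_vs_length_scale(f2, [200, 600], n_pairs=800, seed=3)
        np.testing.assert_allclose(c2.rmse_nm, 3.0 * c1.rmse_nm, rtol=1e-9)

    def test_determinism_and_sparse_scale_flagging(self):
        field, _ = linear_radial_field(0.01, shape=(16, 16, 16), voxel=20.0)
        a = rmse_vs_length_scale(field, [100, 10000], n_pairs=200, seed=5)
        b = rmse_vs_length_scale(field, [100, 10000], n_pairs=200, seed=5)
        np.testing.assert_array_equal(a.rmse_nm[:1], b.rmse_nm[:1])
        assert a.flagged[1] and np.isnan(a.rmse_nm[1])  # scale beyond the grid

    def test_too_few_pairs_rejected(self):
        field, _ = linear_radial_field(0.01)
        with pytest.raises(ValueError, match="n_pairs"):
            rmse_vs_length_scale(field, [100], n_pairs=50)


class TestRadialMap:
    def test_zero_field_zero_map(self):
        field = DistortionField3D(np.zeros((3, 16, 16, 16)), (50.0,) * 3)
        assert np.all(radial_component_map(field, (400.0,) * 3) == 0)

    def test_tangential_field_projects_to_zero(self):
        c = np.array([400.0] * 3)
        grids = np.meshgrid(*[(np.arange(16) + 0.5) * 50.0] * 3, indexing="ij")
        rz, ry, rx = [g - ci for g, ci in zip(grids, c)]
        # tangential: t = r x e_z is orthogonal to r everywhere
        vec = np.stack([ry * 0.0 - rx * 0.0, rx, -ry]) * 0.05
        field = DistortionField3D(vec, (50.0,) * 3)
        m = radial_component_map(field, c)
        assert np.abs(m).max() < 1e-9

    def test_linear_radial_field_map_is_alpha_r(self):
        field, c = linear_radial_field(0.03, shape=(32, 32, 32), voxel=25.0)
        m = radial_component_map(field, c)
        grids = np.meshgrid(*[(np.arange(32) + 0.5) * 25.0] * 3, indexing="ij")
        r = np.sqrt(sum((g - ci) ** 2 for g, ci in zip(grids, c)))
        np.testing.assert_allclose(m, 0.03 * r, atol=1e-9)


class TestEndToEndRecovery:
    def test_rotation_equivariance_on_axis_aligned_rotation(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(100, 1180, (600, 3))
        psf = PSFModel(60.0, 60.0)
        shift = np.array([10.0, 25.0, -15.0])
        pre = render_volume(pts, 1.0, psf, (64, 64, 64), (20.0,) * 3)
        post = render_volume(pts + shift, 1.0, psf, (64, 64, 64), (20.0,) * 3,
                             allow_clipping=True)
        f = resection_flow_3d(pre, post, FlowParams(levels=2, iterations=3))
        # rotate the volume pair 90 deg in the y-x plane: (z,y,x)->(z,x,-y)
        from exmkit.volume import ImageVolume

        rot = lambda v: ImageVolume(np.rot90(v.data, k=1, axes=(1, 2)).copy(), v.voxel_size)
        f_rot = resection_flow_3d(rot(pre), rot(post), FlowParams(levels=2, iterations=3))
        m = f.valid & np.rot90(f_rot.valid, k=-1, axes=(0, 1))
        est = np.array([f.vectors[i][m].mean() for i in range(3)])
        back = np.stack([np.rot90(f_rot.vectors[i], k=-1, axes=(0, 1)) for i in range(3)])
        est_rot = np.array([back[0][m].mean(), back[2][m].mean(), -back[1][m].mean()])
        np.testing.assert_allclose(est, est_rot, atol=1.5)

    def test_under_expansion_field_recovered(self, textured_volume_pair):
        pre, post, gt, dist, center = textured_volume_pair
        field = resection_flow_3d(pre, post, FlowParams(levels=2, winsize=21, iterations=5),
                                  smooth_sigma_nm=60.0)
        shape = pre.spatial_shape
        zz, yy, xx = field.voxel_centers_phys()
        pts = np.stack([zz, yy, xx], -1).reshape(-1, 3)
        true = np.moveaxis(dist.displacement(pts).reshape(*shape, 3), -1, 0)
        m = field.valid & (np.sqrt((true**2).sum(0)) > 2.0)
        est = field.vectors[:, m].T
        tru = true[:, m].T
        cos = (est * tru).sum(1) / (
            np.linalg.norm(est, axis=1) * np.linalg.norm(tru, axis=1) + 1e-12
        )
        median_angle = np.degrees(np.median(np.arccos(np.clip(cos, -1, 1))))
        assert median_angle < 30.0
        mag_ratio = np.median(np.linalg.norm(est, axis=1) / np.linalg.norm(tru, axis=1))
        assert 0.5 < mag_ratio < 2.0

        rmap = radial_component_map(field, center)
        analytic_min = dist.local_amplitude * dist.local_falloff * np.exp(-0.5)
        assert abs(rmap[field.valid].min() / analytic_min - 1.0) < 0.2
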