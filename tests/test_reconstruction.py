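"""Voxel grids, the cone system model and list-mode ML-EM behaviour."""

import numpy as np
import pandas as pd
import pytest

from comptel import reconstruction
from comptel.analysis import profile_fwhm
from comptel.config import make_fixture
from comptel.reconstruction import (Image, MLEMConfig, VoxelGrid,
                                    default_source_plane_grid,
                                    estimate_global_cone_width,
                                    extract_plane, mlem_reconstruct,
                                    system_row)


@pytest.fixture(scope="module")
def point_cones():
    """100 exact cones whose surfaces all contain (3, -2, -35) mm."""
    return make_fixture("analytic_cones",
                        {"point_mm": (3.0, -2.0, -35.0), "n_cones": 100},
                        seed=11)


@pytest.fixture(scope="module")
def noisy_cones(point_cones):
    rng = np.random.default_rng(3)
    c = point_cones.copy()
    c["half_angle_rad"] += rng.normal(0.0, 0.05, len(c))
    c = c[(c.half_angle_rad > 0.02) & (c.half_angle_rad < 3.0)]
    c["sigma_rad"] = 0.05
    return c


class TestVoxelGrid:
    def test_centers_layout(self):
        grid = VoxelGrid((-1.0, -1.0, -35.0), 1.0, (3, 3, 1))
        c = grid.centers()
        assert c.shape == (9, 3)
        assert c[0].tolist() == [-1.0, -1.0, -35.0]
        assert c[-1].tolist() == [1.0, 1.0, -35.0]

    def test_default_source_plane_grid_covers_source(self):
        grid = default_source_plane_grid()
        assert grid.dims == (80, 80, 1)
        c = grid.centers()
        assert c[:, 2].min() == -35.0
        assert np.any(np.linalg.norm(c - [0, 0, -35.0], axis=1) < 1.0)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), -1.0, (2, 2, 1))
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), 1.0, (0, 2, 1))


class TestSystemRow:
    def test_on_surface_voxel_max_weight(self):
        grid = VoxelGrid((-5.0, -5.0, -35.0), 1.0, (11, 11, 1))
        apex = np.array([0.0, 0.0, 2.5])
        target = np.array([3.0, 0.0, -35.0])
        w = target - apex
        w = w / np.linalg.norm(w)
        # tilt the axis by 0.3 rad within the x-z plane; the cone with
        # half-angle 0.3 then passes exactly through the target voxel
        beta = 0.3
        axis = np.array([np.cos(beta) * w[0] - np.sin(beta) * w[2], 0.0,
                         np.sin(beta) * w[0] + np.cos(beta) * w[2]])
        cone = {"apex": apex, "axis": axis, "half_angle": beta,
                "half_angle_sigma": 0.02}
        idx, wts = system_row(cone, grid, MLEMConfig(cone_width_model="per_event"))
        assert len(idx) > 0
        centers = grid.centers()
        j = idx[np.argmax(wts)]
        assert np.linalg.norm(centers[j] - target) <= np.sqrt(2)

    def test_weights_finite_nonnegative(self, point_cones):
        grid = default_source_plane_grid()
        cone = point_cones.iloc[0]
        idx, wts = system_row(
            {"apex": cone[["apex_x_mm", "apex_y_mm", "apex_z_mm"]].to_numpy(),
             "axis": cone[["axis_x", "axis_y", "axis_z"]].to_numpy(),
             "half_angle": cone.half_angle_rad,
             "half_angle_sigma": cone.sigma_rad}, grid)
        assert np.all(np.isfinite(wts)) and np.all(wts >= 0)

    def test_inverse_square_distance(self):
        from comptel.reconstruction import _row_weights
        apex = np.zeros(3)
        axis = np.array([0.0, 0.0, -1.0])
        near = np.array([[0.0, 0.0, -10.0]])
        far = np.array([[0.0, 0.0, -20.0]])
        w_near = _row_weights(apex, axis, 0.5, 0.5, near)
        w_far = _row_weights(apex, axis, 0.5, 0.5, far)
        assert w_far[0] == pytest.approx(w_near[0] / 4.0, rel=1e-12)


class TestMLEM:
    def test_point_source_localized(self, point_cones):
        grid = default_source_plane_grid()
        img = mlem_reconstruct(point_cones, grid, MLEMConfig())
        arr = img.as_array()[0]
        iy, ix = np.unravel_index(np.argmax(arr), arr.shape)
        x, y = grid.x_axis()[ix], grid.y_axis()[iy]
        assert abs(x - 3.0) <= 1.0 and abs(y - (-2.0)) <= 1.0

    def test_log_likelihood_monotone(self, noisy_cones):
        grid = default_source_plane_grid()
        img = mlem_reconstruct(noisy_cones, grid, MLEMConfig(n_iterations=30))
        ll = np.array(img.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[:-1]))

    def test_non_negative_everywhere(self, noisy_cones):
        img = mlem_reconstruct(noisy_cones, default_source_plane_grid(),
                               MLEMConfig(n_iterations=10))
        assert np.all(img.values >= 0)
        assert np.all(np.isfinite(img.values))

    def test_single_cone_backprojection_structure(self, point_cones):
        grid = default_source_plane_grid()
        one = point_cones.iloc[[0]]
        cfg = MLEMConfig(n_iterations=1, cone_width_model="per_event")
        img = mlem_reconstruct(one, grid, cfg)
        w = reconstruction.system_matrix(one, grid, cfg)[0]
        # intensity only where the cone row has support
        assert np.all(img.values[w == 0] == pytest.approx(0.0, abs=1e-300))
        assert img.values[w > 0].sum() > 0

    def test_weight_scaling_equivariance(self, noisy_cones, monkeypatch):
        """A constant factor on all system weights does not change the
        normalized image."""
        grid = default_source_plane_grid()
        imgs = []
        real = reconstruction.system_matrix
        for scale in (1.0, 7.3):
            monkeypatch.setattr(
                reconstruction, "system_matrix",
                lambda c, g, cfg, sigma=None, s=scale: s * real(c, g, cfg, sigma))
            img = mlem_reconstruct(noisy_cones, grid, MLEMConfig(n_iterations=8))
            imgs.append(img.values / img.values.sum())
        np.testing.assert_allclose(imgs[0], imgs[1], atol=1e-9)

    def test_fwhm_non_increasing_with_iterations(self, noisy_cones):
        grid = default_source_plane_grid()
        fwhms = []
        for n in (5, 30):
            img = mlem_reconstruct(noisy_cones, grid,
                                   MLEMConfig(n_iterations=n))
            xs, ys, sl = extract_plane(img, -35.0)
            fwhms.append(profile_fwhm(xs, ys, sl, "x").fwhm_mm)
        assert fwhms[1] <= fwhms[0] * 1.05  # 5% jitter allowance

    def test_no_cones_is_an_error(self):
        with pytest.raises(ValueError):
            mlem_reconstruct(pd.DataFrame(columns=["apex_x_mm"]),
                             default_source_plane_grid(), MLEMConfig())


class TestWidthCalibration:
    def test_recovers_known_angular_noise(self, point_cones):
        rng = np.random.default_rng(8)
        c = point_cones.copy()
        true_sigma = 0.08
        c["half_angle_rad"] += rng.normal(0.0, true_sigma, len(c))
        c = c[(c.half_angle_rad > 0.02) & (c.half_angle_rad < 3.0)]
        est = estimate_global_cone_width(c, default_source_plane_grid())
        assert est == pytest.approx(true_sigma, rel=0.3)

    def test_exact_cones_yield_floor_width(self, point_cones):
        est = estimate_global_cone_width(point_cones,
                                         default_source_plane_grid())
        # residuals limited by the 1 mm voxel quantization of the probe
        assert est < 0.05


class TestExtractPlane:
    def test_slice_identity_and_bounds(self, point_cones):
        grid = VoxelGrid((-2.0, -2.0, -36.0), 1.0, (5, 5, 3))
        vals = np.arange(75, dtype=float)
        img = Image(grid, vals)
        xs, ys, sl = extract_plane(img, -35.0)
        assert sl.shape == (5, 5)
        np.testing.assert_array_equal(sl, img.as_array()[1])
        with pytest.raises(ValueError):
            extract_plane(img, -20.0)

    def test_save_load_round_trip(self, tmp_path):
        grid = VoxelGrid((-2.0, -2.0, -35.0), 1.0, (4, 4, 1))
        img = Image(grid, np.linspace(0, 1, 16), 7)
        img.save(tmp_path / "img")
        back = Image.load(tmp_path / "img")
        np.testing.assert_allclose(back.values, img.values)
        assert back.iteration_count == 7
        assert back.grid.dims == (4, 4, 1)
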