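"""Registration: rigid recovery, field algebra (warp / compose / invert /
Jacobian), and deformable identity + invariance properties."""

import warnings

import numpy as np
import pytest

import doseaccum as da
from doseaccum.grid import DoseGrid, Grid, ImageVolume
from doseaccum.registration import DisplacementField, warp_mask


def smooth_blob_volume(grid: Grid, rng=None, centers=3) -> ImageVolume:
    """A smooth multi-blob test image with usable gradients everywhere."""
    rng = rng or np.random.default_rng(0)
    xs, ys, zs = grid.coordinate_arrays()
    vals = np.zeros(grid.shape)
    ext = np.asarray(grid.extent_mm)
    for _ in range(centers):
        c = rng.uniform(0.25, 0.75, 3) * ext
        w = rng.uniform(8, 25)
        vals += rng.uniform(100, 400) * np.exp(
            -((xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2) / (2 * w**2)
        )
    return ImageVolume(grid, vals)


def shift_volume(vol: ImageVolume, t_mm) -> ImageVolume:
    """Analytic resample: content moved by +t (out(x) = in(x - t))."""
    dvf = DisplacementField.from_constant(vol.grid, -np.asarray(t_mm))
    return da.apply_dvf(vol, dvf, cval=0.0)


class TestRigid:
    def test_identity_on_equal_images(self, small_grid):
        f = smooth_blob_volume(small_grid)
        t = da.rigid_register(f, f)
        assert np.linalg.norm(t.translation_mm) <= 0.1

    def test_recovers_known_shift_within_half_voxel(self, small_grid):
        f = smooth_blob_volume(small_grid)
        m = shift_volume(f, (5.0, -3.0, 2.0))
        t = da.rigid_register(f, m)
        err = np.abs(np.asarray(t.translation_mm) - (5.0, -3.0, 2.0))
        assert np.all(err <= 0.5 * np.asarray(small_grid.spacing))

    def test_recovers_10mm_shift_under_noise(self):
        # phantom planning CT shifted 10 mm with 20 HU additive noise
        from conftest import tiny_phantom_config

        pct, _ = da.generate_planning_ct(tiny_phantom_config())
        m = shift_volume(pct, (10.0, 0.0, 0.0))
        m.values[m.values == 0.0] = -1000.0  # shift padding is air
        rng = np.random.default_rng(3)
        m.values = m.values + rng.normal(0, 20.0, pct.grid.shape).astype(np.float32)
        t = da.rigid_register(pct, m)
        assert np.linalg.norm(np.asarray(t.translation_mm) - (10.0, 0.0, 0.0)) <= 1.0

    def test_constant_image_raises(self, small_grid):
        c = ImageVolume(small_grid, np.zeros(small_grid.shape))
        f = smooth_blob_volume(small_grid)
        with pytest.raises(ValueError, match="constant"):
            da.rigid_register(c, f)

    def test_disjoint_extents_raise(self, small_grid):
        f = smooth_blob_volume(small_grid)
        far = Grid(small_grid.shape, small_grid.spacing, (1e4, 1e4, 1e4))
        m = ImageVolume(far, f.values.copy())
        with pytest.raises(ValueError, match="overlap"):
            da.rigid_register(f, m)

    def test_transform_compose_inverse_is_identity(self):
        t = da.RigidTransform((3.0, -2.0, 5.0), (2.0, -1.0, 3.0), (10.0, 10.0, 10.0))
        c = t.compose(t.inverse())
        assert np.linalg.norm(c.translation_mm) < 1e-9
        assert np.allclose(c.rotation_deg, 0.0, atol=1e-9)


class TestApplyDvf:
    def test_zero_field_is_identity(self, small_grid, rng):
        vol = ImageVolume(small_grid, rng.normal(0, 100, small_grid.shape))
        out = da.apply_dvf(vol, DisplacementField.zero(small_grid))
        assert np.allclose(out.values, vol.values)

    def test_constant_field_shifts_by_one_voxel(self, small_grid):
        # voxel value = x index; u = (+spacing_x, 0, 0) -> out[i] = i + 1
        idx = np.arange(small_grid.shape[0], dtype=float)
        vol = ImageVolume(small_grid, np.broadcast_to(
            idx[:, None, None], small_grid.shape).copy())
        dvf = DisplacementField.from_constant(small_grid, (small_grid.spacing[0], 0, 0))
        out = da.apply_dvf(vol, dvf)
        interior = out.values[:-1, :, :]
        assert np.allclose(interior, (idx[:-1] + 1)[:, None, None])

    def test_linearity_in_the_volume_argument(self, small_grid, rng):
        d1 = DoseGrid(small_grid, rng.uniform(0, 10, small_grid.shape))
        d2 = DoseGrid(small_grid, rng.uniform(0, 10, small_grid.shape))
        u = DisplacementField(
            small_grid, rng.normal(0, 2.0, small_grid.shape + (3,)))
        a, b = 0.7, 1.9
        comb = DoseGrid(small_grid, a * d1.values + b * d2.values)
        lhs = da.apply_dvf(comb, u).values
        rhs = a * da.apply_dvf(d1, u).values + b * da.apply_dvf(d2, u).values
        assert np.abs(lhs - rhs).max() < 1e-6

    def test_mask_warp_volume_change_matches_jacobian(self, default_cfg,
                                                      default_phantom):
        # warping a cube by the analytic field changes its volume by the
        # integral of |J| over the cube, to within discretization
        from doseaccum.phantom import AnalyticDeformation

        pct, _ = default_phantom
        grid = pct.grid
        d = AnalyticDeformation(tuple(grid.center_mm), 1.5, 60.0)
        dvf = d.pullback_field(grid)
        cube = np.zeros(grid.shape, bool)
        cube[44:52, 44:52, 28:36] = True
        warped = warp_mask(cube, dvf)
        pts = grid.index_to_world(np.argwhere(cube))
        predicted = np.mean(d.jacobian_det(pts)) * cube.sum()
        assert warped.sum() == pytest.approx(predicted, rel=0.10)

    def test_geometry_mismatch_raises(self, small_grid, rng):
        vol = ImageVolume(small_grid, rng.normal(size=small_grid.shape))
        other = Grid((8, 8, 8), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError, match="mismatch"):
            da.apply_dvf(vol, DisplacementField.zero(other))

    def test_mask_fully_out_of_grid_warns_and_empties(self, small_grid):
        mask = np.zeros(small_grid.shape, bool)
        mask[5:8, 5:8, 5:8] = True
        dvf = DisplacementField.from_constant(small_grid, (1e4, 0, 0))
        with pytest.warns(UserWarning, match="empty"):
            out = warp_mask(mask, dvf)
        assert not out.any()


class TestComposeInvert:
    def test_compose_with_zero_is_exact(self, small_grid, rng):
        f = DisplacementField(small_grid, rng.normal(0, 3, small_grid.shape + (3,)))
        z = DisplacementField.zero(small_grid)
        assert np.allclose(da.compose(z, f).vectors, f.vectors)

    def test_translations_add(self, small_grid):
        t1 = DisplacementField.from_constant(small_grid, (2.0, -1.0, 0.5))
        t2 = DisplacementField.from_constant(small_grid, (-0.5, 3.0, 1.0))
        c = da.compose(t1, t2)
        interior = c.vectors[2:-2, 2:-2, 2:-2]
        assert np.allclose(interior, (1.5, 2.0, 1.5))

    def test_compose_equals_sequential_application(self, small_grid, rng):
        from scipy.ndimage import gaussian_filter

        vol = DoseGrid(small_grid, np.abs(
            np.cumsum(rng.normal(1, 0.1, small_grid.shape), axis=0)))

        def smooth_field():
            v = rng.normal(0, 4.0, small_grid.shape + (3,))
            for c in range(3):
                v[..., c] = gaussian_filter(v[..., c], 2.0)
            return DisplacementField(small_grid, v)

        ab, bc = smooth_field(), smooth_field()
        once = da.apply_dvf(vol, da.compose(ab, bc)).values
        twice = da.apply_dvf(da.apply_dvf(vol, bc), ab).values
        interior = (slice(3, -3),) * 3
        assert np.abs(once[interior] - twice[interior]).max() < 0.35  # interp error

    def test_inverse_consistency_of_smooth_phantom_field(self, default_weekly):
        _, truth = default_weekly
        f = truth.dvf_true[2]
        g = da.invert_dvf(f, tol_mm=0.01)
        resid = da.compose(f, g)
        assert resid.magnitude().mean() <= 0.1 * 4.0  # 0.1 x min spacing

    def test_invert_zero_and_constant(self, small_grid):
        z = DisplacementField.zero(small_grid)
        assert np.allclose(da.invert_dvf(z).vectors, 0.0)
        t = DisplacementField.from_constant(small_grid, (1.5, -0.5, 1.0))
        inv = da.invert_dvf(t, tol_mm=1e-6)
        interior = inv.vectors[2:-2, 2:-2, 2:-2]
        assert np.allclose(interior, (-1.5, 0.5, -1.0), atol=1e-6)

    def test_invert_matches_analytic_inverse_at_points(self, default_weekly,
                                                       default_phantom):
        pct, _ = default_phantom
        _, truth = default_weekly
        deform = truth.deformations[1]
        dvf = truth.dvf_true[1]  # pull-back field = phi^{-1} - id
        inv = da.invert_dvf(dvf, tol_mm=0.01)
        rng = np.random.default_rng(5)
        lo = np.asarray(pct.grid.origin) + 40
        hi = np.asarray(pct.grid.origin) + np.asarray(pct.grid.extent_mm) - 40
        pts = rng.uniform(lo, hi, (100, 3))
        # inverse of the pull-back field is the forward map phi
        expected = deform.forward(pts) - pts
        got = inv.sample_at(pts)
        assert np.linalg.norm(got - expected, axis=1).max() < 0.2


class TestJacobian:
    def test_zero_field_unit_determinant(self, small_grid):
        rep = da.jacobian_determinant(DisplacementField.zero(small_grid))
        assert np.allclose(rep.values, 1.0)
        assert rep.fraction_nonpositive == 0.0

    def test_uniform_expansion_closed_form(self, small_grid):
        xs, ys, zs = small_grid.coordinate_arrays()
        c = small_grid.center_mm
        u = np.empty(small_grid.shape + (3,))
        u[..., 0] = 0.1 * (xs - c[0])
        u[..., 1] = 0.1 * (ys - c[1])
        u[..., 2] = 0.1 * (zs - c[2])
        rep = da.jacobian_determinant(DisplacementField(small_grid, u))
        interior = rep.values[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, 1.1**3, atol=1e-9)

    def test_phantom_field_matches_analytic_jacobian(self, default_weekly,
                                                     default_phantom):
        pct, _ = default_phantom
        _, truth = default_weekly
        deform = truth.deformations[0]
        inv_field = da.invert_dvf(truth.dvf_true[0], tol_mm=0.005)  # forward map
        rep = da.jacobian_determinant(inv_field)
        rng = np.random.default_rng(11)
        idx = rng.integers((8, 8, 8), np.asarray(pct.grid.shape) - 8, (100, 3))
        pts = pct.grid.index_to_world(idx)
        analytic = deform.jacobian_det(pts)
        numeric = rep.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        # central differences at 5 mm spacing on a 50 mm-scale field
        assert np.abs(numeric - analytic).max() / analytic.max() < 0.05


class TestDeformable:
    def test_identity_registration_small_field(self):
        grid = Grid((32, 32, 24), (4.0, 4.0, 4.0))
        f = smooth_blob_volume(grid, np.random.default_rng(2), centers=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dvf = da.deformable_register(f, f, da.RegistrationParams(
                iterations=(10, 10, 10, 10)))
        assert dvf.magnitude().mean() <= 0.25 * min(grid.spacing)

    def test_contrast_scaled_checkerboard_yields_near_zero_field(self):
        grid = Grid((32, 32, 24), (4.0, 4.0, 4.0))
        xs, ys, zs = np.indices(grid.shape)
        board = (((xs // 4) + (ys // 4) + (zs // 4)) % 2).astype(float) * 100.0
        from scipy.ndimage import gaussian_filter

        board = gaussian_filter(board, 1.0)
        f = da.ImageVolume(grid, board)
        m = da.ImageVolume(grid, 0.8 * board)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dvf = da.deformable_register(
                f, m, da.RegistrationParams(metric="lncc", iterations=(10, 10, 10, 10))
            )
        assert dvf.magnitude().mean() <= 0.5 * min(grid.spacing)

    def test_phantom_pair_parameter_recovery(self, default_phantom, default_weekly,
                                             week1_registration):
        """Known analytic bladder-expansion field: registered landmarks must
        beat rigid-only by >= 2x and stay within 2 x max spacing."""
        pct, structs = default_phantom
        weekly, truth = default_weekly
        rigid, dvf = week1_registration
        moved = da.propagate(structs, dvf)
        per, mean_tre, _ = da.target_registration_error(
            moved.landmarks, truth.landmarks_true[0])
        max_sp = max(pct.grid.spacing)
        assert mean_tre <= 2.0 * max_sp
        # improvement over rigid-only is judged at the surface fiducials:
        # flat-interior centroids carry no intensity signal, so no
        # intensity-driven registration can beat rigid there
        shift = np.asarray(truth.deformations[0].shift_mm)
        surface = ["bladder_anterior", "bladder_superior"]
        rigid_err = np.mean([
            np.linalg.norm((structs.landmarks[n] + shift)
                           - truth.landmarks_true[0][n])
            for n in surface
        ])
        demons_err = np.mean([per[n] for n in surface])
        assert demons_err <= rigid_err / 1.5
        assert da.dice(moved.masks["bladder"],
                       truth.masks_true[0].masks["bladder"]) >= 0.85

    def test_field_regular_inside_body(self, default_phantom, week1_registration):
        pct, structs = default_phantom
        _, dvf = week1_registration
        rep = da.jacobian_determinant(dvf)
        body = structs.masks["body"]
        frac_pos = np.mean(rep.values[body] > 0)
        assert frac_pos >= 0.995

    def test_nan_metric_raises(self, small_grid):
        f = smooth_blob_volume(small_grid)
        bad = f.copy()
        bad.values[0, 0, 0] = np.nan
        with pytest.raises((FloatingPointError, ValueError)):
            da.deformable_register(f, bad, da.RegistrationParams(
                iterations=(2, 2, 2, 2)))
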