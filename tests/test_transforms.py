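"""Affine and B-spline FFD transforms, warping round-trips."""

import numpy as np
import pytest

from npvreg import (
    AffineTransform,
    ComposedTransform,
    Image,
    bspline_basis,
    ffd_apply,
    ffd_displacement,
    ffd_local_coords,
    make_ffd_grid,
    make_shape_phantom,
    resample_to_reference,
    warp_image,
)
from npvreg.errors import SpacingError


class TestAffine:
    def test_identity(self):
        t = AffineTransform.identity(2)
        p = np.array([[3.0, 4.0]])
        assert np.array_equal(t(p), p)

    def test_pure_translation(self):
        t = AffineTransform.from_translation((2.0, -1.0))
        assert np.array_equal(t(np.array([[0.0, 0.0]])), [[2.0, -1.0]])

    def test_rotation_90deg(self):
        t = AffineTransform.rotation_2d(90.0)
        out = t(np.array([[1.0, 0.0]]))[0]
        assert out == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_composition_associativity(self, rng):
        a = AffineTransform.rotation_2d(30.0, center=(5, 5))
        b = AffineTransform.from_translation((1.5, -2.5))
        p = rng.uniform(0, 10, size=(20, 2))
        assert np.allclose(a.compose(b)(p), a(b(p)), atol=1e-9)

    def test_inverse_round_trip(self, rng):
        t = AffineTransform.rotation_2d(17.0, center=(10, 12)).compose(
            AffineTransform.from_translation((3.0, -1.0))
        )
        p = rng.uniform(0, 20, size=(10, 2))
        assert np.allclose(t.inverse()(t(p)), p, atol=1e-9)

    def test_params_round_trip(self):
        t = AffineTransform.rotation_2d(33.0, center=(1, 2))
        back = AffineTransform.from_params(t.to_params(), 2)
        assert np.allclose(back.matrix, t.matrix)

    def test_singular_rejected(self):
        m = np.eye(3)
        m[0, 0] = 0.0
        m[0, 1] = 0.0
        with pytest.raises(ValueError):
            AffineTransform(m)


class TestBsplineBasis:
    def test_values_at_zero(self):
        b = bspline_basis(0.0)
        assert b == pytest.approx([1 / 6, 4 / 6, 1 / 6, 0.0], abs=1e-15)

    def test_values_at_half(self):
        b = bspline_basis(0.5)
        assert b == pytest.approx(
            [1 / 48, 23 / 48, 23 / 48, 1 / 48], abs=1e-12
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bspline_basis(1.0)
        with pytest.raises(ValueError):
            bspline_basis(-0.1)

    def test_partition_of_unity_dense(self):
        u = np.linspace(0, 1, 1001, endpoint=False)
        b = bspline_basis(u)
        assert np.max(np.abs(b.sum(axis=-1) - 1.0)) < 1e-12
        assert np.all(b >= 0)


class TestFFDGrid:
    def test_cell_counts(self):
        grid = make_ffd_grid((64, 64), 16)
        assert grid.n_cells == (4, 4)
        assert grid.control.shape == (7, 7, 2)  # n + 3 padding
        assert np.all(grid.control == 0)

    def test_single_cell(self):
        grid = make_ffd_grid((64, 64), 64)
        assert grid.n_cells == (1, 1)

    def test_non_divisor_rejected(self):
        with pytest.raises(SpacingError):
            make_ffd_grid((64, 64), 10)

    @pytest.mark.parametrize(
        "x, lam, i, u",
        [(0.0, 16, -1, 0.0), (24.0, 16, 0, 0.5), (16.0, 16, 0, 0.0)],
    )
    def test_local_coords(self, x, lam, i, u):
        grid = make_ffd_grid((64, 64), lam)
        idx, frac = ffd_local_coords((x, 0.0), grid)
        assert idx[0] == i
        assert frac[0] == pytest.approx(u)

    def test_local_coords_outside_extent(self):
        grid = make_ffd_grid((64, 64), 16)
        with pytest.raises(ValueError):
            ffd_local_coords((70.0, 0.0), grid)


class TestFFDApply:
    def test_zero_grid_is_identity(self, rng):
        grid = make_ffd_grid((64, 64), 16)
        pts = rng.uniform(0, 63, size=(50, 2))
        assert np.array_equal(ffd_apply(grid, pts), pts)

    def test_uniform_displacement_property(self):
        grid = make_ffd_grid((64, 64), 16)
        control = np.zeros_like(grid.control)
        control[..., 0] = 2.0
        control[..., 1] = -1.5
        grid = grid.with_control(control)
        pts = np.array([[8.0, 8.0], [32.0, 40.0], [55.5, 17.25]])
        out = ffd_apply(grid, pts)
        assert np.allclose(out, pts + [2.0, -1.5], atol=1e-12)

    def test_single_control_point_weight(self):
        # displacing one control point moves its own lattice location by
        # the tensor weight B1(0)^2 = (4/6)^2
        grid = make_ffd_grid((64, 64), 16)
        control = np.zeros_like(grid.control)
        # lattice index (1,1) -> storage (2,2); its location is x=(1+1)*16? no:
        # point x=32 has i=1, support indices i+l = 1..4 with u=0 giving
        # weights (1/6,4/6,1/6,0) on lattice 1..4 per axis
        control[2 + 1, 2 + 1, 0] = 8.0  # lattice (2,2), i.e. x=(32,32) center weight
        grid = grid.with_control(control)
        disp = ffd_displacement(grid, np.array([[32.0, 32.0]]))[0]
        assert disp[0] == pytest.approx(8.0 * (4 / 6) ** 2, abs=1e-12)

    def test_matches_brute_force_tensor_sum(self, rng):
        grid = make_ffd_grid((64, 64), 16)
        grid = grid.with_control(rng.uniform(-3, 3, size=grid.control.shape))
        pts = rng.uniform(0, 63.9, size=(25, 2))
        disp = ffd_displacement(grid, pts)
        for p, d in zip(pts, disp):
            idx, u = ffd_local_coords(p, grid)
            bu = bspline_basis(u[0])
            bv = bspline_basis(u[1])
            acc = np.zeros(2)
            for l in range(4):
                for m in range(4):
                    acc = acc + bu[l] * bv[m] * grid.control[
                        idx[0] + l + 1, idx[1] + m + 1
                    ]
            assert d == pytest.approx(acc, abs=1e-12)


class TestWarpImage:
    def test_identity_unchanged(self, rng):
        img = Image(data=rng.integers(0, 256, size=(16, 16)).astype(float))
        for interp in ("nearest", "linear"):
            assert np.array_equal(
                warp_image(img, AffineTransform.identity(2), interp).data, img.data
            )

    def test_integer_translation_nearest_is_shift(self):
        img = Image(data=np.arange(64.0).reshape(8, 8))
        t = AffineTransform.from_translation((2.0, 0.0))
        out = warp_image(img, t, "nearest")
        assert np.array_equal(out.data[:6], img.data[2:])
        assert np.all(out.data[6:] == 0)

    def test_half_voxel_linear_blend(self):
        data = np.zeros((8, 8))
        data[4:, :] = 100.0
        img = Image(data=data)
        t = AffineTransform.from_translation((0.5, 0.0))
        out = warp_image(img, t, "linear")
        assert np.all(out.data[3] == 50.0)
        assert np.all(out.data[4] == 100.0)

    def test_affine_round_trip_blur_bounded(self):
        from scipy.ndimage import gaussian_filter

        base = make_shape_phantom((64, 64), 3, seed=4)
        img = Image(data=gaussian_filter(base.data, 2.0))  # smooth phantom
        t = AffineTransform.rotation_2d(12.0, center=(31.5, 31.5))
        warped = warp_image(img, t, "linear")
        back = warp_image(warped, t.inverse(), "linear")
        interior = np.s_[8:-8, 8:-8]
        err = np.abs(back.data[interior] - img.data[interior])
        # mean error dominated by class-boundary blur
        assert err.mean() <= 2.0

    def test_displacement_field_export_round_trip(self, tmp_path, rng):
        import nibabel as nib

        from npvreg.transforms import export_displacement_field

        grid = make_ffd_grid((32, 32), 16)
        grid = grid.with_control(rng.uniform(-2, 2, size=grid.control.shape))
        t = ComposedTransform(AffineTransform.from_translation((1.0, 0.5)), grid)
        path = tmp_path / "field.nii.gz"
        field = export_displacement_field(t, (32, 32), path)
        back = np.asarray(nib.load(str(path)).dataobj)
        assert back.shape == (32, 32, 2)
        assert np.allclose(back, field, atol=1e-6)

    def test_resample_inverts_ffd_composition(self, rng):
        img = make_shape_phantom((64, 64), 3, seed=9)
        grid = make_ffd_grid((64, 64), 16)
        grid = grid.with_control(rng.uniform(-2, 2, size=grid.control.shape))
        t = ComposedTransform(AffineTransform.from_translation((1.0, -2.0)), grid)
        flt = warp_image(img, t, "linear")
        back = resample_to_reference(flt, t, shape=img.shape)
        interior = np.s_[8:-8, 8:-8]
        assert np.abs(back.data[interior] - img.data[interior]).mean() <= 4.0
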