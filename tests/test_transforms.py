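"""Affine/displacement transforms, composition, Jacobians, resampling."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from istg.interp import trilinear_sample
from istg.transforms import (
    AffineTransform,
    DisplacementField,
    Grid,
    TransformChain,
    apply_transform,
    compose,
    grid_world_coords,
    jacobian_determinant_map,
    polar_rotation,
    rotation_matrix,
)
from istg.volumes import TensorVolume, compute_fa, compute_md

from conftest import random_spd_field


def centered_affine(shape=(10, 10, 10), voxel=2.0):
    a = np.diag([voxel, voxel, voxel, 1.0])
    a[:3, 3] = -(np.array(shape) - 1) / 2.0 * voxel
    return a


class TestAffineTransform:
    def test_params_round_trip(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = np.concatenate(
                [
                    rng.uniform(-0.5, 0.5, 3),
                    rng.uniform(-10, 10, 3),
                    rng.uniform(-0.2, 0.2, 3),
                    rng.uniform(-0.2, 0.2, 3),
                ]
            )
            center = rng.uniform(-5, 5, 3)
            t = AffineTransform.from_params(p, center=center)
            np.testing.assert_allclose(t.to_params(center=center), p, atol=1e-10)

    def test_rigid_dof_enforces_rotation(self):
        with pytest.raises(ValueError, match="proper rotation"):
            AffineTransform(np.diag([1.5, 1.0, 1.0, 1.0]), dof=6)

    def test_inverse_composes_to_identity(self):
        t = AffineTransform.from_params([0.1, -0.2, 0.3, 1, 2, 3])
        m = t.matrix @ t.inverse().matrix
        np.testing.assert_allclose(m, np.eye(4), atol=1e-12)

    def test_polar_rotation_of_rotation_is_itself(self):
        R = rotation_matrix(0.3, -0.5, 1.0)
        np.testing.assert_allclose(polar_rotation(R[None])[0], R, atol=1e-12)


class TestCompose:
    def test_inverse_pair_gives_zero_field(self):
        grid = Grid((8, 8, 8), centered_affine((8, 8, 8)))
        A = AffineTransform.from_params([0.2, 0.1, -0.3, 2, -1, 3])
        field = compose([A, A.inverse()], grid)
        assert np.abs(field.displacement).max() <= 1e-6

    def test_translations_add(self):
        grid = Grid((6, 6, 6), centered_affine((6, 6, 6)))
        t1 = AffineTransform.from_params([0, 0, 0, 1.0, 2.0, 0])
        t2 = AffineTransform.from_params([0, 0, 0, -0.5, 1.0, 4.0])
        field = compose([t1, t2], grid)
        assert np.abs(
            field.displacement - np.array([0.5, 3.0, 4.0])
        ).max() <= 1e-12

    def test_chain_order_is_native_first(self):
        # phi_total = phi_1 o phi_2: scaling then translation in native space
        grid = Grid((4, 4, 4), np.eye(4))
        s = AffineTransform(np.diag([2.0, 1, 1, 1]))
        t = AffineTransform.from_params([0, 0, 0, 1.0, 0, 0])
        m = TransformChain([s, t]).affine_matrix()
        np.testing.assert_allclose(m, s.matrix @ t.matrix)


class TestJacobian:
    def test_identity_and_rigid_are_volume_preserving(self):
        grid = Grid((8, 8, 8), centered_affine((8, 8, 8)))
        for t in (
            AffineTransform.identity(),
            AffineTransform.from_params([0.3, -0.2, 0.5, 4, 1, -2]),
        ):
            jmap = jacobian_determinant_map([t], grid)
            np.testing.assert_allclose(jmap.values, 1.0, atol=1e-6)

    def test_anisotropic_scale(self):
        grid = Grid((6, 6, 6), centered_affine((6, 6, 6)))
        jmap = jacobian_determinant_map([AffineTransform(np.diag([1.2, 1, 1, 1.0]))], grid)
        np.testing.assert_allclose(jmap.values, 1.2, atol=1e-12)

    def test_affine_chain_determinant_is_product(self):
        grid = Grid((6, 6, 6), centered_affine((6, 6, 6)))
        a = AffineTransform(np.diag([1.2, 0.9, 1.0, 1.0]))
        b = AffineTransform.from_params([0.1, 0, 0, 1, 0, 0, 0.05, 0, -0.02, 0, 0, 0])
        jmap = jacobian_determinant_map([a, b], grid)
        want = np.linalg.det(a.linear) * np.linalg.det(b.linear)
        np.testing.assert_allclose(jmap.values, want, atol=1e-6)

    def test_displacement_field_jacobian_matches_analytic(self):
        # u_x = 0.1 * x gives det J = 1.1 away from boundaries
        shape = (12, 12, 12)
        grid = Grid(shape, centered_affine(shape))
        pts = grid_world_coords(grid)
        u = np.zeros(shape + (3,))
        u[..., 0] = 0.1 * pts[..., 0]
        field = DisplacementField(u, grid.affine)
        jmap = jacobian_determinant_map([field], grid)
        np.testing.assert_allclose(jmap.values[1:-1], 1.1, atol=1e-6)


class TestApplyTransform:
    def test_identity_preserves_tensors(self, phantom32):
        out = apply_transform(phantom32, [AffineTransform.identity()])
        interior = np.s_[2:-2, 2:-2, 2:-2]
        assert np.abs(out.tensors - phantom32.tensors)[interior].max() <= 1e-6

    def test_rz90_reorients_principal_axis(self):
        t6 = np.zeros((10, 10, 10, 6))
        t6[..., 0] = 2e-3
        t6[..., 2] = t6[..., 5] = 1e-3
        vol = TensorVolume(t6, centered_affine((10, 10, 10)))
        A = AffineTransform.from_params([0, 0, np.pi / 2, 0, 0, 0])
        out = apply_transform(vol, [A])
        interior = out.tensors[3:-3, 3:-3, 3:-3].reshape(-1, 6)
        np.testing.assert_allclose(
            interior.mean(axis=0), [1e-3, 0, 2e-3, 0, 0, 1e-3], atol=1e-9
        )

    def test_reorientation_preserves_eigenvalues(self, phantom32):
        A = AffineTransform.from_params([0.2, -0.1, 0.4, 1.0, -2.0, 0.5])
        out = apply_transform(phantom32, [A])
        # MD is rotation invariant: compare warped MD with MD warped as scalar
        md_warped = compute_md(out)
        md_then_warp = apply_transform(compute_md(phantom32), [A])
        brain = md_then_warp.values > 5e-4
        diff = np.abs(md_warped.values - md_then_warp.values)[brain]
        assert diff.mean() <= 2e-5

    def test_fa_commutes_with_rigid_warp(self, phantom32):
        A = AffineTransform.from_params([0.05, 0.02, np.deg2rad(7), 2.0, -1.0, 0.5])
        fa_of_warped = compute_fa(apply_transform(phantom32, [A]))
        warped_fa = apply_transform(compute_fa(phantom32), [A])
        interior = np.s_[3:-3, 3:-3, 3:-3]
        diff = np.abs(fa_of_warped.values - warped_fa.values)[interior]
        assert diff.mean() <= 0.02

    def test_composed_equals_sequential_resampling(self, phantom32):
        grid = Grid.of(phantom32)
        A = AffineTransform.from_params([0, 0, np.deg2rad(4), 1.5, 0, 0])
        rng = np.random.default_rng(0)
        u = np.zeros(grid.shape + (3,))
        for k in range(3):
            from scipy.ndimage import gaussian_filter

            u[..., k] = gaussian_filter(rng.standard_normal(grid.shape), 4.0)
        u *= 2.0 / np.abs(u).max()
        W = DisplacementField(u, grid.affine)
        one_shot = apply_transform(phantom32, [A, W], grid)
        sequential = apply_transform(apply_transform(phantom32, [A], grid), [W], grid)
        fa1 = compute_fa(one_shot).values
        fa2 = compute_fa(sequential).values
        interior = np.s_[3:-3, 3:-3, 3:-3]
        assert np.abs(fa1 - fa2)[interior].mean() <= 0.02

    def test_out_of_field_becomes_floor(self, phantom32):
        big = AffineTransform.from_params([0, 0, 0, 500.0, 0, 0])
        out = apply_transform(phantom32, [big])
        assert compute_md(out).values.max() <= 1e-11


class TestTrilinearSample:
    def test_matches_map_coordinates_inside(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((7, 8, 9, 2))
        pts = rng.uniform(0, 6, size=(200, 3))
        got = trilinear_sample(data, pts, cval=np.zeros(2))
        for c in range(2):
            want = map_coordinates(data[..., c], pts.T, order=1, mode="constant")
            np.testing.assert_allclose(got[:, c], want, atol=1e-12)

    def test_edge_clamp_matches_nearest_mode(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 5, 5, 1))
        pts = rng.uniform(-2, 7, size=(100, 3))
        got = trilinear_sample(data, pts, cval=None)
        want = map_coordinates(data[..., 0], pts.T, order=1, mode="nearest")
        np.testing.assert_allclose(got[:, 0], want, atol=1e-12)

    def test_constant_fill_outside(self):
        data = np.ones((4, 4, 4, 1))
        out = trilinear_sample(data, np.array([[10.0, 0, 0]]), cval=np.array([-7.0]))
        assert out[0, 0] == -7.0
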