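"""Transform algebra: resampling, exponentials, composition, inversion."""

import numpy as np
import pytest

from fetalatlas.core import (DisplacementField, DivergenceError, GridMismatchError,
                             RigidTransform, VelocityField, VolumetricImage,
                             compose, exponentiate, invert,
                             jacobian_determinant, resample)

from conftest import gradient_image, random_smooth_velocity

SHAPE = (16, 16, 16)
SP = np.ones(3)


def translation_field(shape, vec_mm):
    d = np.zeros(tuple(shape) + (3,), dtype=np.float32)
    d[...] = np.asarray(vec_mm, dtype=np.float32)
    return DisplacementField(d, SP)


class TestResample:
    def test_identity_returns_input(self):
        img = gradient_image(SHAPE)
        out = resample(img, DisplacementField.identity(SHAPE, SP))
        np.testing.assert_allclose(out.data, img.data, atol=1e-5)

    def test_one_voxel_translation_shifts_linear_ramp(self):
        img = gradient_image(SHAPE, axis=0, slope=2.5)
        out = resample(img, translation_field(SHAPE, (1.0, 0, 0)))
        # pull-back: out(i) = img(i+1) = 2.5 (i+1) for interior voxels
        np.testing.assert_allclose(out.data[:-1], img.data[:-1] + 2.5, atol=1e-4)

    def test_zero_image_stays_zero(self):
        img = VolumetricImage(np.zeros(SHAPE), SP)
        out = resample(img, translation_field(SHAPE, (0.7, -1.2, 0.3)))
        assert np.all(out.data == 0)

    def test_constant_preserved_in_interior(self):
        img = VolumetricImage(np.full(SHAPE, 5.0), SP)
        out = resample(img, translation_field(SHAPE, (0.5, 0.5, 0.5)))
        np.testing.assert_allclose(out.data[:-1, :-1, :-1], 5.0, atol=1e-5)

    def test_rigid_translation(self):
        img = gradient_image(SHAPE, axis=1)
        out = resample(img, RigidTransform(np.eye(3), (0, 2.0, 0)))
        np.testing.assert_allclose(out.data[:, :-2], img.data[:, :-2] + 2.0,
                                   atol=1e-4)

    def test_grid_mismatch_rejected(self):
        img = gradient_image(SHAPE)
        bad = DisplacementField.identity((8, 8, 8), SP)
        with pytest.raises(GridMismatchError):
            resample(img, bad, out_grid=img)


class TestExponentiate:
    def test_zero_velocity_is_identity(self):
        v = VelocityField.zeros(SHAPE, SP)
        d = exponentiate(v)
        assert np.all(d.vectors == 0)
        assert d.diffeomorphic

    def test_constant_velocity_is_translation(self):
        v = VelocityField.zeros(SHAPE, SP)
        v.vectors[...] = (0.8, 0, 0)
        d = exponentiate(v, steps=6)
        interior = d.vectors[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(
            interior, np.broadcast_to([0.8, 0, 0], interior.shape), atol=1e-3)

    def test_inverse_consistency(self, smooth_velocity_24):
        v = smooth_velocity_24
        rt = compose(exponentiate(v, 6), exponentiate(VelocityField(-v.vectors, v.spacing), 6))
        assert rt.mean_magnitude_voxels() < 0.1

    def test_converges_as_steps_double(self, smooth_velocity_24):
        prev = exponentiate(smooth_velocity_24, 3)
        cur = exponentiate(smooth_velocity_24, 6)
        diff = np.sqrt(((prev.vectors - cur.vectors) ** 2).sum(-1)).mean()
        assert diff < 0.05

    def test_jacobian_positive(self, smooth_velocity_24):
        jac = jacobian_determinant(exponentiate(smooth_velocity_24, 6))
        assert jac.data.min() > 0

    def test_rejects_bad_steps(self, smooth_velocity_24):
        with pytest.raises(ValueError):
            exponentiate(smooth_velocity_24, 0)


class TestCompose:
    def test_identity_neutral(self):
        d = exponentiate(random_smooth_velocity(SHAPE, SP, seed=5))
        ident = DisplacementField.identity(SHAPE, SP)
        for c in (compose(ident, d), compose(d, ident)):
            np.testing.assert_allclose(c.vectors, d.vectors, atol=1e-4)

    def test_translations_add(self):
        a = translation_field(SHAPE, (1.0, 0, 0))
        b = translation_field(SHAPE, (0, 2.0, 0))
        got = compose(a, b).vectors[2:-2, 2:-4, 2:-2]
        np.testing.assert_allclose(
            got, np.broadcast_to([1.0, 2.0, 0.0], got.shape), atol=1e-4)

    def test_matches_sequential_resampling(self):
        img = gradient_image(SHAPE)
        d1 = exponentiate(random_smooth_velocity(SHAPE, SP, 0.5, seed=1))
        d2 = exponentiate(random_smooth_velocity(SHAPE, SP, 0.5, seed=2))
        via_compose = resample(img, compose(d1, d2))
        sequential = resample(resample(img, d1), d2)
        inner = (slice(3, -3),) * 3
        np.testing.assert_allclose(via_compose.data[inner],
                                   sequential.data[inner], atol=0.05)


class TestInvert:
    def test_identity(self):
        inv = invert(DisplacementField.identity(SHAPE, SP))
        assert np.abs(inv.vectors).max() < 1e-6

    def test_translation(self):
        inv = invert(translation_field(SHAPE, (1.5, 0, 0)))
        got = inv.vectors[3:-3, 3:-3, 3:-3]
        np.testing.assert_allclose(
            got, np.broadcast_to([-1.5, 0, 0], got.shape), atol=1e-3)

    def test_roundtrip_on_smooth_field(self, smooth_velocity_24):
        d = exponentiate(smooth_velocity_24, 6)
        inv = invert(d, iters=30, tol=1e-3)
        rt = compose(d, inv)
        mag_vox = rt.magnitude_mm()[4:-4, 4:-4, 4:-4]
        assert np.mean(mag_vox < 0.05) >= 0.99


class TestJacobian:
    def test_identity_is_one(self):
        jac = jacobian_determinant(DisplacementField.identity(SHAPE, SP))
        np.testing.assert_allclose(jac.data, 1.0, atol=1e-6)

    def test_uniform_expansion(self):
        idx = np.indices(SHAPE).astype(np.float32)
        center = (np.array(SHAPE) - 1) / 2
        vec = np.moveaxis(0.1 * (idx - center.reshape(3, 1, 1, 1)), 0, -1)
        jac = jacobian_determinant(DisplacementField(vec, SP))
        np.testing.assert_allclose(jac.data[2:-2, 2:-2, 2:-2], 1.1 ** 3,
                                   rtol=1e-3)


class TestValidation:
    def test_nonfinite_rejected(self):
        data = np.zeros(SHAPE)
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            VolumetricImage(data, SP)

    def test_rigid_requires_proper_rotation(self):
        refl = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            RigidTransform(refl, np.zeros(3))
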