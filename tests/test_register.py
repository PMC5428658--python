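"""Metric properties, rigid pre-alignment, and deformable registration."""

import numpy as np
import pytest

from fetalatlas.core import GridMismatchError, RigidTransform, VolumetricImage, compose
from fetalatlas.phantom import GrowthPhantomSpec, canonical_image, make_subject
from fetalatlas.register import (RegistrationConfig, moments_rigid, ncc_cost,
                                 rigid_mi, symmetric_diffeo_register)


@pytest.fixture(scope="module")
def canon():
    return canonical_image(GrowthPhantomSpec(), 30.0)


class TestNccCost:
    def test_self_similarity_is_minus_one(self, canon):
        assert ncc_cost(canon, canon) == pytest.approx(-1.0, abs=1e-6)

    def test_constant_image_scores_zero(self, canon):
        flat = canon.like(np.full(canon.shape, 7.0, dtype=np.float32))
        assert ncc_cost(canon, flat) == 0.0

    def test_affine_intensity_invariance(self, canon):
        remapped = canon.like(2.0 * canon.data + 3.0)
        assert ncc_cost(canon, remapped) == pytest.approx(-1.0, abs=1e-5)

    def test_bounded(self, canon):
        rng = np.random.default_rng(0)
        other = canon.like(rng.normal(300, 100, canon.shape).astype(np.float32))
        c = ncc_cost(canon, other)
        assert -1.0 <= c <= 0.0

    def test_grid_mismatch(self, canon):
        small = VolumetricImage(np.zeros((8, 8, 8)), np.ones(3))
        with pytest.raises(GridMismatchError):
            ncc_cost(canon, small)


class TestMomentsRigid:
    def test_identical_images_identity(self, canon):
        t = moments_rigid(canon, canon)
        assert np.allclose(t.translation_mm, 0, atol=1e-6)
        assert np.allclose(t.rotation, np.eye(3))

    def test_known_shift_recovered(self, canon):
        shifted = canon.like(np.roll(canon.data, 3, axis=0))  # content moved +3mm
        t = moments_rigid(shifted, canon)
        assert abs(t.translation_mm[0] - 3.0) < 0.1
        assert np.allclose(t.translation_mm[1:], 0, atol=0.1)

    def test_intensity_scale_invariance(self, canon):
        shifted = canon.like(np.roll(canon.data, 3, axis=0))
        bright = shifted.like(5.0 * shifted.data)
        t1 = moments_rigid(shifted, canon)
        t2 = moments_rigid(bright, canon)
        assert np.allclose(t1.translation_mm, t2.translation_mm, atol=1e-6)

    def test_zero_mass_rejected(self, canon):
        empty = canon.like(np.zeros(canon.shape, dtype=np.float32))
        with pytest.raises(ValueError):
            moments_rigid(empty, canon)


class TestRigidMI:
    def test_self_registration_near_identity(self, canon):
        res = rigid_mi(canon, canon)
        angle = np.degrees(np.arccos(np.clip(
            (np.trace(res.transform.rotation) - 1) / 2, -1, 1)))
        assert angle < 0.5
        assert np.linalg.norm(res.transform.translation_mm) < 0.2

    def test_known_rotation_recovered(self):
        # a rotationally asymmetric target (anisotropic ellipsoid plus an
        # off-axis marker); the near-spherical brain phantom has too
        # shallow a rotational MI landscape to localize small angles
        n = 48
        ax = np.arange(n) - (n - 1) / 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        data = np.where((x / 16) ** 2 + (y / 10) ** 2 + (z / 8) ** 2 <= 1,
                        300.0, 0.0)
        data += np.where((x - 8) ** 2 + (y - 4) ** 2 + z ** 2 <= 9, 500.0, 0.0)
        img = VolumetricImage(data.astype(np.float32), np.ones(3))

        from fetalatlas.core import resample
        th = np.radians(5.0)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        center = (np.asarray(img.shape) - 1) / 2 * img.spacing
        t = center - rot @ center
        moved = resample(img, RigidTransform(rot, t))
        res = rigid_mi(moved, img, moments_rigid(moved, img))
        angle = np.degrees(np.arccos(np.clip(
            (np.trace(res.transform.rotation) - 1) / 2, -1, 1)))
        assert abs(angle - 5.0) < 1.0

    def test_disjoint_images_flagged(self):
        a = np.zeros((24, 24, 24), dtype=np.float32)
        b = np.zeros((24, 24, 24), dtype=np.float32)
        a[2:6, 2:6, 2:6] = 100.0
        b[18:22, 18:22, 18:22] = 100.0
        res = rigid_mi(VolumetricImage(a, np.ones(3)),
                       VolumetricImage(b, np.ones(3)))
        # either flagged, or at minimum it did not fabricate an improvement
        assert res.warning or res.mi_after <= res.mi_before + 1e-6


class TestSymmetricDiffeo:
    @pytest.fixture(scope="class")
    def pair(self):
        spec = GrowthPhantomSpec()
        fixed = canonical_image(spec, 30.0)
        subj = make_subject(spec, 30.0, 7)
        return fixed, subj

    @pytest.fixture(scope="class")
    def result(self, pair):
        fixed, subj = pair
        return symmetric_diffeo_register(fixed, subj.image)

    def test_self_registration_small(self, pair):
        fixed, _ = pair
        res = symmetric_diffeo_register(fixed, fixed)
        assert res.forward.mean_magnitude_voxels() < 0.1

    def test_ground_truth_recovery(self, pair, result):
        _, subj = pair
        resid = compose(subj.ground_truth_deformation, result.forward)
        mag = resid.magnitude_mm()[6:-6, 6:-6, 6:-6]
        assert mag.mean() < 0.5

    def test_inverse_consistency(self, result):
        rt = compose(result.forward, result.inverse)
        assert rt.mean_magnitude_voxels() < 0.1

    def test_jacobian_positive(self, result):
        from fetalatlas.core import jacobian_determinant
        assert jacobian_determinant(result.forward).data.min() > 0

    def test_swap_gives_inverse(self, pair, result):
        fixed, subj = pair
        swapped = symmetric_diffeo_register(subj.image, fixed)
        diff = result.forward_velocity.vectors + swapped.forward_velocity.vectors
        assert np.sqrt((diff ** 2).sum(-1)).mean() < 0.2

    def test_cost_decreases_within_levels(self, result):
        # per level the recorded best cost must not exceed the starting cost
        ofs = 0
        for n in result.iterations_run:
            seg = result.cost_history[ofs:ofs + n]
            ofs += n
            if len(seg) >= 2:
                assert min(seg) <= seg[0] + 1e-3

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            RegistrationConfig(iters_per_level=(10, 10), pyramid_factors=(4, 2, 1))
        with pytest.raises(ValueError):
            RegistrationConfig(cc_window_voxels=4)
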