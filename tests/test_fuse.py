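"""Label propagation, STAPLE fusion, clustering, PV correction."""

import numpy as np
import pytest

from fetalatlas.core import DisplacementField, VolumetricImage
from fetalatlas.fuse import (ProbLabelImage, intensity_cluster, one_hot,
                             propagate_labels, pv_correct, staple_fuse)


def crisp(cfg, shape=(2, 2, 1)):
    arr = np.asarray(cfg).reshape(shape)
    return one_hot(arr, label_set=[0, 1])


class TestPropagateLabels:
    def test_identity_is_one_hot(self):
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[2:4, 2:4, 2:4] = 3
        ident = DisplacementField.identity(labels.shape, np.ones(3))
        p = propagate_labels(labels, ident)
        assert p.label_set == [0, 3]
        np.testing.assert_allclose(p.probs[..., 1], (labels == 3).astype(float),
                                   atol=1e-6)

    def test_half_voxel_shift_splits_boundary(self):
        labels = np.zeros((8, 4, 4), dtype=np.int16)
        labels[4:] = 1
        d = DisplacementField.identity(labels.shape, np.ones(3))
        d.vectors[..., 0] = 0.5
        p = propagate_labels(labels, d)
        # the voxel at index 3 now samples the 3.5 position: half each label
        np.testing.assert_allclose(p.probs[3, 1, 1], [0.5, 0.5], atol=1e-6)

    def test_single_label_input(self):
        labels = np.full((5, 5, 5), 2, dtype=np.int16)
        d = DisplacementField.identity(labels.shape, np.ones(3))
        d.vectors[..., 1] = 0.3
        p = propagate_labels(labels, d)
        assert p.label_set == [2]
        np.testing.assert_allclose(p.probs[..., 0], 1.0)


class TestStapleFuse:
    def test_unanimous_raters_reproduced(self):
        seg = crisp((0, 1, 1, 0))
        m = staple_fuse([seg, seg, seg], block_size=0)
        assert tuple(m.hard_labels().ravel()) == (0, 1, 1, 0)
        # confusion matrices near identity
        theta = m.performance.reshape(3, 2, 2)
        assert (np.diagonal(theta, axis1=1, axis2=2) > 0.9).all()

    def test_single_rater_passthrough(self):
        probs = np.array([[[[0.7, 0.3]]], [[[0.2, 0.8]]]], dtype=np.float32)
        seg = ProbLabelImage(probs, [0, 1])
        m = staple_fuse([seg], prior="uniform", block_size=0)
        hard = m.hard_labels().ravel()
        assert tuple(hard) == (0, 1)

    def test_inverted_rater_downweighted(self):
        # 3 raters on a 4x4x1 toy; one rater is inverted
        rng = np.random.default_rng(0)
        truth = (rng.random((4, 4, 1)) > 0.5).astype(np.int16)
        good = one_hot(truth, [0, 1])
        inverted = one_hot(1 - truth, [0, 1])
        m = staple_fuse([good, good, inverted], block_size=0)
        assert np.array_equal(m.hard_labels(), truth)
        theta_inv = m.performance.reshape(3, 2, 2)[2]
        assert theta_inv[0, 1] > theta_inv[0, 0]
        assert theta_inv[1, 0] > theta_inv[1, 1]

    def test_loglikelihood_monotone(self):
        rng = np.random.default_rng(3)
        segs = []
        for _ in range(3):
            p = rng.random((4, 4, 2, 2)).astype(np.float32)
            p /= p.sum(-1, keepdims=True)
            segs.append(ProbLabelImage(p, [0, 1]))
        m = staple_fuse(segs, block_size=2)
        h = np.asarray(m.log_likelihood_history)
        assert np.all(np.diff(h) >= -1e-8)

    def test_rater_order_invariance(self):
        rng = np.random.default_rng(4)
        segs = []
        for _ in range(3):
            p = rng.random((3, 3, 3, 2)).astype(np.float32)
            p /= p.sum(-1, keepdims=True)
            segs.append(ProbLabelImage(p, [0, 1]))
        m1 = staple_fuse(segs, block_size=0)
        m2 = staple_fuse(segs[::-1], block_size=0)
        np.testing.assert_array_equal(m1.posterior.probs, m2.posterior.probs)

    def test_duplicate_rater_strengthens_consensus(self):
        rng = np.random.default_rng(5)
        truth = (rng.random((4, 4, 1)) > 0.5).astype(np.int16)
        a = one_hot(truth, [0, 1])
        noisy = truth.copy()
        noisy[0, 0, 0] = 1 - noisy[0, 0, 0]
        b = one_hot(noisy, [0, 1])
        base = staple_fuse([a, b], block_size=0)
        dup = staple_fuse([a, b, a], block_size=0)
        agree_base = (base.hard_labels() == truth).mean()
        agree_dup = (dup.hard_labels() == truth).mean()
        assert agree_dup >= agree_base

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            staple_fuse([])

    def test_mismatched_label_sets_rejected(self):
        a = crisp((0, 1, 1, 0))
        b = one_hot(np.full((2, 2, 1), 2, dtype=np.int16))
        with pytest.raises(ValueError):
            staple_fuse([a, b])


class TestIntensityCluster:
    def test_two_separated_regions(self):
        data = np.zeros((6, 6, 6), dtype=np.float32)
        data[3:] = 100.0
        img = VolumetricImage(data + np.linspace(0, 1, 216).reshape(6, 6, 6),
                              np.ones(3))
        p = intensity_cluster(img, k=2)
        hard = p.hard_labels()
        assert (hard[:3] == 0).all() and (hard[3:] == 1).all()

    def test_gaussian_mixture_parameter_recovery(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(100, 10, 2500),
                               rng.normal(200, 10, 2500)])
        img = VolumetricImage(vals.reshape(10, 10, 50).astype(np.float32),
                              np.ones(3))
        p = intensity_cluster(img, k=2)
        m0 = img.data[p.hard_labels() == 0].mean()
        m1 = img.data[p.hard_labels() == 1].mean()
        assert abs(m0 - 100) < 3 or abs(m0 - 100) < 3 * 1.5
        assert abs(m1 - 200) < 3.5

    def test_too_few_distinct_values_rejected(self):
        img = VolumetricImage(np.zeros((4, 4, 4)), np.ones(3))
        with pytest.raises(ValueError):
            intensity_cluster(img, k=3)


class TestPvCorrect:
    def _phantom(self):
        labels = np.zeros((10, 6, 6), dtype=np.int16)
        labels[5:] = 2
        labels[:5] = 1
        data = np.where(labels == 1, 400.0, 280.0).astype(np.float32)
        return labels, VolumetricImage(data, np.ones(3))

    def test_noiseless_unchanged(self):
        labels, img = self._phantom()
        out = pv_correct(labels, img, [(1, 2)])
        assert np.array_equal(out, labels)

    def test_biased_boundary_voxels_reassigned(self):
        labels, img = self._phantom()
        # boundary voxels labeled 2 but with intensities near label 1's mean
        img.data[5, :, :] = 390.0
        out = pv_correct(labels, img, [(1, 2)])
        assert (out[5] == 1).all()
        # interior untouched
        assert (out[8] == 2).all() and (out[1] == 1).all()

    def test_empty_pair_list_identity(self):
        labels, img = self._phantom()
        assert np.array_equal(pv_correct(labels, img, []), labels)

    def test_absent_label_skipped_with_warning(self):
        labels, img = self._phantom()
        with pytest.warns(UserWarning):
            out = pv_correct(labels, img, [(1, 9)])
        assert np.array_equal(out, labels)
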