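"""Shared fixtures: small grids and phantom cohorts sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from fetalatlas.core import VelocityField, VolumetricImage, smooth_vectors
from fetalatlas.phantom import GrowthPhantomSpec, make_subject


@pytest.fixture(scope="session")
def default_spec() -> GrowthPhantomSpec:
    return GrowthPhantomSpec()


@pytest.fixture(scope="session")
def clean_spec() -> GrowthPhantomSpec:
    """Zero-noise, zero-deformation phantom settings."""
    return GrowthPhantomSpec(noise_sd=0.0, deform_magnitude_mm=0.0)


@pytest.fixture(scope="session")
def subject_30(default_spec):
    return make_subject(default_spec, 30.0, 7)


def random_smooth_velocity(shape, spacing, magnitude_mm=1.0, sigma_vox=4.0,
                           seed=0) -> VelocityField:
    rng = np.random.default_rng(seed)
    v = smooth_vectors(rng.standard_normal(tuple(shape) + (3,)).astype(np.float32),
                       sigma_vox)
    rms = np.sqrt((v ** 2).sum(-1).mean())
    if rms > 0:
        v *= magnitude_mm / rms
    return VelocityField(v, spacing)


@pytest.fixture()
def smooth_velocity_24():
    return random_smooth_velocity((24, 24, 24), np.ones(3), seed=3)


def gradient_image(shape=(16, 16, 16), axis=0, slope=1.0) -> VolumetricImage:
    idx = np.indices(shape).astype(np.float32)
    return VolumetricImage(slope * idx[axis], np.ones(3))
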