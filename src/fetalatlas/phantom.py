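"""Age-parameterized labeled 3-D brain phantoms.

The canonical anatomy is analytic so that structure volumes have closed
forms (free oracles for the atlas pipeline):

* label 1, "white matter": a sphere of radius ``r1(age)`` centred in the
  field of view, minus the structures carved out of it;
* label 2, "cortex ribbon": a shell of thickness ``t2(age)`` outside the
  white-matter sphere, whose inner and outer boundaries are perturbed by
  a fixed angular pattern with an amplitude that grows linearly with age
  (a crude stand-in for gyrification);
* label 3, "ventricles": two unperturbed spheres of radius ``r3(age)``;
* labels 4/5, "deep nucleus L/R": two spheres of radius ``r45(age)``;
* label 6, "thin commissure": an axis-aligned bar of half-width
  ``w6(age)`` (two voxels wide at default settings) between the nuclei.

All radii grow linearly: ``r(age) = baseline + rate * (age - 30)`` with
30 weeks as the reference age.  Subjects are the canonical anatomy warped
by a random diffeomorphism (the exponential of a Gaussian-smoothed random
velocity field) with additive noise and an optional low-order bias field.
Intensities are T2-like: CSF-filled ventricles are the brightest tissue,
which anchors the intensity-normalization convention used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (DisplacementField, VelocityField, VolumetricImage,
                   exponentiate, resample, smooth_vectors)

REFERENCE_AGE_WEEKS = 30.0

#: label id -> (baseline size at 30 wk [mm], linear growth [mm/week])
DEFAULT_STRUCTURE_PARAMS: dict[int, tuple[float, float]] = {
    0: (0.0, 0.0),        # background (reserved)
    1: (14.0, 0.20),      # white-matter sphere radius
    2: (2.5, 0.03),       # cortical-ribbon thickness
    3: (2.8, 0.10),       # ventricle radius (each of two spheres)
    4: (2.2, 0.05),       # deep nucleus L radius
    5: (2.2, 0.05),       # deep nucleus R radius
    6: (1.0, 0.01),       # commissure half-width
}

DEFAULT_INTENSITY_MEANS: dict[int, float] = {
    0: 0.0, 1: 400.0, 2: 280.0, 3: 1000.0, 4: 560.0, 5: 560.0, 6: 180.0,
}

LABEL_NAMES: dict[int, str] = {
    0: "background", 1: "white matter", 2: "cortex ribbon", 3: "ventricles",
    4: "deep nucleus L", 5: "deep nucleus R", 6: "thin commissure",
}

_VENTRICLE_CENTERS = ((0.0, 4.5, 2.0), (0.0, -4.5, 2.0))
_NUCLEUS_CENTERS = {4: (6.0, 0.0, -2.0), 5: (-6.0, 0.0, -2.0)}
_COMMISSURE_HALF_LENGTH = 3.0
_COMMISSURE_AXIS_Z = -2.0
_FOLDING_FREQ = 3.0 * np.pi


@dataclass
class GrowthPhantomSpec:
    """Parameters of the growth-phantom cohort generator."""

    grid_size: int = 48
    spacing_mm: float = 1.0
    age_range_weeks: tuple[float, float] = (19.0, 39.0)
    structure_params: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_PARAMS))
    folding_amplitude_per_week: float = 0.05
    deform_sigma_mm: float = 8.0
    deform_magnitude_mm: float = 1.0
    noise_sd: float = 20.0
    bias_amplitude: float = 0.0
    intensity_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS))

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size must be at least 8 voxels")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        lo, hi = self.age_range_weeks
        if not lo < hi:
            raise ValueError("age range must be increasing")
        for lbl, (r0, _) in self.structure_params.items():
            if lbl != 0 and r0 <= 0:
                raise ValueError(f"structure {lbl} needs a positive baseline size")

    def radius(self, label: int, age: float) -> float:
        r0, rate = self.structure_params[label]
        return r0 + rate * (age - REFERENCE_AGE_WEEKS)

    @property
    def labels(self) -> list[int]:
        return sorted(k for k in self.structure_params if k != 0)


@dataclass
class SubjectRecord:
    """One cohort member: image, age, optional labels, and (for phantoms)
    the ground-truth diffeomorphism that produced it."""

    subject_id: str
    age_weeks: float
    image: VolumetricImage
    labels: np.ndarray | None = None
    ground_truth_deformation: DisplacementField | None = None


def _coords_mm(spec: GrowthPhantomSpec) -> np.ndarray:
    n, s = spec.grid_size, spec.spacing_mm
    center = (n - 1) / 2.0 * s
    ax = np.arange(n) * s - center
    return np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)


def canonical_labels(spec: GrowthPhantomSpec, age: float) -> np.ndarray:
    """Rasterize the analytic anatomy at ``age`` (no noise, no deformation)."""
    xyz = _coords_mm(spec)
    r = np.sqrt(np.sum(xyz ** 2, axis=-1))
    with np.errstate(invalid="ignore"):
        u = np.where(r[..., None] > 0, xyz / np.maximum(r[..., None], 1e-9), 0.0)

    amp = spec.folding_amplitude_per_week * (age - spec.age_range_weeks[0])
    fold = amp * (np.sin(_FOLDING_FREQ * u[..., 0])
                  + np.sin(_FOLDING_FREQ * u[..., 1])
                  + np.sin(_FOLDING_FREQ * u[..., 2])) / 3.0

    r1 = spec.radius(1, age)
    t2 = spec.radius(2, age)
    labels = np.zeros(xyz.shape[:3], dtype=np.int16)
    labels[r <= r1 + t2 + fold] = 2
    labels[r <= r1 + fold] = 1

    for cx, cy, cz in _VENTRICLE_CENTERS:
        d = np.sqrt((xyz[..., 0] - cx) ** 2 + (xyz[..., 1] - cy) ** 2
                    + (xyz[..., 2] - cz) ** 2)
        labels[(d <= spec.radius(3, age)) & (labels == 1)] = 3
    for lbl, (cx, cy, cz) in _NUCLEUS_CENTERS.items():
        d = np.sqrt((xyz[..., 0] - cx) ** 2 + (xyz[..., 1] - cy) ** 2
                    + (xyz[..., 2] - cz) ** 2)
        labels[(d <= spec.radius(lbl, age)) & (labels == 1)] = lbl

    w6 = spec.radius(6, age)
    bar = ((np.abs(xyz[..., 0]) <= _COMMISSURE_HALF_LENGTH)
           & (np.abs(xyz[..., 1]) <= w6)
           & (np.abs(xyz[..., 2] - _COMMISSURE_AXIS_Z) <= w6))
    labels[bar & (labels == 1)] = 6
    return labels


def canonical_image(spec: GrowthPhantomSpec, age: float) -> VolumetricImage:
    labels = canonical_labels(spec, age)
    lut = np.zeros(max(spec.intensity_means) + 1, dtype=np.float32)
    for lbl, mean in spec.intensity_means.items():
        lut[lbl] = mean
    data = lut[labels]
    return VolumetricImage(data, np.full(3, spec.spacing_mm))


def analytic_volume(spec: GrowthPhantomSpec, label: int, age: float) -> float:
    """Closed-form volume (mm^3) of an unperturbed spherical structure."""
    if label == 3:
        return 2 * (4.0 / 3.0) * np.pi * spec.radius(3, age) ** 3
    if label in (4, 5):
        return (4.0 / 3.0) * np.pi * spec.radius(label, age) ** 3
    raise ValueError(f"no closed-form volume for label {label}")


def _random_deformation(spec: GrowthPhantomSpec, age: float,
                        rng: np.random.Generator) -> DisplacementField:
    """Random diffeomorphism emulating inter-subject anatomical variability.

    A white-noise velocity field is smoothed to the stated correlation
    length, windowed to the anatomy (variability deforms tissue, not air),
    scaled to the stated RMS magnitude over the anatomy, and exponentiated.
    """
    shape = (spec.grid_size,) * 3
    noise = rng.standard_normal(shape + (3,)).astype(np.float32)
    sigma_vox = spec.deform_sigma_mm / spec.spacing_mm
    v = smooth_vectors(noise, sigma_vox)
    support = canonical_labels(spec, age) > 0
    window = ndimage.gaussian_filter(support.astype(np.float32),
                                     3.0 / spec.spacing_mm, mode="nearest")
    window /= max(window.max(), 1e-9)
    v *= window[..., None]
    rms = float(np.sqrt(np.mean(np.sum(v[support] ** 2, axis=-1)))) if support.any() else 0.0
    if rms > 0 and spec.deform_magnitude_mm > 0:
        v *= spec.deform_magnitude_mm / rms
    else:
        v[:] = 0.0
    vel = VelocityField(v, np.full(3, spec.spacing_mm))
    return exponentiate(vel, steps=6)


def _warp_labels(labels: np.ndarray, d: DisplacementField) -> np.ndarray:
    """Warp an integer label map by linear one-hot interpolation + argmax."""
    img = VolumetricImage(labels.astype(np.float32), d.spacing)
    ids = np.unique(labels)
    best = np.full(labels.shape, -np.inf, dtype=np.float32)
    out = np.zeros(labels.shape, dtype=labels.dtype)
    for lbl in ids:
        chan = resample(img.like((labels == lbl).astype(np.float32)), d,
                        fill=1.0 if lbl == 0 else 0.0)
        better = chan.data > best
        best[better] = chan.data[better]
        out[better] = lbl
    return out


def make_subject(spec: GrowthPhantomSpec, age: float, seed: int,
                 subject_id: str | None = None) -> SubjectRecord:
    """Generate one phantom subject: canonical anatomy at ``age``, randomly
    deformed, with noise and optional bias.  Deterministic in (spec, age, seed).
    """
    lo, hi = spec.age_range_weeks
    if not lo <= age <= hi:
        raise ValueError(f"age {age} weeks outside configured range [{lo}, {hi}]")
    if seed < 0:
        raise ValueError("seed must be non-negative")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    d = _random_deformation(spec, age, rng)
    clean = resample(canonical_image(spec, age), d)
    labels = _warp_labels(canonical_labels(spec, age), d)

    data = clean.data.astype(np.float32)
    if spec.bias_amplitude > 0:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        xyz = _coords_mm(spec)
        ramp = xyz @ direction
        ramp /= np.abs(ramp).max()
        data = data * (1.0 + spec.bias_amplitude * ramp.astype(np.float32))
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, data.shape).astype(np.float32)

    image = VolumetricImage(data, np.full(3, spec.spacing_mm))
    return SubjectRecord(subject_id or f"phantom-{seed}", float(age), image,
                         labels, ground_truth_deformation=d)


def _subject_seed(cohort_seed: int, index: int) -> int:
    # Mixing rule: affine hash of (cohort seed, 1-based index) modulo 2**31.
    # Keeps per-subject streams distinct and reproducible from one seed.
    return (cohort_seed * 1_000_003 + 7_919 * (index + 1)) % (2 ** 31)


def make_cohort(spec: GrowthPhantomSpec, n: int, seed: int,
                age_range: tuple[float, float] | None = None) -> list[SubjectRecord]:
    """Generate ``n`` subjects with ages uniform over the (sub)range."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    lo, hi = age_range if age_range is not None else spec.age_range_weeks
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    ages = rng.uniform(lo, hi, size=n)
    subjects = []
    for i, age in enumerate(ages):
        rec = make_subject(spec, float(age), _subject_seed(seed, i),
                           subject_id=f"S{i:03d}")
        subjects.append(rec)
    return subjects


def foreground_mask(labels: np.ndarray, dilate_voxels: int = 2) -> np.ndarray:
    """Brain mask: labeled voxels dilated by a small margin."""
    mask = labels > 0
    if dilate_voxels > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate_voxels)
    return mask
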