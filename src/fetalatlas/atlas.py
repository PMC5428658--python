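"""Age-kernel regression and unbiased spatiotemporal template estimation.

An atlas timepoint at gestational age ``t`` is a template image I(t) that
minimizes the kernel-weighted sum of registration costs to the cohort
images, with Gaussian weights K(t - t_i) over subject ages.  The estimate
is iterated: (1) register the current template to every retained subject;
(2) average the resulting stationary velocities with the kernel weights;
(3) rebuild the template as the weighted average of the subjects warped
into template space, then pull it back through the exponential of the
negated mean velocity, so that the weighted mean subject-to-template
transform is driven toward identity (the "unbiased" property).  The loop
stops when the mean velocity update over the brain foreground falls below
a tolerance (default 0.05 voxel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (DisplacementField, VelocityField, VolumetricImage,
                   compose, exponentiate, resample)
from .register import RegistrationConfig, symmetric_diffeo_register

DEFAULT_SIGMA_WEEKS = 1.0
DEFAULT_CUTOFF = 0.01


class NoSubjectsInKernelError(ValueError):
    """No cohort subject has a kernel weight above the cutoff at the query age."""


@dataclass
class KernelWeights:
    """Normalized Gaussian age-kernel weights at a query age."""

    query_age: float
    subject_ids: list[str]
    raw: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        assert abs(self.weights.sum() - 1.0) < 1e-12


def kernel_weights(t: float, ages, sigma: float = DEFAULT_SIGMA_WEEKS,
                   cutoff: float = DEFAULT_CUTOFF,
                   subject_ids: list[str] | None = None) -> KernelWeights:
    """Gaussian kernel weights ``exp(-(t - t_i)^2 / (2 sigma^2))``.

    Raw values are 1 at zero age distance; subjects at or below ``cutoff``
    are dropped (with the defaults this retains ages within about 3.03
    weeks) and the survivors are normalized to sum to one.
    """
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if subject_ids is None:
        subject_ids = [str(i) for i in range(ages.size)]
    raw = np.exp(-((t - ages) ** 2) / (2.0 * sigma ** 2))
    keep = raw > cutoff
    if not np.any(keep):
        raise NoSubjectsInKernelError(
            f"no subjects within the kernel support at age {t} weeks "
            f"(sigma={sigma}, cutoff={cutoff})")
    kept_raw = raw[keep]
    w = kept_raw / kept_raw.sum()
    # kill round-off so the sum-of-unity contract holds to 1e-12
    w = w / w.sum()
    ids = [sid for sid, k in zip(subject_ids, keep) if k]
    return KernelWeights(float(t), ids, kept_raw, w)


def normalize_intensity(image: VolumetricImage,
                        reference_percentile: float = 99.0,
                        target: float = 1000.0) -> VolumetricImage:
    """Linear intensity rescaling anchored on the bright-CSF end.

    The chosen high percentile of the positive voxels (standing in for the
    maximum CSF intensity) is mapped to ``target``; zeros stay zero.
    """
    data = np.asarray(image.data, dtype=np.float64)
    positive = data[data > 0]
    if positive.size == 0 or np.ptp(data) == 0:
        raise ValueError("cannot normalize a constant or non-positive image")
    ref = float(np.percentile(positive, reference_percentile))
    if ref <= 0:
        raise ValueError("reference percentile is non-positive")
    return image.like((data * (target / ref)).astype(np.float32))


@dataclass
class PerSubjectFit:
    velocity: VelocityField
    displacement: DisplacementField  # template -> subject pull-back map
    weight: float


@dataclass
class AtlasTimepoint:
    """One age point of the spatiotemporal atlas."""

    age: float
    template: VolumetricImage
    per_subject: dict[str, PerSubjectFit] = field(default_factory=dict)
    iterations_run: int = 0
    residual_history: list[float] = field(default_factory=list)
    labels: np.ndarray | None = None
    label_probs: np.ndarray | None = None
    label_set: list[int] | None = None
    weights: KernelWeights | None = None
    #: kernel-weighted mean velocity measured by the latest iteration,
    #: before the unbias correction was applied
    mean_velocity: VelocityField | None = None

    def mean_weighted_velocity(self) -> VelocityField | None:
        if not self.per_subject:
            return None
        acc = None
        for fit in self.per_subject.values():
            term = fit.weight * fit.velocity.vectors
            acc = term if acc is None else acc + term
        first = next(iter(self.per_subject.values())).velocity
        return VelocityField(acc, first.spacing.copy(), first.affine.copy())


def initialize_template(subjects, weights: KernelWeights) -> VolumetricImage:
    """Voxelwise weighted mean of (rigidly pre-aligned) subject images."""
    by_id = {s.subject_id: s for s in subjects}
    acc = None
    ref = None
    for sid, w in zip(weights.subject_ids, weights.weights):
        img = by_id[sid].image
        if ref is None:
            ref = img
        else:
            ref.require_same_grid(img, "cohort images")
        term = w * np.asarray(img.data, dtype=np.float64)
        acc = term if acc is None else acc + term
    return ref.like(acc.astype(np.float32))


def _foreground(template: VolumetricImage) -> np.ndarray:
    thresh = 0.02 * float(np.abs(template.data).max())
    mask = np.abs(template.data) > thresh
    return ndimage.binary_dilation(mask, iterations=2)


def atlas_iteration(tp: AtlasTimepoint, subjects,
                    config: RegistrationConfig | None = None,
                    warm_start: bool = True) -> AtlasTimepoint:
    """One outer iteration of the unbiased template loop.

    Registers the template to each retained subject, kernel-averages the
    velocities, rebuilds the template from the warped subjects and unbiases
    it by the inverse mean flow.  The appended residual measures the
    convergence of the mean transform: the mean magnitude (voxels, over the
    brain foreground) of the *change* in the kernel-weighted mean velocity
    relative to the previous iteration (relative to identity on the first).
    Individual registrations have a noise-driven error floor, so the mean
    velocity itself levels off at a small nonzero value; the iteration has
    converged when it stops changing.
    """
    if tp.weights is None:
        raise ValueError("timepoint carries no kernel weights")
    cfg = config or RegistrationConfig()
    by_id = {s.subject_id: s for s in subjects}
    fg = _foreground(tp.template)

    fits: dict[str, PerSubjectFit] = {}
    acc_vel = None
    for sid, w in zip(tp.weights.subject_ids, tp.weights.weights):
        subj = by_id[sid]
        init = tp.per_subject[sid].velocity if (warm_start and sid in tp.per_subject) else None
        try:
            res = symmetric_diffeo_register(tp.template, subj.image, cfg,
                                            init_velocity=init)
        except Exception as exc:
            raise RuntimeError(
                f"registration of subject {sid!r} failed: {exc}") from exc
        fits[sid] = PerSubjectFit(res.forward_velocity, res.forward, float(w))
        term_v = w * res.forward_velocity.vectors
        acc_vel = term_v if acc_vel is None else acc_vel + term_v

    spacing = tp.template.spacing
    vbar = VelocityField(acc_vel, spacing.copy(), tp.template.affine.copy())
    vox = float(np.prod(spacing) ** (1.0 / 3.0))
    prev = tp.mean_velocity.vectors if tp.mean_velocity is not None else 0.0
    delta = np.sqrt(((vbar.vectors - prev) ** 2).sum(-1))
    residual = float(delta[fg].mean() / vox)

    # fold the unbias correction into each subject's map, then rebuild the
    # template with a single interpolation per subject (resampling the
    # intermediate average a second time would blur it)
    unbias = exponentiate(-vbar, cfg.exp_steps)
    acc_img = None
    for sid, fit in fits.items():
        fit.displacement = compose(fit.displacement, unbias)
        fit.velocity = VelocityField(fit.velocity.vectors - vbar.vectors,
                                     spacing.copy())
        warped = resample(by_id[sid].image, fit.displacement)
        term_i = fit.weight * np.asarray(warped.data, dtype=np.float64)
        acc_img = term_i if acc_img is None else acc_img + term_i
    new_template = tp.template.like(acc_img.astype(np.float32))

    return AtlasTimepoint(tp.age, new_template, fits, tp.iterations_run + 1,
                          tp.residual_history + [residual],
                          weights=tp.weights, mean_velocity=vbar)


def build_atlas(subjects, t: float, config: RegistrationConfig | None = None,
                sigma: float = DEFAULT_SIGMA_WEEKS, cutoff: float = DEFAULT_CUTOFF,
                max_iters: int = 10, tol: float = 0.05,
                fuse_labels: bool = False) -> AtlasTimepoint:
    """Estimate the atlas at age ``t`` from a pre-aligned, intensity-
    normalized cohort.  Iterates :func:`atlas_iteration` until the mean
    velocity update drops below ``tol`` voxels or ``max_iters`` is reached.
    """
    # canonical subject order makes the whole build permutation-invariant
    subjects = sorted(subjects, key=lambda s: s.subject_id)
    ages = [s.age_weeks for s in subjects]
    ids = [s.subject_id for s in subjects]
    kw = kernel_weights(t, ages, sigma, cutoff, ids)
    template = initialize_template(subjects, kw)
    tp = AtlasTimepoint(t, template, weights=kw)
    for _ in range(max_iters):
        tp = atlas_iteration(tp, subjects, config)
        if tp.residual_history[-1] < tol:
            break
    if tp.per_subject:
        # final rendering pass: cubic interpolation preserves the sharpness
        # that repeated linear resampling would erode
        by_id = {s.subject_id: s for s in subjects}
        acc = None
        for sid, fit in tp.per_subject.items():
            warped = resample(by_id[sid].image, fit.displacement, order=3)
            term = fit.weight * np.asarray(warped.data, dtype=np.float64)
            acc = term if acc is None else acc + term
        tp.template = tp.template.like(np.maximum(acc, 0.0).astype(np.float32))
    if fuse_labels:
        fuse_template_labels(tp, subjects)
    return tp


def fuse_template_labels(tp: AtlasTimepoint, subjects) -> np.ndarray | None:
    """Kernel-weighted probabilistic label fusion in template space.

    Each retained subject's labels are propagated through its
    template-to-subject map and averaged with the kernel weights — the
    label-space analog of the weighted intensity averaging that defines the
    template.  Stores the probability maps (``label_probs``) and the argmax
    hard labels; returns the hard map.  (STAPLE fusion is used when
    segmenting individual subjects, where rater quality varies; here the
    raters are the same subjects that define the template, with known
    kernel weights.)
    """
    from .fuse import propagate_labels

    by_id = {s.subject_id: s for s in subjects}
    label_set = sorted({int(l) for s in subjects if s.labels is not None
                        for l in np.unique(s.labels)})
    acc = None
    total_w = 0.0
    for sid, w in zip(tp.weights.subject_ids, tp.weights.weights):
        subj = by_id[sid]
        if subj.labels is None:
            continue
        probs = propagate_labels(subj.labels, tp.per_subject[sid].displacement,
                                 label_set).probs
        acc = w * probs if acc is None else acc + w * probs
        total_w += w
    if acc is None:
        warnings.warn("no labeled subjects retained; template left unlabeled")
        return None
    acc /= total_w
    tp.label_probs = acc
    tp.label_set = label_set
    lut = np.asarray(label_set)
    tp.labels = lut[acc.argmax(-1)].astype(np.int16)
    return tp.labels


@dataclass
class TrajectoryResult:
    timepoints: list[AtlasTimepoint]
    errors: dict[float, str] = field(default_factory=dict)


def build_trajectory(subjects, t_values, config: RegistrationConfig | None = None,
                     fuse_labels: bool = True, **kwargs) -> TrajectoryResult:
    """Independent :func:`build_atlas` at each requested age.

    Per-timepoint failures are collected in ``errors`` rather than aborting
    the remaining ages (sparse ends of the age range raise kernel errors).
    """
    out = TrajectoryResult([])
    for t in t_values:
        try:
            out.timepoints.append(
                build_atlas(subjects, float(t), config,
                            fuse_labels=fuse_labels, **kwargs))
        except Exception as exc:
            out.errors[float(t)] = str(exc)
    return out


def structure_volumes(labels: np.ndarray, spacing,
                      label_ids=None) -> dict[int, float]:
    """Volume (mm^3) of each labeled structure in a hard label map."""
    vv = float(np.prod(np.asarray(spacing, dtype=float)))
    ids = label_ids if label_ids is not None else np.unique(labels)
    return {int(l): float(np.count_nonzero(labels == l) * vv)
            for l in ids if l != 0}


def soft_structure_volumes(tp: AtlasTimepoint) -> dict[int, float]:
    """Probabilistic structure volumes of a labeled atlas timepoint:
    the integral of each fused probability map.  Unlike hard argmax counts,
    these are unbiased for structures only a few voxels across."""
    if tp.label_probs is None:
        raise ValueError("timepoint has no fused label probabilities")
    vv = float(np.prod(tp.template.spacing))
    sums = tp.label_probs.reshape(-1, tp.label_probs.shape[-1]).sum(axis=0)
    return {int(l): float(s * vv)
            for l, s in zip(tp.label_set, sums) if l != 0}
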