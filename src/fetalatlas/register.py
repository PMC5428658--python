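"""Rigid pre-alignment and symmetric diffeomorphic registration.

The deformable scheme is a symmetric, log-domain fluid registration with a
local normalized cross-correlation (LNCC) metric.  Both images are deformed
toward their midpoint by a pair of stationary half-velocities; per
iteration the metric gradient on each side is smoothed with ``fluid_sigma``
(the fluid/update regularizer), robustly normalized so a typical active
vector moves ``step_size`` voxels (capped per voxel), accumulated, and the
accumulated half-velocity is smoothed with ``elastic_sigma`` (the
elastic/total regularizer).  The pair
of Gaussian regularizers is the practical stand-in for a Sobolev penalty on
the velocity.  The full fixed-to-moving velocity is the difference of the
half-velocities (first-order Baker-Campbell-Hausdorff), so forward and
inverse transforms are exact exponentials of one stationary field — which
is what makes the fields averageable during atlas construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (DisplacementField, VelocityField, VolumetricImage,
                   exponentiate, jacobian_determinant, resample,
                   smooth_vectors)

try:  # SimpleITK backs the mutual-information rigid refinement only.
    import SimpleITK as sitk
except ImportError:  # pragma: no cover
    sitk = None


@dataclass
class RegistrationConfig:
    """Settings for :func:`symmetric_diffeo_register`.

    Defaults follow the greedy symmetric scheme: cross-correlation cost,
    gradient step 0.05, Gaussian regularization (2, 0.05), and a
    100 x 100 x 20 coarse-to-fine iteration ceiling.
    """

    metric: str = "local-cross-correlation"
    cc_window_voxels: int = 5
    step_size: float = 0.05
    fluid_sigma: float = 2.0
    elastic_sigma: float = 0.05
    iters_per_level: tuple[int, ...] = (100, 100, 20)
    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    # 4 squarings resolve the short flows these cohorts need; raise for
    # larger deformations
    exp_steps: int = 4
    # metric-side smoothing of the finest-level images (voxels); the
    # coarser pyramid levels are already smoothed by decimation.  Damps
    # noise-driven forces without blurring the transforms themselves.
    image_sigma: float = 0.7
    # a level stops early once the best cost has not improved by a relative
    # plateau_tol within plateau_patience iterations
    plateau_tol: float = 1e-4
    plateau_patience: int = 3

    def __post_init__(self) -> None:
        if self.metric != "local-cross-correlation":
            raise ValueError(f"unsupported metric {self.metric!r}")
        if self.cc_window_voxels % 2 != 1:
            raise ValueError("cc_window_voxels must be odd")
        if self.fluid_sigma < 0 or self.elastic_sigma < 0:
            raise ValueError("regularization sigmas must be >= 0")
        if len(self.iters_per_level) != len(self.pyramid_factors):
            raise ValueError("iteration schedule must match the pyramid depth")


@dataclass
class RegistrationResult:
    forward_velocity: VelocityField
    forward: DisplacementField
    inverse: DisplacementField
    final_similarity: float
    iterations_run: list[int] = field(default_factory=list)
    cost_history: list[float] = field(default_factory=list)
    step_halvings: int = 0


# ---------------------------------------------------------------------------
# metric

def _local_moments(a: np.ndarray, b: np.ndarray, window: int):
    size = (window,) * 3
    mean = lambda x: ndimage.uniform_filter(x, size, mode="nearest")
    ma, mb = mean(a), mean(b)
    ac, bc = a - ma, b - mb
    s_ab = mean(ac * bc)
    s_aa = mean(ac * ac)
    s_bb = mean(bc * bc)
    return ac, bc, s_ab, s_aa, s_bb


def _var_floor(data: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Local-variance floor below which a window counts as signal-free.

    Combines a scale-invariant fraction of the global variance with a
    robust estimate of the noise variance (MAD of the residual from a
    3-voxel box mean), so that windows containing only noise do not
    contribute spurious correlation or forces.
    """
    base = 1e-6 * float(np.var(data)) + 1e-30
    # noise is estimated from the near-zero-intensity (air) voxels, which
    # carry no anatomy; structure edges would otherwise inflate the estimate
    amax = float(np.abs(data).max())
    if amax == 0:
        return base
    air = np.abs(data) <= 0.02 * amax
    if int(air.sum()) < 100:
        return base
    resid = data - ndimage.uniform_filter(data, 3, mode="nearest")
    noise_sd = 1.4826 * float(np.median(np.abs(resid[air])))
    return max(base, 4.0 * noise_sd ** 2)


def ncc_cost(a: VolumetricImage, b: VolumetricImage, window: int = 5,
             mask: np.ndarray | None = None) -> float:
    """Negative mean squared local NCC over the foreground, in [-1, 0].

    Windows where either image has (near-)zero local variance are excluded;
    if no window has signal the cost is 0.  Invariant to affine intensity
    maps of either image.
    """
    a.require_same_grid(b, "ncc_cost images")
    da = np.asarray(a.data, dtype=np.float32)
    db = np.asarray(b.data, dtype=np.float32)
    _, _, s_ab, s_aa, s_bb = _local_moments(da, db, window)
    valid = (s_aa > _var_floor(da, mask)) & (s_bb > _var_floor(db, mask))
    if mask is not None:
        valid &= mask
    if not np.any(valid):
        return 0.0
    cc2 = (s_ab[valid] ** 2) / (s_aa[valid] * s_bb[valid])
    return float(-np.clip(cc2, 0.0, 1.0).mean())


def _lncc_forces(f: np.ndarray, m: np.ndarray, window: int,
                 mask: np.ndarray | None,
                 eps_f: float | None = None, eps_m: float | None = None):
    """Pointwise LNCC ascent fields for the fixed and moving sides,
    plus the metric value on the masked region.

    Returns (g_f, g_m, cost): scalar fields that multiply the spatial
    gradient of the respective image to give the similarity gradient with
    respect to a perturbation of that image's deformation, and the
    negative mean cc^2 over the valid masked windows.
    """
    if eps_f is None:
        eps_f = _var_floor(f, mask)
    if eps_m is None:
        eps_m = _var_floor(m, mask)
    fc, mc, s_fm, s_ff, s_mm = _local_moments(f, m, window)
    valid = (s_ff > eps_f) & (s_mm > eps_m)
    if mask is not None:
        valid &= mask
    denom = np.where(valid, s_ff * s_mm, 1.0)
    common = np.where(valid, 2.0 * s_fm / denom, 0.0)
    g_m = common * (fc - np.where(valid, s_fm / np.maximum(s_mm, eps_m), 0.0) * mc)
    g_f = common * (mc - np.where(valid, s_fm / np.maximum(s_ff, eps_f), 0.0) * fc)
    if np.any(valid):
        cc2 = (s_fm[valid] ** 2) / denom[valid]
        cost = float(-np.clip(cc2, 0.0, 1.0).mean())
    else:
        cost = 0.0
    return g_f, g_m, cost


def _spatial_gradient(data: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    gx, gy, gz = np.gradient(data, *spacing)
    return np.stack([gx, gy, gz], axis=-1).astype(np.float32)


# ---------------------------------------------------------------------------
# rigid pre-alignment

def moments_rigid(moving: VolumetricImage, fixed: VolumetricImage) -> "RigidTransform":
    """Translation-only alignment of intensity centroids (identity rotation).

    The returned pull-back translation is ``centroid(moving) - centroid(fixed)``
    in world mm, so resampling ``moving`` through it centres it on ``fixed``.
    """
    from .core import RigidTransform

    def centroid(img: VolumetricImage) -> np.ndarray:
        w = np.abs(np.asarray(img.data, dtype=np.float64))
        total = w.sum()
        if total <= 0:
            raise ValueError("cannot compute moments of a zero-mass image")
        idx = np.indices(img.shape).reshape(3, -1)
        c_vox = (idx * w.reshape(1, -1)).sum(axis=1) / total
        return c_vox * img.spacing

    t = centroid(moving) - centroid(fixed)
    return RigidTransform(np.eye(3), t)


@dataclass
class RigidMIResult:
    transform: "RigidTransform"
    mi_before: float
    mi_after: float
    warning: bool = False


def _to_sitk(img: VolumetricImage):
    arr = np.ascontiguousarray(np.asarray(img.data, dtype=np.float32).transpose(2, 1, 0))
    im = sitk.GetImageFromArray(arr)
    im.SetSpacing(tuple(float(s) for s in img.spacing))
    return im


def rigid_mi(moving: VolumetricImage, fixed: VolumetricImage,
             init=None, bins: int = 32,
             shrink_factors=(4, 2, 1)) -> RigidMIResult:
    """Multiresolution Mattes mutual-information rigid refinement.

    Runs SimpleITK's registration framework with dense sampling (fully
    deterministic).  If the optimizer fails or worsens the metric, the
    initial transform is returned with ``warning=True``.
    """
    from .core import RigidTransform

    if init is None:
        init = RigidTransform.identity()

    def make_method():
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
        reg.SetMetricSamplingStrategy(reg.NONE)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetShrinkFactorsPerLevel(list(shrink_factors))
        reg.SetSmoothingSigmasPerLevel([f / 2.0 for f in shrink_factors])
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4, numberOfIterations=100,
            relaxationFactor=0.6)
        reg.SetOptimizerScalesFromPhysicalShift()
        return reg

    f_im, m_im = _to_sitk(fixed), _to_sitk(moving)
    # rotate about the image centre (estimating a rotation about the grid
    # corner is badly conditioned); our centre-free convention is restored
    # on the way out
    c = (np.asarray(fixed.shape) - 1) / 2.0 * fixed.spacing
    tx = sitk.Euler3DTransform()
    tx.SetCenter(tuple(c))
    tx.SetMatrix(tuple(init.rotation.ravel()))
    tx.SetTranslation(tuple((init.rotation - np.eye(3)) @ c
                            + init.translation_mm))

    try:
        mi_before = make_method().MetricEvaluate(f_im, m_im)
    except RuntimeError:
        mi_before = 0.0
    try:
        reg = make_method()
        reg.SetInitialTransform(tx, inPlace=False)
        out = reg.Execute(f_im, m_im)
        out = out.Downcast() if hasattr(out, "Downcast") else out
        if isinstance(out, sitk.CompositeTransform):
            out = out.GetNthTransform(0).Downcast()
        out = sitk.Euler3DTransform(out)
        ev = make_method()
        ev.SetInitialTransform(out, inPlace=False)
        # MetricEvaluate ignores SetInitialTransform; resample instead.
        moved = sitk.Resample(m_im, f_im, out, sitk.sitkLinear, 0.0)
        mi_after = make_method().MetricEvaluate(f_im, moved)
    except RuntimeError as exc:
        warnings.warn(f"rigid MI registration failed: {exc}")
        return RigidMIResult(init, mi_before, mi_before, warning=True)

    if mi_after > mi_before + 1e-12:  # Mattes metric: lower is better
        return RigidMIResult(init, mi_before, mi_before, warning=True)

    rot = np.array(out.GetMatrix()).reshape(3, 3)
    center = np.array(out.GetCenter())
    trans = np.array(out.GetTranslation())
    # fold the rotation centre into a centre-free (R, t) pair
    t = trans + center - rot @ center
    return RigidMIResult(RigidTransform(rot, t), mi_before, mi_after, False)


def _default_foreground(data: np.ndarray) -> np.ndarray:
    """Tissue support: a tenth of the robust intensity maximum separates
    tissue from air even in the presence of additive noise."""
    thresh = 0.1 * np.percentile(np.abs(data), 99.9)
    return np.abs(data) > max(thresh, 1e-6)


# ---------------------------------------------------------------------------
# pyramid helpers

def _downsample_image(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data.astype(np.float32)
    sm = ndimage.gaussian_filter(data.astype(np.float32), factor / 2.0,
                                 mode="nearest")
    return sm[::factor, ::factor, ::factor]


def _downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return mask
    return mask[::factor, ::factor, ::factor]


def _resize_vectors(vec: np.ndarray, new_shape) -> np.ndarray:
    if vec.shape[:3] == tuple(new_shape):
        return vec
    zoom = [n / o for n, o in zip(new_shape, vec.shape[:3])]
    out = np.empty(tuple(new_shape) + (3,), dtype=np.float32)
    for c in range(3):
        out[..., c] = ndimage.zoom(vec[..., c], zoom, order=1, mode="nearest",
                                   grid_mode=True)
    return out


# ---------------------------------------------------------------------------
# symmetric diffeomorphic registration

def symmetric_diffeo_register(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    config: RegistrationConfig | None = None,
    mask: np.ndarray | None = None,
    init_velocity: VelocityField | None = None,
) -> RegistrationResult:
    """Register ``moving`` to ``fixed``; both must share a grid.

    Returns a stationary velocity ``v`` such that
    ``resample(moving, exponentiate(v))`` approximates ``fixed``;
    ``exponentiate(-v)`` is the inverse map.  Swapping the two images
    negates ``v`` up to the method's tolerance (symmetry contract).

    ``mask`` restricts the metric to the foreground; if omitted it is the
    union of the two images' nonzero support dilated by 2 voxels.
    ``init_velocity`` warm-starts the solve (used by the atlas loop).
    """
    cfg = config or RegistrationConfig()
    fixed.require_same_grid(moving, "registration images")

    if mask is None:
        mask = _default_foreground(fixed.data) | _default_foreground(moving.data)
        mask = ndimage.binary_dilation(mask, iterations=2)

    full_shape = fixed.shape
    spacing = fixed.spacing
    step_size = cfg.step_size
    halvings = 0
    cost_history: list[float] = []
    iters_run: list[int] = []

    v_f = v_m = None  # half-velocity vector arrays at the current level
    if init_velocity is not None:
        v_m0 = init_velocity.vectors * 0.5
        v_f0 = -init_velocity.vectors * 0.5
    else:
        v_m0 = v_f0 = None

    for factor, max_iters in zip(cfg.pyramid_factors, cfg.iters_per_level):
        f_data = _downsample_image(np.asarray(fixed.data, np.float32), factor)
        m_data = _downsample_image(np.asarray(moving.data, np.float32), factor)
        if factor == 1 and cfg.image_sigma > 0:
            f_data = ndimage.gaussian_filter(f_data, cfg.image_sigma,
                                             mode="nearest")
            m_data = ndimage.gaussian_filter(m_data, cfg.image_sigma,
                                             mode="nearest")
        lvl_mask = _downsample_mask(mask, factor)
        lvl_shape = f_data.shape
        lvl_spacing = spacing * factor
        f_img = VolumetricImage(f_data, lvl_spacing)
        m_img = VolumetricImage(m_data, lvl_spacing)

        if v_f is None:
            if v_f0 is not None:
                v_f = _resize_vectors(v_f0, lvl_shape)
                v_m = _resize_vectors(v_m0, lvl_shape)
            else:
                v_f = np.zeros(lvl_shape + (3,), dtype=np.float32)
                v_m = np.zeros(lvl_shape + (3,), dtype=np.float32)
        else:
            v_f = _resize_vectors(v_f, lvl_shape)
            v_m = _resize_vectors(v_m, lvl_shape)

        # freeze the set of windows with usable local signal at this level:
        # evaluating the metric on a fixed region keeps the recorded cost
        # comparable across iterations
        eps_f = _var_floor(f_data, lvl_mask)
        eps_m = _var_floor(m_data, lvl_mask)
        _, _, _, s_ff0, s_mm0 = _local_moments(f_data, m_data,
                                               cfg.cc_window_voxels)
        metric_mask = lvl_mask & (s_ff0 > eps_f) & (s_mm0 > eps_m)

        vox = float(np.prod(lvl_spacing) ** (1.0 / 3.0))
        it = 0
        best_cost = np.inf
        best_it = 0
        while it < max_iters:
            d_f = exponentiate(VelocityField(v_f, lvl_spacing), cfg.exp_steps)
            d_m = exponentiate(VelocityField(v_m, lvl_spacing), cfg.exp_steps)
            f_mid = resample(f_img, d_f)
            m_mid = resample(m_img, d_m)

            g_f, g_m, cost = _lncc_forces(f_mid.data, m_mid.data,
                                          cfg.cc_window_voxels, metric_mask,
                                          eps_f, eps_m)
            cost_history.append(cost)
            if cost < best_cost - cfg.plateau_tol * max(abs(cost), 1e-8):
                best_cost = cost
                best_v = (v_f.copy(), v_m.copy())
                best_it = it
            elif it - best_it >= cfg.plateau_patience:
                break

            u_f = g_f[..., None] * _spatial_gradient(f_mid.data, lvl_spacing)
            u_m = g_m[..., None] * _spatial_gradient(m_mid.data, lvl_spacing)
            u_f = smooth_vectors(u_f, cfg.fluid_sigma)
            u_m = smooth_vectors(u_m, cfg.fluid_sigma)
            # robust normalization: a high quantile of the active-force
            # magnitudes maps to a full step of step_size voxels, and each
            # vector is capped at that step, so isolated outliers cannot
            # freeze the update everywhere else
            mags = np.sqrt((u_f ** 2).sum(-1)) + np.sqrt((u_m ** 2).sum(-1))
            active = mags[metric_mask] if np.any(metric_mask) else mags.ravel()
            ref = float(np.percentile(active, 98)) if active.size else 0.0
            if ref <= 1e-12:
                break  # no usable force anywhere: aligned or signal-free
            cap = step_size * vox
            for u in (u_f, u_m):
                u *= cap / ref
                norm = np.sqrt((u ** 2).sum(-1, keepdims=True))
                u *= np.where(norm > cap, cap / np.maximum(norm, 1e-12), 1.0)
            v_f = smooth_vectors(v_f + u_f, cfg.elastic_sigma)
            v_m = smooth_vectors(v_m + u_m, cfg.elastic_sigma)
            it += 1
        if best_cost < np.inf:
            v_f, v_m = best_v  # keep the best iterate seen at this level
        iters_run.append(it)

        # diffeomorphism guard: shrink the step and rerun the level once if
        # the accumulated transform folds
        v_full = VelocityField(v_m - v_f, lvl_spacing)
        jac = jacobian_determinant(exponentiate(v_full, cfg.exp_steps))
        if jac.data.min() <= 0 and step_size > cfg.step_size / 8:
            warnings.warn("non-positive Jacobian; halving gradient step")
            halvings += 1
            step_size *= 0.5
            v_f *= 0.5
            v_m *= 0.5

    v_f = _resize_vectors(v_f, full_shape)
    v_m = _resize_vectors(v_m, full_shape)
    v_full = VelocityField(v_m - v_f, spacing, fixed.affine.copy())
    forward = exponentiate(v_full, cfg.exp_steps)
    inverse = exponentiate(-v_full, cfg.exp_steps)

    final = ncc_cost(resample(moving, forward), fixed, cfg.cc_window_voxels, mask)
    return RegistrationResult(v_full, forward, inverse, final, iters_run,
                              cost_history, halvings)
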