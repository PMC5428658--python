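"""Label propagation, probabilistic STAPLE fusion, and segmentation.

The fusion model is a locally-adaptive STAPLE: each rater (candidate
probabilistic segmentation) has a confusion matrix
``theta[true, observed]`` per spatial block (default 8^3 voxels), so that
rater quality can vary across the image.  Rater inputs are probability
maps; a rater's per-voxel distribution is treated as fractional label
counts, which makes the EM updates closed-form and keeps the objective
monotone.  A small Dirichlet pseudocount on the confusion rows avoids
degenerate zero probabilities; the recorded history is the corresponding
penalized log-likelihood, which EM never decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from .core import DisplacementField, GridMismatchError, VolumetricImage, resample
from .register import RegistrationConfig, symmetric_diffeo_register

_THETA_PSEUDOCOUNT = 0.01
_LOG_TINY = 1e-300


@dataclass
class ProbLabelImage:
    """Per-voxel probability vectors over an ordered label set."""

    probs: np.ndarray            # (X, Y, Z, L)
    label_set: list[int]
    spacing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 4 or self.probs.shape[-1] != len(self.label_set):
            raise ValueError("probs must be (X, Y, Z, n_labels)")
        if np.any(self.probs < -1e-6) or np.any(self.probs > 1 + 1e-6):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("per-voxel probabilities must sum to 1")
        if self.spacing is not None:
            self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[:3]

    def hard_labels(self) -> np.ndarray:
        idx = np.argmax(self.probs, axis=-1)  # ties -> first = lowest id
        lut = np.asarray(self.label_set)
        return lut[idx].astype(np.int16)


def one_hot(labels: np.ndarray, label_set=None) -> ProbLabelImage:
    label_set = sorted(int(l) for l in (label_set if label_set is not None
                                        else np.unique(labels)))
    probs = np.stack([(labels == l).astype(np.float32) for l in label_set],
                     axis=-1)
    return ProbLabelImage(probs, label_set)


def propagate_labels(labels: np.ndarray, transform: DisplacementField,
                     label_set=None) -> ProbLabelImage:
    """Warp an integer label map through a pull-back transform.

    Each label channel of the one-hot encoding is warped with linear
    interpolation (the background channel fills with 1 outside the domain)
    and the result is renormalized per voxel.
    """
    labels = np.asarray(labels)
    if labels.shape != tuple(transform.shape):
        raise GridMismatchError("label map and transform must share a grid")
    ls = sorted(int(l) for l in (label_set if label_set is not None
                                 else np.unique(labels)))
    chans = []
    for l in ls:
        img = VolumetricImage((labels == l).astype(np.float32), transform.spacing)
        warped = resample(img, transform, fill=1.0 if l == ls[0] and l == 0 else 0.0)
        chans.append(np.clip(warped.data, 0.0, 1.0))
    probs = np.stack(chans, axis=-1)
    total = probs.sum(axis=-1, keepdims=True)
    probs = np.where(total > 1e-6, probs / np.maximum(total, 1e-6), 0.0)
    # voxels that received no mass at all default to the first (lowest) label
    empty = total[..., 0] <= 1e-6
    if np.any(empty):
        probs[empty, 0] = 1.0
    return ProbLabelImage(probs, ls, transform.spacing)


@dataclass
class FusionModel:
    """Fitted local-STAPLE model."""

    performance: np.ndarray          # (n_raters, n_blocks, L, L), rows over observed
    posterior: ProbLabelImage        # consensus W
    block_size: int
    log_likelihood_history: list[float] = field(default_factory=list)
    label_set: list[int] = field(default_factory=list)
    block_index: np.ndarray | None = None

    def hard_labels(self) -> np.ndarray:
        return self.posterior.hard_labels()


def _block_index(shape, block_size: int) -> np.ndarray:
    if block_size <= 0:
        return np.zeros(int(np.prod(shape)), dtype=np.int64)
    gi = np.arange(shape[0]) // block_size
    gj = np.arange(shape[1]) // block_size
    gk = np.arange(shape[2]) // block_size
    nb_j, nb_k = gj.max() + 1, gk.max() + 1
    bi = (gi[:, None, None] * nb_j * nb_k + gj[None, :, None] * nb_k
          + gk[None, None, :])
    return bi.ravel().astype(np.int64)


def staple_fuse(segs: list[ProbLabelImage],
                prior: ProbLabelImage | str | None = None,
                block_size: int = 4, max_em: int = 50,
                tol: float = 1e-4) -> FusionModel:
    """Probabilistic STAPLE fusion with block-local performance parameters.

    ``block_size=0`` uses a single global confusion matrix per rater.
    ``prior`` defaults to the normalized mean of the input probability
    maps; pass ``"uniform"`` for a flat prior.  Stops when the relative
    change of the (penalized) log-likelihood falls below ``tol``.
    """
    if not segs:
        raise ValueError("staple_fuse needs at least one input segmentation")
    shape = segs[0].shape
    label_set = list(segs[0].label_set)
    for s in segs[1:]:
        if s.shape != shape:
            raise GridMismatchError("all raters must share a grid")
        if list(s.label_set) != label_set:
            raise ValueError("all raters must share the label set")

    L = len(label_set)
    J = len(segs)
    N = int(np.prod(shape))
    p = np.stack([s.probs.reshape(N, L) for s in segs]).astype(np.float64)

    if prior is None:
        pr = p.mean(axis=0)
        pr /= pr.sum(axis=1, keepdims=True)
    elif isinstance(prior, str) and prior == "uniform":
        pr = np.full((N, L), 1.0 / L)
    elif isinstance(prior, ProbLabelImage):
        if prior.shape != shape or list(prior.label_set) != label_set:
            raise ValueError("prior must share grid and label set")
        pr = prior.probs.reshape(N, L).astype(np.float64)
    else:
        raise TypeError("prior must be None, 'uniform', or a ProbLabelImage")
    log_prior = np.log(np.maximum(pr, _LOG_TINY))

    if J == 1:
        # a single rater gives no information about its own reliability;
        # the fused result is the rater itself with ideal performance
        theta = np.broadcast_to(np.eye(L), (1, 1, L, L)).copy()
        return FusionModel(theta, segs[0], block_size, [0.0], label_set,
                           _block_index(shape, 0))

    bidx = _block_index(shape, block_size)
    n_blocks = int(bidx.max()) + 1
    order = np.argsort(bidx, kind="stable")
    bounds = np.searchsorted(bidx[order], np.arange(n_blocks + 1))
    slices = [order[bounds[b]:bounds[b + 1]] for b in range(n_blocks)]

    alpha = _THETA_PSEUDOCOUNT

    def m_step(w: np.ndarray) -> np.ndarray:
        theta = np.empty((J, n_blocks, L, L))
        for j in range(J):
            for b, vox in enumerate(slices):
                counts = w[vox].T @ p[j, vox] + alpha
                theta[j, b] = counts / counts.sum(axis=1, keepdims=True)
        return theta

    def e_step(theta: np.ndarray):
        logw = log_prior.copy()
        logtheta = np.log(np.maximum(theta, _LOG_TINY))
        for j in range(J):
            for b, vox in enumerate(slices):
                logw[vox] += p[j, vox] @ logtheta[j, b].T
        norm = logsumexp(logw, axis=1)
        w = np.exp(logw - norm[:, None])
        ll = float(norm.sum())
        penalty = float(alpha * np.log(np.maximum(theta, _LOG_TINY)).sum())
        return w, ll + penalty

    def run_em(w0: np.ndarray):
        theta = m_step(w0)
        history: list[float] = []
        w = w0
        for _ in range(max_em):
            w, obj = e_step(theta)
            history.append(obj)
            if len(history) >= 2:
                prev = history[-2]
                if abs(obj - prev) < tol * max(abs(prev), 1.0):
                    break
            theta = m_step(w)
        return w, theta, history

    # EM is local; tiny global-mode problems are genuinely multimodal, so
    # run a deterministic multi-start there (prior-seeded plus one start
    # trusting each rater) and keep the best converged objective.  Large
    # problems are effectively unimodal around the prior start.
    starts = [pr]
    if block_size <= 0 and N <= 512:
        starts += [p[j] for j in range(J)]
    best = None
    for w0 in starts:
        w, theta, history = run_em(w0)
        if best is None or history[-1] > best[2][-1] + 1e-12:
            best = (w, theta, history)
    w, theta, history = best

    posterior = ProbLabelImage(w.reshape(shape + (L,)).astype(np.float32),
                               label_set, segs[0].spacing)
    return FusionModel(theta, posterior, block_size, history, label_set, bidx)


# ---------------------------------------------------------------------------
# multi-atlas segmentation

def segment_with_atlases(query, atlases,
                         config: RegistrationConfig | None = None,
                         block_size: int = 4, label_set=None) -> np.ndarray:
    """Multi-atlas segmentation of one subject.

    Each atlas image is registered to the query with the symmetric
    diffeomorphic scheme, its labels are propagated through the forward
    map, and the candidates are fused with :func:`staple_fuse`.  Atlases
    whose registration fails are dropped with a warning.
    """
    if not atlases:
        raise ValueError("segment_with_atlases needs at least one atlas")
    if label_set is None:
        label_set = sorted({int(l) for _, lbl in atlases for l in np.unique(lbl)})
    segs = []
    for k, (img, lbl) in enumerate(atlases):
        try:
            res = symmetric_diffeo_register(query.image, img, config)
        except Exception as exc:
            warnings.warn(f"atlas {k} dropped (registration failed: {exc})")
            continue
        segs.append(propagate_labels(np.asarray(lbl), res.forward, label_set))
    if not segs:
        raise RuntimeError("all atlases were dropped; cannot segment")
    return staple_fuse(segs, block_size=block_size).hard_labels()


@dataclass
class BootstrapResult:
    pass1: dict[str, np.ndarray]
    pass2: dict[str, np.ndarray]
    fallbacks: list[str] = field(default_factory=list)


def bootstrap_cohort_segment(cohort, atlas_trajectory,
                             window_weeks: float = 1.0,
                             config: RegistrationConfig | None = None,
                             block_size: int = 4,
                             include_atlases: bool = True) -> BootstrapResult:
    """Two-pass cohort segmentation.

    Pass 1 segments every subject from its three age-nearest labeled atlas
    timepoints.  Pass 2 re-segments each subject with an enlarged atlas
    set: the pass-1 segmentations of all subjects (itself included) whose
    age lies within ``window_weeks`` of the query, used as
    individual-subject atlases alongside the same spatiotemporal atlas
    timepoints (``include_atlases=False`` drops the latter) — the
    bootstrapping strategy.
    """
    labeled = [tp for tp in atlas_trajectory if tp.labels is not None]
    if len(labeled) < 3:
        raise ValueError("need at least three labeled atlas timepoints")
    label_set = sorted({int(l) for tp in labeled for l in np.unique(tp.labels)})

    def nearest_tps(subj):
        return sorted(labeled, key=lambda tp: (abs(tp.age - subj.age_weeks),
                                               tp.age))[:3]

    # pass 1: per subject, propagate the template raters once and keep them —
    # pass 2 reuses the identical registrations
    pass1: dict[str, np.ndarray] = {}
    template_raters: dict[str, list[ProbLabelImage]] = {}
    for subj in cohort:
        segs = []
        for tp in nearest_tps(subj):
            res = symmetric_diffeo_register(subj.image, tp.template, config)
            segs.append(propagate_labels(tp.labels, res.forward, label_set))
        template_raters[subj.subject_id] = segs
        pass1[subj.subject_id] = staple_fuse(
            segs, block_size=block_size).hard_labels()

    pass2: dict[str, np.ndarray] = {}
    fallbacks: list[str] = []
    for subj in cohort:
        peers = [s for s in cohort
                 if abs(s.age_weeks - subj.age_weeks) <= window_weeks]
        if not peers:  # defensive: the subject itself always qualifies
            warnings.warn(f"{subj.subject_id}: no peers in window; keeping pass 1")
            fallbacks.append(subj.subject_id)
            pass2[subj.subject_id] = pass1[subj.subject_id]
            continue
        segs = list(template_raters[subj.subject_id]) if include_atlases else []
        for peer in peers:
            res = symmetric_diffeo_register(subj.image, peer.image, config)
            segs.append(propagate_labels(pass1[peer.subject_id], res.forward,
                                         label_set))
        pass2[subj.subject_id] = staple_fuse(
            segs, block_size=block_size).hard_labels()
    return BootstrapResult(pass1, pass2, fallbacks)


# ---------------------------------------------------------------------------
# intensity models

def intensity_cluster(image: VolumetricImage, k: int = 10,
                      mask: np.ndarray | None = None) -> ProbLabelImage:
    """K-component 1-D Gaussian-mixture clustering of voxel intensities.

    Components are initialized at evenly spaced intensity quantiles and
    reported sorted by mean, so cluster ids are deterministic.  Voxels
    outside the mask get a uniform probability vector.
    """
    from sklearn.mixture import GaussianMixture

    if k < 2:
        raise ValueError("k must be >= 2")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("mask is empty")
    vals = np.asarray(image.data, dtype=np.float64)[mask].reshape(-1, 1)
    if np.unique(vals).size < k:
        raise ValueError(f"fewer than k={k} distinct intensities in the mask")

    q = np.linspace(0, 100, k + 2)[1:-1]
    means_init = np.percentile(vals, q).reshape(-1, 1)
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         means_init=means_init, random_state=0,
                         reg_covar=1e-4, max_iter=200)
    gm.fit(vals)
    order = np.argsort(gm.means_.ravel())
    resp = gm.predict_proba(vals)[:, order]

    probs = np.full(image.shape + (k,), 1.0 / k, dtype=np.float32)
    probs[mask] = resp.astype(np.float32)
    probs /= probs.sum(axis=-1, keepdims=True)
    return ProbLabelImage(probs, list(range(k)), image.spacing)


def pv_correct(labels: np.ndarray, image: VolumetricImage,
               pairs: list[tuple[int, int]]) -> np.ndarray:
    """Partial-volume correction at tissue interfaces.

    For each label pair, voxels within one voxel of the shared boundary are
    refit with a two-component Gaussian mixture on intensity and reassigned
    to the component (tissue) with the higher posterior.  Voxels away from
    the boundaries are untouched.
    """
    from sklearn.mixture import GaussianMixture

    out = np.asarray(labels).copy()
    data = np.asarray(image.data, dtype=np.float64)
    struct = ndimage.generate_binary_structure(3, 3)  # 1-voxel neighbourhood

    for a, b in pairs:
        in_a, in_b = out == a, out == b
        if not (in_a.any() and in_b.any()):
            warnings.warn(f"pair ({a}, {b}): a label is absent; skipped")
            continue
        near_b = ndimage.binary_dilation(in_b, structure=struct)
        near_a = ndimage.binary_dilation(in_a, structure=struct)
        boundary = (in_a & near_b) | (in_b & near_a)
        if not boundary.any():
            warnings.warn(f"pair ({a}, {b}): no shared boundary; skipped")
            continue
        core_a, core_b = in_a & ~boundary, in_b & ~boundary
        mu_a = data[core_a].mean() if core_a.any() else data[in_a].mean()
        mu_b = data[core_b].mean() if core_b.any() else data[in_b].mean()
        vals = data[boundary].reshape(-1, 1)
        if np.unique(vals).size < 2:
            continue
        gm = GaussianMixture(2, covariance_type="full", random_state=0,
                             means_init=[[mu_a], [mu_b]], reg_covar=1e-3,
                             max_iter=200)
        gm.fit(vals)
        resp = gm.predict_proba(vals)
        # component order follows means_init: column 0 ~ label a
        out[boundary] = np.where(resp[:, 0] >= resp[:, 1], a, b)
    return out
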