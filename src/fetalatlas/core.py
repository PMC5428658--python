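"""Image and transformation data model.

Conventions used throughout the package:

* Volumes are 3-D scalar arrays indexed ``[i, j, k]`` with 0-based voxel
  indices; the voxel-to-world affine is RAS and, for everything this
  package produces, axis aligned (``affine[:3, :3] = diag(spacing)``).
* Displacement and velocity fields store vectors in **millimetres along
  world axes** on the same grid as the image they transform.
* All transforms are *pull-back* maps: ``resample(img, d)`` evaluates
  ``img`` at ``x + d(x)``, so ``d`` carries output-grid points into the
  input image's space.
* Out-of-domain image samples take a constant fill value (default 0);
  out-of-domain *vector* samples are edge-clamped, which keeps composed
  flows smooth near the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Two objects were expected to share a sampling grid but do not."""


class DivergenceError(RuntimeError):
    """A fixed-point iteration failed to contract."""


def _axis_aligned_affine(spacing: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumetricImage:
    """3-D scalar grid with voxel spacing and voxel-to-world affine."""

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacings must be positive")
        if self.affine is None:
            self.affine = _axis_aligned_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other) -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.spacing, other.spacing
        )

    def require_same_grid(self, other, what: str = "operands") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} must share a grid: {self.shape}@{tuple(self.spacing)} vs "
                f"{tuple(other.shape)}@{tuple(np.asarray(other.spacing))}"
            )

    def like(self, data: np.ndarray) -> "VolumetricImage":
        return VolumetricImage(np.asarray(data), self.spacing.copy(), self.affine.copy())


@dataclass
class _VectorGrid:
    """Shared behaviour of displacement and velocity fields (mm vectors)."""

    vectors: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"expected an (X, Y, Z, 3) vector grid, got {self.vectors.shape}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacings must be positive")
        if self.affine is None:
            self.affine = _axis_aligned_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vector field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def same_grid(self, other) -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.spacing, other.spacing
        )

    def require_same_grid(self, other, what: str = "operands") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(f"{what} must share a grid")

    def magnitude_mm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors.astype(np.float64) ** 2, axis=-1))

    def mean_magnitude_voxels(self) -> float:
        """Mean vector magnitude in units of the (geometric-mean) voxel size."""
        vox = float(np.prod(self.spacing) ** (1.0 / 3.0))
        return float(self.magnitude_mm().mean() / vox)


@dataclass
class DisplacementField(_VectorGrid):
    diffeomorphic: bool = False

    @classmethod
    def identity(cls, shape, spacing, affine=None) -> "DisplacementField":
        vec = np.zeros(tuple(shape) + (3,), dtype=np.float32)
        return cls(vec, spacing, affine, diffeomorphic=True)


@dataclass
class VelocityField(_VectorGrid):
    @classmethod
    def zeros(cls, shape, spacing, affine=None) -> "VelocityField":
        return cls(np.zeros(tuple(shape) + (3,), dtype=np.float32), spacing, affine)

    def __neg__(self) -> "VelocityField":
        return VelocityField(-self.vectors, self.spacing.copy(), self.affine.copy())


@dataclass
class RigidTransform:
    """Pull-back rigid map ``y = R x + t`` on world coordinates."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        return points_mm @ self.rotation.T + self.translation_mm


def _index_grid(shape) -> np.ndarray:
    """(X, Y, Z, 3) array of voxel indices, float32."""
    ax = [np.arange(n, dtype=np.float32) for n in shape]
    return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)


def sample_scalar(data: np.ndarray, coords_vox: np.ndarray, fill: float = 0.0,
                  order: int = 1) -> np.ndarray:
    """Interpolate ``data`` at fractional voxel coordinates (X, Y, Z, 3)."""
    return ndimage.map_coordinates(
        data, np.moveaxis(coords_vox, -1, 0), order=order,
        mode="grid-constant", cval=fill, prefilter=order > 1,
    )


def sample_vectors(vectors: np.ndarray, coords_vox: np.ndarray) -> np.ndarray:
    """Interpolate a vector grid at fractional voxel coords, edge-clamped."""
    coords = np.moveaxis(coords_vox, -1, 0)
    out = np.empty(coords_vox.shape[:-1] + (3,), dtype=np.float32)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            vectors[..., c], coords, order=1, mode="nearest", prefilter=False
        )
    return out


def resample(image: VolumetricImage,
             transform: DisplacementField | RigidTransform,
             out_grid: VolumetricImage | DisplacementField | None = None,
             fill: float = 0.0, order: int = 1) -> VolumetricImage:
    """Pull ``image`` back through ``transform`` onto ``out_grid``.

    ``out(x) = image(x + d(x))`` for a displacement field, or
    ``out(x) = image(R x + t)`` (world coordinates) for a rigid map.
    """
    if out_grid is None:
        out_grid = transform if isinstance(transform, DisplacementField) else image
    out_shape = tuple(out_grid.shape)
    out_spacing = np.asarray(out_grid.spacing, dtype=float)

    if isinstance(transform, DisplacementField):
        if transform.shape != out_shape or not np.allclose(
            transform.spacing, out_spacing
        ):
            raise GridMismatchError("displacement field must live on the output grid")
        idx = _index_grid(out_shape)
        coords = idx + transform.vectors / image.spacing.astype(np.float32)
    elif isinstance(transform, RigidTransform):
        idx = _index_grid(out_shape)
        world = idx * out_spacing.astype(np.float32)
        mapped = transform.apply(world.reshape(-1, 3)).reshape(world.shape)
        coords = (mapped / image.spacing).astype(np.float32)
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")

    data = sample_scalar(np.asarray(image.data, dtype=np.float32), coords,
                         fill=fill, order=order)
    return VolumetricImage(data, out_spacing,
                           getattr(out_grid, "affine", image.affine))


def compose(d1: DisplacementField, d2: DisplacementField) -> DisplacementField:
    """Composite map ``(Id + d1) o (Id + d2)`` as a displacement field.

    Satisfies ``resample(img, compose(d1, d2)) == resample(resample(img, d1), d2)``
    up to interpolation.
    """
    d1.require_same_grid(d2, "composed fields")
    idx = _index_grid(d1.shape)
    coords = idx + d2.vectors / d2.spacing.astype(np.float32)
    warped_d1 = sample_vectors(d1.vectors, coords)
    return DisplacementField(d2.vectors + warped_d1, d1.spacing.copy(),
                             d1.affine.copy(),
                             diffeomorphic=d1.diffeomorphic and d2.diffeomorphic)


def exponentiate(v: VelocityField, steps: int = 6) -> DisplacementField:
    """Flow of the stationary velocity field from s=0 to s=1.

    Scaling and squaring: the field is scaled by ``2**-steps`` and the
    resulting small displacement is composed with itself ``steps`` times.
    ``exponentiate(-v)`` approximates the inverse map.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    d = DisplacementField(v.vectors / np.float32(2 ** steps), v.spacing.copy(),
                          v.affine.copy(), diffeomorphic=True)
    for _ in range(steps):
        d = compose(d, d)
    d.diffeomorphic = True
    return d


def invert(d: DisplacementField, iters: int = 20, tol: float = 0.01) -> DisplacementField:
    """Fixed-point inverse: iterate ``inv(x) <- -d(x + inv(x))``.

    ``tol`` is the mean update magnitude (mm) at which iteration stops.
    Raises :class:`DivergenceError` if the residual grows twice in a row.
    """
    idx = _index_grid(d.shape)
    inv = -d.vectors.copy()
    prev_res = np.inf
    grew = 0
    for _ in range(iters):
        coords = idx + inv / d.spacing.astype(np.float32)
        new = -sample_vectors(d.vectors, coords)
        res = float(np.mean(np.sqrt(np.sum((new - inv) ** 2, axis=-1))))
        inv = new
        if res < tol:
            break
        if res > prev_res * 1.001:
            grew += 1
            if grew >= 2:
                raise DivergenceError(
                    f"inverse iteration diverging (residual {res:.3g} mm)"
                )
        else:
            grew = 0
        prev_res = res
    return DisplacementField(inv, d.spacing.copy(), d.affine.copy(),
                             diffeomorphic=d.diffeomorphic)


def jacobian_determinant(d: DisplacementField) -> VolumetricImage:
    """Central-difference Jacobian determinant of ``x + d(x)``.

    Identity maps give 1 everywhere; values > 0 certify local
    invertibility of the (discretized) transform.
    """
    phi = _index_grid(d.shape).astype(np.float64)
    phi += d.vectors.astype(np.float64) / d.spacing
    grads = np.empty(d.shape + (3, 3))
    for comp in range(3):
        gx, gy, gz = np.gradient(phi[..., comp], axis=(0, 1, 2))
        grads[..., comp, 0] = gx
        grads[..., comp, 1] = gy
        grads[..., comp, 2] = gz
    det = np.linalg.det(grads)
    return VolumetricImage(det, d.spacing.copy(), d.affine.copy())


def smooth_vectors(vectors: np.ndarray, sigma_voxels: float) -> np.ndarray:
    """Per-component Gaussian smoothing of a vector grid (sigma in voxels)."""
    if sigma_voxels <= 0:
        return vectors
    out = np.empty_like(vectors)
    for c in range(3):
        ndimage.gaussian_filter(vectors[..., c], sigma_voxels, output=out[..., c],
                                mode="nearest")
    return out
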