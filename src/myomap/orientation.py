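"""Per-voxel fiber orientation from image intensity via the structure tensor.

The local direction of myocyte aggregates is estimated in three steps:

1. intensity gradients are computed along the three grid axes with Gaussian
   derivative filters at scale ``sigma_gradient``;
2. the outer product of the gradient is smoothed componentwise with a
   Gaussian of scale ``sigma_smooth``, giving the structure tensor
   ``T = G_s * (grad I grad I^T)``;
3. each tensor is eigendecomposed and the eigenvector of the *smallest*
   eigenvalue is taken as the fiber direction, because intensity is not
   expected to change along the long axis of a myocyte aggregate.

The fiber direction is an axis, defined only up to sign; every consumer in
this package is sign-invariant.  For storage the vector is canonicalized so
its largest-magnitude component is positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume import ImageVolume

__all__ = [
    "OrientationConfig",
    "StructureTensorField",
    "OrientationField",
    "compute_structure_tensor",
    "extract_fiber_orientation",
    "compute_orientation",
]

# index pairs of the six unique tensor components, (z,y,x) axis order
TENSOR_COMPONENTS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


@dataclass(frozen=True)
class OrientationConfig:
    """Scales and tolerances of the structure-tensor analysis.

    Parameters
    ----------
    sigma_gradient
        Gaussian derivative scale in voxels (> 0).  Sets the finest image
        feature that contributes a gradient.
    sigma_smooth
        Tensor integration scale in voxels (>= 0).  Must exceed
        ``sigma_gradient`` for the tensor to become anisotropic over a
        neighborhood; suits textures of roughly 4-12 voxel wavelength at
        the defaults.
    eig_tol
        Relative degeneracy tolerance: a voxel is flagged invalid when
        ``(lambda2 - lambda3) / lambda1 < eig_tol``, i.e. when the two
        smallest eigenvalues are too close to define a unique direction.
    mask
        Optional boolean array (e.g. the myocardial wall).  Voxels outside
        it are flagged invalid, and before filtering the intensities
        outside the mask are replaced by a normalized-convolution
        extension of the masked intensities, so that sharp compartment
        boundaries (wall/lumen/background) do not bias the orientation of
        near-surface voxels.
    """

    sigma_gradient: float = 1.0
    sigma_smooth: float = 2.5
    eig_tol: float = 1e-3
    mask: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.sigma_gradient <= 0:
            raise ValueError("sigma_gradient must be > 0")
        if self.sigma_smooth < 0:
            raise ValueError("sigma_smooth must be >= 0")
        if not 0 < self.eig_tol < 1:
            raise ValueError("eig_tol must lie in (0, 1)")


@dataclass
class StructureTensorField:
    """Per-voxel symmetric 3x3 structure tensor as 6 unique components.

    ``components`` has shape (6, nz, ny, nx) with the component order
    Tzz, Tzy, Tzx, Tyy, Tyx, Txx.
    """

    components: np.ndarray
    sigma_gradient: float
    sigma_smooth: float
    constant_input: bool = False

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[1:]

    def as_matrices(self) -> np.ndarray:
        """Dense (..., 3, 3) symmetric matrices (float64)."""
        t = self.components.astype(np.float64)
        m = np.empty(self.shape + (3, 3))
        for k, (i, j) in enumerate(TENSOR_COMPONENTS):
            m[..., i, j] = t[k]
            m[..., j, i] = t[k]
        return m


@dataclass
class OrientationField:
    """Fiber directions with eigenvalues and a validity flag.

    ``vectors`` has shape (nz, ny, nx, 3), components in (z, y, x) order,
    unit norm where ``valid``; ``eigenvalues`` are sorted descending
    (lambda1 >= lambda2 >= lambda3).
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]


def compute_structure_tensor(
    volume: ImageVolume, config: OrientationConfig | None = None
) -> StructureTensorField:
    """Structure tensor of an image volume with Gaussian derivatives.

    Mirror-reflect padding is used at the borders for every filter.  A
    constant-intensity volume yields zero tensors and a warning flag.
    """
    config = config or OrientationConfig()
    if min(volume.shape) < 8:
        raise ValueError("volume must be at least 8 voxels along each axis")
    data = volume.data.astype(np.float32)
    if config.mask is not None:
        data = _extend_masked(data, np.asarray(config.mask, dtype=bool),
                              sigma=max(config.sigma_smooth, 1.0))

    grads = [
        ndi.gaussian_filter(
            data, config.sigma_gradient, order=[int(ax == k) for k in range(3)],
            mode="mirror",
        )
        for ax in range(3)
    ]
    constant = all(np.allclose(g, 0) for g in grads)
    if constant:
        warnings.warn(
            "volume has (numerically) constant intensity: structure tensor "
            "is identically zero",
            stacklevel=2,
        )

    comps = np.empty((6,) + volume.shape, dtype=np.float32)
    for k, (i, j) in enumerate(TENSOR_COMPONENTS):
        prod = grads[i] * grads[j]
        if config.sigma_smooth > 0:
            prod = ndi.gaussian_filter(prod, config.sigma_smooth, mode="mirror")
        comps[k] = prod
    return StructureTensorField(
        components=comps,
        sigma_gradient=config.sigma_gradient,
        sigma_smooth=config.sigma_smooth,
        constant_input=constant,
    )


def _extend_masked(data: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Replace out-of-mask intensities by a normalized-convolution extension.

    ``G(I*M)/G(M)`` smoothly continues the masked intensities outward;
    far from the mask (where the weight underflows) the masked mean is
    used.  In-mask voxels keep their original values.
    """
    m = mask.astype(np.float32)
    num = ndi.gaussian_filter(data * m, sigma, mode="mirror")
    den = ndi.gaussian_filter(m, sigma, mode="mirror")
    fill = np.where(den > 1e-6, num / np.where(den > 0, den, 1.0),
                    data[mask].mean(dtype=np.float64))
    return np.where(mask, data, fill.astype(data.dtype))


def _canonical_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each vector so its largest-magnitude component is positive."""
    idx = np.argmax(np.abs(vectors), axis=-1)
    lead = np.take_along_axis(vectors, idx[..., None], axis=-1)[..., 0]
    sign = np.where(lead < 0, -1.0, 1.0)
    return vectors * sign[..., None]


def extract_fiber_orientation(
    tensors: StructureTensorField, config: OrientationConfig | None = None
) -> OrientationField:
    """Eigendecompose the tensor field and select the fiber direction.

    The eigenvector of the smallest eigenvalue is the direction of least
    intensity change.  A voxel is flagged invalid when

    * any tensor component is NaN,
    * ``lambda1 <= 0`` (no gradient energy),
    * ``(lambda2 - lambda3) / lambda1 < eig_tol`` (degenerate direction),
    * it lies within ``ceil(3 * sigma_smooth)`` voxels of the volume border
      (filter support is incomplete there), or
    * it falls outside ``config.mask`` when a mask is given.
    """
    config = config or OrientationConfig(
        sigma_gradient=tensors.sigma_gradient, sigma_smooth=tensors.sigma_smooth
    )
    shape = tensors.shape
    n = int(np.prod(shape))
    mats = tensors.as_matrices().reshape(n, 3, 3)

    evals = np.empty((n, 3))
    evecs = np.empty((n, 3))
    nan_rows = np.isnan(mats).any(axis=(1, 2))
    mats[nan_rows] = np.eye(3)
    # chunked eigh keeps peak memory modest on large volumes
    chunk = 1 << 20
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        w, v = np.linalg.eigh(mats[sl])  # ascending eigenvalues
        evals[sl] = w[:, ::-1]  # descending: lambda1 >= lambda2 >= lambda3
        evecs[sl] = v[:, :, 0]  # eigenvector of the smallest eigenvalue

    lam1, lam2, lam3 = evals[:, 0], evals[:, 1], evals[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        sep = np.where(lam1 > 0, (lam2 - lam3) / lam1, 0.0)
    valid = (~nan_rows) & (lam1 > 0) & (sep >= config.eig_tol)

    valid = valid.reshape(shape)
    margin = math.ceil(3 * tensors.sigma_smooth)
    if margin > 0:
        border = np.zeros(shape, dtype=bool)
        interior = tuple(
            slice(margin, s - margin) if s > 2 * margin else slice(0, 0)
            for s in shape
        )
        border[interior] = True
        valid &= border
    if config.mask is not None:
        valid &= np.asarray(config.mask, dtype=bool)

    vectors = _canonical_sign(evecs).reshape(shape + (3,)).astype(np.float32)
    vectors[~valid] = np.nan
    return OrientationField(
        vectors=vectors,
        eigenvalues=evals.reshape(shape + (3,)).astype(np.float32),
        valid=valid,
    )


def compute_orientation(
    volume: ImageVolume, config: OrientationConfig | None = None
) -> OrientationField:
    """Convenience wrapper: structure tensor followed by eigen-analysis."""
    config = config or OrientationConfig()
    return extract_fiber_orientation(compute_structure_tensor(volume, config), config)
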