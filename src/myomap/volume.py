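"""Core in-memory containers for volumetric cardiac image analysis.

Conventions used throughout the package:

* image arrays are indexed ``(z, y, x)``, 0-based, voxel centers at integer
  indices;
* world coordinates are in micrometres (µm) and, like every vector quantity,
  are stored with components ordered ``(z, y, x)`` so that
  ``world = index * voxel_size_um`` componentwise;
* voxels are isotropic — anisotropic inputs must be resampled before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMap",
    "LandmarkCurve",
    "cross_zyx",
    "normalize",
]


def cross_zyx(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cross product for vectors whose components are ordered (z, y, x).

    The (z, y, x) ordering is an odd permutation of (x, y, z), so applying
    :func:`numpy.cross` directly would flip the handedness.  Reversing the
    component axis before and after restores the right-handed product.
    """
    return np.cross(u[..., ::-1], v[..., ::-1])[..., ::-1]


def normalize(v: np.ndarray, axis: int = -1, eps: float = 0.0) -> np.ndarray:
    """Unit-normalize vectors along ``axis``; norms <= ``eps`` give NaN."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > eps, v / n, np.nan)
    return out


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with isotropic voxel size.

    Parameters
    ----------
    data
        3D array of intensities, indexed (z, y, x).
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    """

    data: np.ndarray
    voxel_size_um: float
    axis_order: str = field(default="zyx")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive and finite")
        if self.axis_order != "zyx":
            raise ValueError("only (z, y, x) axis order is supported")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """Integer label volume on the same grid conventions as ImageVolume."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must have an integer dtype")
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive and finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, *labels: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.data, labels)


@dataclass
class LandmarkCurve:
    """An ordered 3D point curve in world coordinates (µm, zyx components).

    Used for the mitral-valve hinge line and the crest of the adjacent
    ventricular myocardium.  Points may carry an angular annotation
    (degrees about the annular axis).
    """

    points_um: np.ndarray
    angles_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float)
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 3:
            raise ValueError("points_um must have shape (n, 3)")
        if len(self.points_um) < 2:
            raise ValueError("a landmark curve needs at least 2 points")
        if np.any(np.all(np.diff(self.points_um, axis=0) == 0, axis=1)):
            raise ValueError("consecutive duplicate points are not allowed")
        if self.angles_deg is not None:
            self.angles_deg = np.asarray(self.angles_deg, dtype=float)
            if self.angles_deg.shape != (len(self.points_um),):
                raise ValueError("angles_deg must match the number of points")

    def __len__(self) -> int:
        return len(self.points_um)
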