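"""LV-centered cylindrical geometry and helix-angle mapping.

The heart's cylindrical coordinate system is anchored on the left
ventricular long axis.  Each voxel gets a right-handed orthonormal triad
(radial, circumferential, longitudinal); the fiber direction is projected
onto the local tangential plane (circumferential-longitudinal) and the
helical angle is the signed angle between that projection and the
transverse plane:

    alpha_h = atan2(e . z_hat, e . c_hat)   folded into [-90, 90] degrees

so that 0 deg is purely circumferential and +/-90 deg purely longitudinal.
The fold makes the angle invariant under the fiber's sign ambiguity.
The sign convention is right-handed: alpha_h > 0 when a positive
longitudinal component (along the fitted axis direction, normalized to
point toward +z) accompanies a positive circumferential component.
The transverse plane is taken normal to the single fitted axis, not to the
image z-plane, which matters for tilted hearts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .orientation import OrientationField
from .volume import LabelMap, cross_zyx

__all__ = [
    "Centerline",
    "CylindricalFrame",
    "HelixAngleMap",
    "estimate_centerline",
    "local_cylindrical_frame",
    "compute_helix_angle_map",
    "transmural_depth",
    "transmural_profile",
    "plot_helix_midslice",
]


@dataclass
class Centerline:
    """A fitted straight LV long axis.

    ``point_um`` is a point on the axis, ``direction`` a unit vector
    (components z, y, x, normalized so the z component is positive),
    ``centroids_um`` the per-slice centroids the fit used.
    """

    point_um: np.ndarray
    direction: np.ndarray
    centroids_um: np.ndarray

    def __post_init__(self) -> None:
        self.point_um = np.asarray(self.point_um, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis direction must be a nonzero vector")
        self.direction = self.direction / n
        if self.direction[0] < 0:
            self.direction = -self.direction


@dataclass
class CylindricalFrame:
    """Per-point orthonormal triad (radial, circumferential, longitudinal)."""

    r_hat: np.ndarray
    c_hat: np.ndarray
    z_hat: np.ndarray
    valid: np.ndarray


@dataclass
class HelixAngleMap:
    """Per-voxel helical angle in degrees; NaN where undefined."""

    angle_deg: np.ndarray
    valid: np.ndarray
    voxel_size_um: float


def estimate_centerline(
    wall_mask: LabelMap | np.ndarray,
    voxel_size_um: float | None = None,
    label: int | None = None,
) -> Centerline:
    """Fit the LV long axis from a wall (or cavity) mask.

    Per z-slice the mask centroid is taken; empty slices are skipped; the
    centroids are then fit with a total-least-squares line.  At least three
    usable slices are required.
    """
    if isinstance(wall_mask, LabelMap):
        voxel_size_um = wall_mask.voxel_size_um
        arr = wall_mask.data == label if label is not None else wall_mask.data > 0
    else:
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required with a bare array mask")
        arr = np.asarray(wall_mask) > 0

    centroids = []
    for z in range(arr.shape[0]):
        ys, xs = np.nonzero(arr[z])
        if ys.size == 0:
            continue
        centroids.append((float(z), ys.mean(), xs.mean()))
    if len(centroids) < 3:
        raise ValueError(
            f"centerline fit needs >= 3 nonempty slices, found {len(centroids)}"
        )
    pts = np.asarray(centroids) * voxel_size_um
    mean = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
    return Centerline(point_um=mean, direction=vt[0], centroids_um=pts)


def local_cylindrical_frame(
    positions_um: np.ndarray,
    centerline: Centerline,
    min_radius_um: float = 0.0,
) -> CylindricalFrame:
    """Orthonormal (r_hat, c_hat, z_hat) triads at world positions.

    ``z_hat`` is the axis direction, ``r_hat`` the unit perpendicular from
    the axis to the point, and ``c_hat = z_hat x r_hat``, making the triad
    right-handed (``r_hat x c_hat = z_hat``).  Points within
    ``min_radius_um`` of the axis are flagged undefined.
    """
    pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
    a = centerline.direction
    rel = pos - centerline.point_um
    axial = rel @ a
    radial = rel - axial[:, None] * a
    rho = np.linalg.norm(radial, axis=1)
    valid = rho > min_radius_um
    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = radial / rho[:, None]
    r_hat[~valid] = np.nan
    z_hat = np.broadcast_to(a, pos.shape).copy()
    c_hat = cross_zyx(z_hat, r_hat)
    return CylindricalFrame(r_hat=r_hat, c_hat=c_hat, z_hat=z_hat, valid=valid)


def compute_helix_angle_map(
    orientation: OrientationField,
    centerline: Centerline,
    mask: LabelMap | np.ndarray,
    voxel_size_um: float | None = None,
    tangential_min: float = 0.2,
    min_radius_voxels: float = 1.0,
) -> HelixAngleMap:
    """Helical angle of the fiber direction at every valid wall voxel.

    A voxel is assigned an angle only when the orientation there is valid,
    it lies inside ``mask``, it is farther than ``min_radius_voxels`` from
    the axis, and the norm of the fiber's tangential projection is at least
    ``tangential_min`` (near-radial fibers have no meaningful helix angle).
    """
    if isinstance(mask, LabelMap):
        voxel_size_um = mask.voxel_size_um
        mask_arr = mask.data > 0
    else:
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required with a bare array mask")
        mask_arr = np.asarray(mask) > 0
    if mask_arr.shape != orientation.shape:
        raise ValueError("orientation field and mask must share the grid")

    sel = orientation.valid & mask_arr
    idx = np.argwhere(sel)
    angle = np.full(orientation.shape, np.nan, dtype=np.float32)
    valid = np.zeros(orientation.shape, dtype=bool)
    if idx.size:
        pos_um = idx.astype(float) * voxel_size_um
        frame = local_cylindrical_frame(
            pos_um, centerline, min_radius_um=min_radius_voxels * voxel_size_um
        )
        e = orientation.vectors[sel].astype(np.float64)
        a_c = np.einsum("ij,ij->i", e, frame.c_hat)
        a_z = np.einsum("ij,ij->i", e, frame.z_hat)
        tnorm = np.hypot(a_c, a_z)
        ok = frame.valid & (tnorm >= tangential_min)
        alpha = np.degrees(np.arctan2(a_z, a_c))
        alpha = np.where(alpha > 90.0, alpha - 180.0, alpha)
        alpha = np.where(alpha < -90.0, alpha + 180.0, alpha)
        zz, yy, xx = idx[:, 0], idx[:, 1], idx[:, 2]
        angle[zz[ok], yy[ok], xx[ok]] = alpha[ok].astype(np.float32)
        valid[zz[ok], yy[ok], xx[ok]] = True
    return HelixAngleMap(angle_deg=angle, valid=valid, voxel_size_um=voxel_size_um)


def transmural_depth(
    labelmap: LabelMap,
    wall_label: int = 2,
    inner_label: int = 1,
    outer_label: int = 0,
) -> np.ndarray:
    """Normalized transmural depth d in [0, 1] over the wall.

    ``d = D_endo / (D_endo + D_epi)`` where the two distances are Euclidean
    distances (half a voxel is subtracted so that the surfaces themselves
    sit at d = 0 and d = 1) from a wall voxel to the inner (cavity) and
    outer (background) compartments.  Well defined for curved walls and
    reduces to linear depth for a slab.  NaN outside the wall.
    """
    data = labelmap.data
    d_in = ndi.distance_transform_edt(data != inner_label)
    d_out = ndi.distance_transform_edt(data != outer_label)
    d_in = np.maximum(d_in - 0.5, 0.0)
    d_out = np.maximum(d_out - 0.5, 0.0)
    wall = data == wall_label
    depth = np.full(data.shape, np.nan)
    denom = d_in + d_out
    good = wall & (denom > 0)
    depth[good] = d_in[good] / denom[good]
    depth[wall & ~good] = 0.5  # wall a single voxel thick: midway
    return depth


def transmural_profile(
    helix: HelixAngleMap, depth: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Binned transmural helix-angle profile.

    Returns one row per depth bin with the bin center, circular-free mean
    and standard deviation of the helical angle, and the voxel count.
    """
    sel = helix.valid & np.isfinite(depth)
    if not sel.any():
        raise ValueError("no voxels with both a helix angle and a depth value")
    d = depth[sel]
    a = helix.angle_deg[sel].astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        vals = a[which == b]
        if vals.size == 0:
            continue
        rows.append(
            {
                "depth_bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "mean_deg": vals.mean(),
                "sd_deg": vals.std(ddof=1) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
    if len(rows) < n_bins:
        warnings.warn(f"{n_bins - len(rows)} empty depth bins", stacklevel=2)
    return pd.DataFrame(rows)


def plot_helix_midslice(helix: HelixAngleMap, path) -> None:
    """Color-mapped mid-stack slice of the helix-angle map (PNG)."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    sl = helix.angle_deg[helix.angle_deg.shape[0] // 2]
    im = ax.imshow(sl, cmap="RdYlBu_r", vmin=-90, vmax=90, origin="lower")
    fig.colorbar(im, ax=ax, label="helical angle (deg)")
    ax.set_xlabel("x (voxels)")
    ax.set_ylabel("y (voxels)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
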