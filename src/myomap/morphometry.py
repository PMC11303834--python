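"""Wall-layer thickness, mitral annular disjunction, and CNR measurement.

Thickness is measured caliper-style: at sample locations evenly
distributed over the wall mid-surface, a ray is cast along the local wall
normal and each sublayer's chord length is reported in µm.  Mitral
annular disjunction (MAD) is the displacement of the mitral-valve hinge
line from the crest of the adjacent ventricular myocardium, profiled in
angular steps around the annulus.  Contrast-to-noise ratio (CNR) uses a
single background region (the embedding agar):

    CNR = |mean(tissue) - mean(background)| / sd(background)

which is invariant under global affine intensity maps with positive gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .geometry import Centerline
from .volume import ImageVolume, LabelMap, LandmarkCurve

__all__ = [
    "SUBLAYER_NAMES",
    "ThicknessMeasurementSet",
    "MADProfile",
    "measure_layer_thickness",
    "compute_mad_profile",
    "compute_cnr",
    "cnr_report",
]

SUBLAYER_NAMES = {1: "endocardium", 2: "myocardium", 3: "epicardium"}


@dataclass
class ThicknessMeasurementSet:
    """Per-location, per-sublayer thickness records.

    ``table`` has columns location, sublayer, thickness_um and optionally
    the group labels heart (control/diseased) and chamber (left
    atrium/right atrium) that feed the statistical comparison.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"location", "sublayer", "thickness_um"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.table["thickness_um"] <= 0).any():
            raise ValueError("thicknesses must be > 0")
        bad = set(self.table["sublayer"]) - set(SUBLAYER_NAMES.values())
        if bad:
            raise ValueError(f"unknown sublayer labels: {sorted(bad)}")

    def with_groups(self, heart: str, chamber: str) -> "ThicknessMeasurementSet":
        t = self.table.copy()
        t["heart"] = heart
        t["chamber"] = chamber
        return ThicknessMeasurementSet(t)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False, float_format="%.6f")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThicknessMeasurementSet":
        return cls(pd.read_csv(path))


@dataclass
class MADProfile:
    """Disjunction distance (µm) versus angle around the annulus."""

    angles_deg: np.ndarray
    distance_um: np.ndarray
    step_deg: float = 5.0

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        if self.angles_deg.shape != self.distance_um.shape:
            raise ValueError("angles and distances must have equal length")
        steps = np.diff(self.angles_deg)
        if len(steps) and not np.allclose(steps, self.step_deg):
            raise ValueError("angles must increase in constant steps")
        if np.any(self.distance_um < 0):
            raise ValueError("disjunction distances must be >= 0")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"angle_deg": self.angles_deg, "disjunction_um": self.distance_um}
        ).to_csv(path, index=False, float_format="%.6f")
        return path


def _sample_labels(data: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel label lookup; -1 outside the grid."""
    idx = np.floor(points + 0.5).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(data.shape)), axis=-1)
    out = np.full(len(points), -1, dtype=int)
    if inside.any():
        ii = idx[inside]
        out[inside] = data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def _mid_surface_voxels(labelmap: LabelMap, layer_labels) -> tuple[np.ndarray, np.ndarray]:
    """Mid-surface voxels of the wall and a smooth signed-depth field.

    Depth runs 0 -> 1 from the side adjacent to the first layer label to
    the side adjacent to the last; the mid-surface is where it crosses
    0.5 between 6-neighbors.
    """
    data = labelmap.data
    wall = np.isin(data, layer_labels)
    non_wall = ~wall
    struct = ndi.generate_binary_structure(3, 1)
    side_a = non_wall & ndi.binary_dilation(data == layer_labels[0], struct)
    side_b = non_wall & ndi.binary_dilation(data == layer_labels[-1], struct)
    if not side_a.any() or not side_b.any():
        raise ValueError("wall must be bounded by non-wall voxels on both sides")
    d_a = ndi.distance_transform_edt(~side_a)
    d_b = ndi.distance_transform_edt(~side_b)
    depth = np.full(data.shape, np.nan)
    depth[wall] = d_a[wall] / (d_a[wall] + d_b[wall])

    signed = depth - 0.5
    mid = np.zeros(data.shape, dtype=bool)
    core = np.nan_to_num(signed, nan=np.inf)
    for ax in range(3):
        for shift in (1, -1):
            neigh = np.roll(core, shift, axis=ax)
            mid |= wall & (np.isfinite(core)) & (core <= 0) & (neigh > 0) & np.isfinite(neigh)
    if not mid.any():
        # wall thinner than two voxels transmurally: fall back to |d-0.5| minimum
        mid = wall & (np.abs(signed) < 0.25)
    smooth_depth = np.nan_to_num(depth, nan=0.0)
    smooth_depth = ndi.gaussian_filter(smooth_depth, 1.5, mode="nearest")
    return mid, smooth_depth


def measure_layer_thickness(
    labelmap: LabelMap,
    n_locations: int = 15,
    seed: int = 0,
    layer_labels: tuple[int, int, int] = (1, 2, 3),
    ray_step_voxels: float = 0.25,
) -> ThicknessMeasurementSet:
    """Normal-ray chord thickness of each sublayer at sampled locations.

    Locations are spread with equal spacing along the principal extent of
    the wall mid-surface (ties broken with the seeded generator).  At each
    location a ray along the local normal (gradient of the transmural
    depth field) is marched in sub-voxel steps from outside the wall on
    one side to outside on the other; each sublayer's thickness is its
    chord length times the voxel size.  Rays that leave the volume before
    traversing all three sublayers are skipped with a warning; if fewer
    than ``n_locations`` remain the measurement fails.
    """
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    rng = np.random.default_rng(seed)
    data = labelmap.data
    vox = labelmap.voxel_size_um
    mid, depth_field = _mid_surface_voxels(labelmap, layer_labels)

    pts = np.argwhere(mid).astype(float)
    grad = np.stack(np.gradient(depth_field), axis=-1)

    # keep only mid-surface candidates whose normal ray can traverse the
    # whole wall without leaving the volume (estimated from the mean chord)
    wall_extent = np.isin(data, layer_labels).sum() / max(len(pts), 1)
    normals = grad[tuple(pts.astype(int).T)]
    nrm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(nrm > 0, normals / np.where(nrm > 0, nrm, 1.0), 0.0)
    reach = 0.75 * wall_extent + 2.0
    hi = np.array(data.shape) - 1.0
    feasible = np.ones(len(pts), dtype=bool)
    for sign in (1.0, -1.0):
        end = pts + sign * reach * normals
        feasible &= np.all((end >= 0.0) & (end <= hi), axis=1)
    if feasible.any():
        pts = pts[feasible]

    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]
    order = rng.permutation(len(t))  # seeded tie-break among equal projections
    pts, t = pts[order], t[order]

    targets = t.min() + (np.arange(n_locations) + 0.5) * (t.max() - t.min()) / n_locations

    records = []
    skipped = 0
    loc_index = 0
    for target in targets:
        p = pts[np.argmin(np.abs(t - target))]
        n = grad[tuple(p.astype(int))]
        nn = np.linalg.norm(n)
        if nn == 0:
            skipped += 1
            warnings.warn("zero normal at a sampled location; skipped", stacklevel=2)
            continue
        n = n / nn
        # march to just outside the wall on the negative side
        max_steps = int(np.ceil(np.linalg.norm(data.shape) / ray_step_voxels)) + 2
        ks = (np.arange(max_steps) + 0.5) * ray_step_voxels
        back = p - ks[:, None] * n
        lab_back = _sample_labels(data, back)
        in_wall = np.isin(lab_back, layer_labels)
        exits = np.nonzero(~in_wall)[0]
        if len(exits) == 0 or lab_back[exits[0]] == -1:
            skipped += 1
            warnings.warn("ray left the volume before exiting the wall; skipped",
                          stacklevel=2)
            continue
        start = back[exits[0]]
        fwd = start + ks[:, None] * n
        lab_fwd = _sample_labels(data, fwd)
        in_wall_f = np.isin(lab_fwd, layer_labels)
        entered = np.nonzero(in_wall_f)[0]
        if len(entered) == 0:
            skipped += 1
            continue
        after = np.nonzero(~in_wall_f[entered[0]:])[0]
        if len(after) == 0 or lab_fwd[entered[0] + after[0]] == -1:
            skipped += 1
            warnings.warn("ray left the volume before exiting the wall; skipped",
                          stacklevel=2)
            continue
        chord = lab_fwd[entered[0]: entered[0] + after[0]]
        counts = {lab: int(np.sum(chord == lab)) for lab in layer_labels}
        if any(c == 0 for c in counts.values()):
            skipped += 1
            warnings.warn("ray missed a sublayer; skipped", stacklevel=2)
            continue
        for lab in layer_labels:
            records.append(
                {
                    "location": loc_index,
                    "sublayer": SUBLAYER_NAMES[lab],
                    "thickness_um": counts[lab] * ray_step_voxels * vox,
                }
            )
        loc_index += 1

    if loc_index < n_locations:
        raise ValueError(
            f"only {loc_index} of {n_locations} locations usable "
            f"({skipped} rays skipped)"
        )
    return ThicknessMeasurementSet(pd.DataFrame(records))


def _curve_angles_axial(
    curve: LandmarkCurve, point: np.ndarray, axis: np.ndarray,
    b1: np.ndarray, b2: np.ndarray,
):
    rel = curve.points_um - point
    axial = rel @ axis
    theta = np.degrees(np.unwrap(np.arctan2(rel @ b2, rel @ b1)))
    return theta, axial, rel


def compute_mad_profile(
    hinge: LandmarkCurve,
    crest: LandmarkCurve,
    annulus_axis: Centerline | tuple[np.ndarray, np.ndarray],
    step_deg: float = 5.0,
    mode: str = "axial",
) -> MADProfile:
    """Disjunction distance at every ``step_deg`` node of the common arc.

    Both curves are parameterized by their angle about the annular axis
    (origin at the first hinge point); the hinge and crest positions are
    linearly interpolated at each node and their separation reported —
    along the axis (``mode='axial'``, default) or as the full 3D distance
    (``mode='euclidean'``).
    """
    if mode not in ("axial", "euclidean"):
        raise ValueError("mode must be 'axial' or 'euclidean'")
    if isinstance(annulus_axis, Centerline):
        point, axis = annulus_axis.point_um, annulus_axis.direction
    else:
        point, axis = (np.asarray(v, dtype=float) for v in annulus_axis)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 1.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    b1 = ref - (ref @ axis) * axis
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis[::-1], b1[::-1])[::-1]

    th_h, ax_h, rel_h = _curve_angles_axial(hinge, point, axis, b1, b2)
    th_c, ax_c, rel_c = _curve_angles_axial(crest, point, axis, b1, b2)
    origin = th_h[0]
    th_h = th_h - origin
    th_c = th_c - origin
    for name, th in (("hinge", th_h), ("crest", th_c)):
        d = np.diff(th)
        if np.any(d <= 0) and np.any(d >= 0) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(f"{name} curve is not monotone in angle about the axis")
    if th_h[0] > th_h[-1]:
        th_h, ax_h, rel_h = th_h[::-1], ax_h[::-1], rel_h[::-1]
    if th_c[0] > th_c[-1]:
        th_c, ax_c, rel_c = th_c[::-1], ax_c[::-1], rel_c[::-1]

    for name, th in (("hinge", th_h), ("crest", th_c)):
        gaps = np.diff(th)
        if np.any(gaps > step_deg + 1e-9):
            raise ValueError(
                f"{name} curve has angular gaps up to {gaps.max():.2f} deg, "
                f"larger than the {step_deg} deg step; interpolation refused"
            )

    lo = max(th_h[0], th_c[0])
    hi = min(th_h[-1], th_c[-1])
    if hi <= lo:
        raise ValueError("hinge and crest arcs do not overlap")
    nodes = np.arange(np.ceil(lo / step_deg), np.floor(hi / step_deg) + 0.5) * step_deg
    if len(nodes) == 0:
        raise ValueError("overlapping arc shorter than one step")

    if mode == "axial":
        h = np.interp(nodes, th_h, ax_h)
        c = np.interp(nodes, th_c, ax_c)
        dist = np.abs(h - c)
    else:
        h = np.column_stack([np.interp(nodes, th_h, rel_h[:, k]) for k in range(3)])
        c = np.column_stack([np.interp(nodes, th_c, rel_c[:, k]) for k in range(3)])
        dist = np.linalg.norm(h - c, axis=1)
    return MADProfile(angles_deg=nodes, distance_um=dist, step_deg=step_deg)


def compute_cnr(
    volume: ImageVolume,
    tissue_roi: LabelMap | np.ndarray,
    background_roi: LabelMap | np.ndarray,
) -> pd.DataFrame:
    """CNR of each replicate tissue ROI against a single background ROI.

    ``tissue_roi`` is a label volume whose distinct positive labels mark
    replicate ROIs; ``background_roi`` is a mask (any positive voxel).
    Returns one row per replicate with the tissue mean/sd, background
    mean/sd and the CNR value.
    """
    tis = tissue_roi.data if isinstance(tissue_roi, LabelMap) else np.asarray(tissue_roi)
    bg = background_roi.data if isinstance(background_roi, LabelMap) else np.asarray(background_roi)
    if tis.shape != volume.shape or bg.shape != volume.shape:
        raise ValueError("ROIs must share the volume grid")
    bg_mask = bg > 0
    if not bg_mask.any():
        raise ValueError("background ROI is empty")
    if np.any((tis > 0) & bg_mask):
        raise ValueError("tissue and background ROIs overlap")
    bvals = volume.data[bg_mask].astype(float)
    b_mean = bvals.mean()
    b_sd = bvals.std(ddof=1)
    if b_sd == 0:
        raise ValueError("undefined CNR: background sd is zero")
    rows = []
    labels = np.unique(tis[tis > 0])
    if labels.size == 0:
        raise ValueError("tissue ROI is empty")
    for lab in labels:
        tvals = volume.data[tis == lab].astype(float)
        rows.append(
            {
                "replicate": int(lab),
                "tissue_mean": tvals.mean(),
                "tissue_sd": tvals.std(ddof=1) if tvals.size > 1 else 0.0,
                "background_mean": b_mean,
                "background_sd": b_sd,
                "cnr": abs(tvals.mean() - b_mean) / b_sd,
            }
        )
    return pd.DataFrame(rows)


def cnr_report(
    volume: ImageVolume,
    tissue_rois: dict[str, LabelMap | np.ndarray],
    background_roi: LabelMap | np.ndarray,
) -> pd.DataFrame:
    """Per-region CNR table (replicate rows plus a mean +/- sd summary row).

    ``tissue_rois`` maps a region name (e.g. aorta, LV wall, epicardial
    fat) to a replicate-labelled ROI volume.
    """
    frames = []
    for region, roi in tissue_rois.items():
        df = compute_cnr(volume, roi, background_roi)
        df.insert(0, "region", region)
        summary = pd.DataFrame(
            [
                {
                    "region": region,
                    "replicate": -1,
                    "tissue_mean": df["tissue_mean"].mean(),
                    "tissue_sd": df["tissue_mean"].std(ddof=1),
                    "background_mean": df["background_mean"].iloc[0],
                    "background_sd": df["background_sd"].iloc[0],
                    "cnr": df["cnr"].mean(),
                }
            ]
        )
        frames.append(pd.concat([df, summary], ignore_index=True))
    return pd.concat(frames, ignore_index=True)
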