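"""Synthetic cardiac phantoms with known ground truth.

Whole-heart phase-contrast scan volumes are far too large to ship with a
software package, so every quantitative stage here is validated on
phantoms that emulate the geometric and textural features the methods
rely on:

* an annular left-ventricle-like wall whose fiber texture follows a
  prescribed transmural helix-angle law ``alpha(d) = alpha_endo +
  (alpha_epi - alpha_endo) * d`` with ``d`` the normalized transmural
  depth (0 at the endocardium, 1 at the epicardium);
* a three-sublayer wall slab (endocardium / myocardium / epicardium) of
  known thicknesses, flat or curved;
* a hinge/crest landmark-curve pair with a known axial displacement
  (mitral-annular-disjunction stand-in);
* controlled additive Gaussian noise.

The fiber texture is a bundle of discrete myocyte-aggregate-like tubes:
random helices that follow the prescribed helix law exactly and are
splatted with a narrow Gaussian cross-section.  Intensity is therefore
constant along the local fiber direction and oscillates transverse to it
in both normal directions, matching the structure-tensor premise that
intensity does not change along a myocyte aggregate's long axis while
keeping the tensor's two larger eigenvalues well separated from the
smallest.  (Phase-based laminae textures were rejected: any global
helical phase accumulates radial frequency until it aliases.)

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage as ndi

from .volume import ImageVolume, LabelMap, LandmarkCurve, cross_zyx

__all__ = [
    "BACKGROUND",
    "LUMEN",
    "WALL",
    "LAYER_ENDO",
    "LAYER_MYO",
    "LAYER_EPI",
    "LVPhantomSpec",
    "WallSlabSpec",
    "MADPhantomSpec",
    "GroundTruthOrientation",
    "generate_lv_phantom",
    "generate_wall_slab",
    "generate_mad_phantom",
    "add_noise",
]

BACKGROUND = 0
LUMEN = 1
WALL = 2

LAYER_ENDO = 1
LAYER_MYO = 2
LAYER_EPI = 3


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction vector must be nonzero")
    return v / n


def _perp_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis (b1, b2) of the plane normal to axis."""
    ref = np.array([0.0, 1.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    b1 = _unit(ref - (ref @ axis) * axis)
    b2 = cross_zyx(axis, b1)
    return b1, b2


@dataclass(frozen=True)
class LVPhantomSpec:
    """Annular LV-like wall with a transmural helix-angle law.

    Radii and lengths in µm; angles in degrees; the axis runs through
    ``center_um`` (grid center by default) along ``axis_direction``
    (components z, y, x).  ``snr`` — the ratio of the noise-free wall
    texture's standard deviation to the noise standard deviation —
    overrides ``noise_sd`` when given.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 20.0
    inner_radius_um: float = 600.0
    outer_radius_um: float = 1100.0
    height_um: float | None = None
    center_um: tuple[float, float, float] | None = None
    axis_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    alpha_endo_deg: float = 60.0
    alpha_epi_deg: float = -60.0
    texture_wavelength_um: float = 160.0
    texture_amplitude: float = 50.0
    wall_intensity: float = 100.0
    lumen_intensity: float = 20.0
    background_intensity: float = 0.0
    noise_sd: float = 0.0
    snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_um < self.outer_radius_um:
            raise ValueError("need 0 < inner radius < outer radius")
        for a in (self.alpha_endo_deg, self.alpha_epi_deg):
            if not -90.0 <= a <= 90.0:
                raise ValueError("helix-law angles must lie in [-90, 90] deg")
        if self.texture_wavelength_um < 2 * self.voxel_size_um:
            raise ValueError(
                "texture wavelength under 2 voxels would alias (Nyquist)"
            )
        wall_voxels = (self.outer_radius_um - self.inner_radius_um) / self.voxel_size_um
        if wall_voxels < 3:
            raise ValueError("wall must be at least 3 voxels thick")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0")

    def helix_angle_deg(self, depth) -> np.ndarray:
        """The prescribed linear transmural law alpha(d)."""
        depth = np.asarray(depth, dtype=float)
        return self.alpha_endo_deg + (self.alpha_epi_deg - self.alpha_endo_deg) * depth


@dataclass
class GroundTruthOrientation:
    """Known per-voxel fiber directions of a phantom.

    ``vectors`` (z, y, x, 3) are unit, lie in the local tangential plane,
    and are NaN outside ``wall_mask``; ``depth`` is the normalized
    transmural depth map used to evaluate the helix law.
    """

    vectors: np.ndarray
    wall_mask: np.ndarray
    depth: np.ndarray
    helix_deg: np.ndarray | None = None


def _splat_trilinear(image: np.ndarray, points: np.ndarray) -> None:
    """Accumulate unit mass at fractional voxel positions (trilinear)."""
    base = np.floor(points).astype(int)
    frac = points - base
    for corner in range(8):
        off = np.array([(corner >> k) & 1 for k in (2, 1, 0)])
        idx = base + off
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < np.array(image.shape)), axis=1)
        np.add.at(image, tuple(idx[ok].T), w[ok])


def _tube_texture(
    spec: "LVPhantomSpec",
    wall: np.ndarray,
    center_um: np.ndarray,
    axis: np.ndarray,
    axial: np.ndarray,
    rng: np.random.Generator,
    tube_sigma_voxels: float = 0.8,
    tube_length_voxels: float = 40.0,
    arc_step_voxels: float = 0.25,
) -> np.ndarray:
    """Fiber-bundle texture: random helical tubes following the helix law.

    Myocyte-aggregate-like tubes are seeded at random positions in the
    wall; each runs along the exact helix of its radius (pitch angle
    ``alpha(d)``) and is splatted into the volume with a Gaussian
    cross-section of about one voxel.  The intensity is therefore
    constant along the local fiber direction and oscillates transverse to
    it in both normal directions, which keeps the structure tensor's two
    leading eigenvalues well above the smallest.  The mean tube spacing
    is half the texture wavelength.  Returned with zero mean and standard
    deviation ``texture_amplitude`` over the wall.
    """
    vox = spec.voxel_size_um
    r_in, r_out = spec.inner_radius_um / vox, spec.outer_radius_um / vox
    spacing = spec.texture_wavelength_um / vox / 2.0
    wall_volume = float(wall.sum())
    n_tubes = max(int(wall_volume / (spacing**2) / tube_length_voxels), 8)

    ax_vals = axial[wall] / vox
    u = rng.uniform(size=n_tubes)
    rho = np.sqrt(u * (r_out**2 - r_in**2) + r_in**2)  # area-uniform radii
    phi0 = rng.uniform(0.0, 2 * np.pi, size=n_tubes)
    z0 = rng.uniform(ax_vals.min() - 1.0, ax_vals.max() + 1.0, size=n_tubes)

    d = (rho - r_in) / (r_out - r_in)
    alpha = np.radians(spec.helix_angle_deg(d))
    s = np.arange(-tube_length_voxels / 2, tube_length_voxels / 2, arc_step_voxels)
    theta = phi0[:, None] + s[None, :] * np.cos(alpha)[:, None] / rho[:, None]
    zax = z0[:, None] + s[None, :] * np.sin(alpha)[:, None]

    b1, b2 = _perp_basis(axis)
    pts = (
        center_um[None, None, :] / vox
        + zax[..., None] * axis
        + rho[:, None, None]
        * (np.cos(theta)[..., None] * b1 + np.sin(theta)[..., None] * b2)
    ).reshape(-1, 3)

    image = np.zeros(wall.shape)
    _splat_trilinear(image, pts)
    image = ndi.gaussian_filter(image, tube_sigma_voxels, mode="nearest")

    tex_wall = image[wall]
    tex_wall = tex_wall - tex_wall.mean()
    sd = tex_wall.std()
    if sd > 0:
        tex_wall = tex_wall * (spec.texture_amplitude / sd)
    texture = np.zeros(wall.shape)
    texture[wall] = tex_wall
    return texture


def _world_grids(shape, voxel_size_um):
    axes = [np.arange(n, dtype=float) * voxel_size_um for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def generate_lv_phantom(
    spec: LVPhantomSpec,
) -> tuple[ImageVolume, LabelMap, GroundTruthOrientation]:
    """Build the annular LV phantom: volume, label map, ground truth.

    The label map uses 0 = background, 1 = lumen, 2 = wall.  The depth map
    is the two-distance normalization ``d = D_endo / (D_endo + D_epi)``
    computed from the label map, so the ground-truth helix law is
    evaluated on exactly the depth definition downstream analyses use.
    """
    rng = np.random.default_rng(spec.seed)
    vox = spec.voxel_size_um
    zz, yy, xx = _world_grids(spec.shape, vox)
    pos = np.stack([zz, yy, xx], axis=-1)

    center = (
        np.asarray(spec.center_um, dtype=float)
        if spec.center_um is not None
        else (np.asarray(spec.shape, dtype=float) - 1) / 2 * vox
    )
    axis = _unit(spec.axis_direction)
    rel = pos - center
    axial = rel @ axis
    radial = rel - axial[..., None] * axis
    rho = np.linalg.norm(radial, axis=-1)

    half_h = np.inf if spec.height_um is None else spec.height_um / 2
    in_height = np.abs(axial) <= half_h
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[(rho < spec.inner_radius_um) & in_height] = LUMEN
    labels[(rho >= spec.inner_radius_um) & (rho <= spec.outer_radius_um) & in_height] = WALL
    labelmap = LabelMap(data=labels, voxel_size_um=vox)
    wall = labels == WALL

    # two depth definitions that agree to half a voxel on this geometry:
    # the analytic radial depth drives the texture and ground truth; the
    # two-distance (EDT) normalization is the reusable depth-map product
    d_in = np.maximum(ndi.distance_transform_edt(labels != LUMEN) - 0.5, 0.0)
    d_out = np.maximum(ndi.distance_transform_edt(labels != BACKGROUND) - 0.5, 0.0)
    denom = d_in + d_out
    depth_edt = np.where(denom > 0, d_in / np.where(denom > 0, denom, 1.0), 0.5)
    d_analytic = np.clip(
        (rho - spec.inner_radius_um)
        / (spec.outer_radius_um - spec.inner_radius_um),
        0.0,
        1.0,
    )
    helix_deg = spec.helix_angle_deg(d_analytic)
    alpha = np.radians(helix_deg)

    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = radial / rho[..., None]
    c_hat = cross_zyx(np.broadcast_to(axis, r_hat.shape), r_hat)
    vectors = (
        np.cos(alpha)[..., None] * c_hat + np.sin(alpha)[..., None] * axis
    )
    vectors[~wall] = np.nan
    helix_deg = np.where(wall, helix_deg, np.nan)

    texture = _tube_texture(spec, wall, center, axis, axial, rng)

    intensity = np.full(spec.shape, spec.background_intensity, dtype=np.float64)
    intensity[labels == LUMEN] = spec.lumen_intensity
    intensity[wall] = spec.wall_intensity + texture[wall]

    noise_sd = spec.noise_sd
    if spec.snr is not None:
        noise_sd = float(texture[wall].std()) / spec.snr
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=spec.shape)
    depth = np.where(wall, depth_edt, np.nan)

    volume = ImageVolume(data=intensity.astype(np.float32), voxel_size_um=vox)
    truth = GroundTruthOrientation(
        vectors=vectors, wall_mask=wall, depth=depth, helix_deg=helix_deg
    )
    return volume, labelmap, truth


@dataclass(frozen=True)
class WallSlabSpec:
    """Three-sublayer wall slab (endocardium / myocardium / epicardium).

    Layers are stacked along ``normal_direction`` (flat) or as concentric
    shells around a center placed ``curvature_radius_um`` behind the wall
    mid-surface (curved).  ``offset_um``, when given, is the signed
    distance of the endocardial surface from the world origin along the
    normal; by default the wall is centered in the grid with the surface
    on a voxel boundary, so axis-aligned flat slabs have exact integer
    label runs.
    """

    shape: tuple[int, int, int] = (160, 32, 32)
    voxel_size_um: float = 20.0
    thickness_endo_um: float = 200.0
    thickness_myo_um: float = 2000.0
    thickness_epi_um: float = 400.0
    normal_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    curvature_radius_um: float | None = None
    offset_um: float | None = None
    intensity_endo: float = 120.0
    intensity_myo: float = 80.0
    intensity_epi: float = 140.0
    intensity_background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.thicknesses_um:
            if t <= 0:
                raise ValueError("all sublayer thicknesses must be > 0")
            if t < 2 * self.voxel_size_um:
                raise ValueError("each sublayer must span at least 2 voxels")
        if self.curvature_radius_um is not None and self.curvature_radius_um <= 0:
            raise ValueError("curvature radius must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def thicknesses_um(self) -> tuple[float, float, float]:
        return (self.thickness_endo_um, self.thickness_myo_um, self.thickness_epi_um)

    @property
    def total_thickness_um(self) -> float:
        return float(sum(self.thicknesses_um))


def generate_wall_slab(spec: WallSlabSpec) -> tuple[ImageVolume, LabelMap]:
    """Build the layered wall slab: label map (1/2/3 = endo/myo/epi) + volume.

    Layer membership is decided by the signed distance of each voxel
    center from the endocardial surface, measured along the normal (flat)
    or radially from the curvature center (curved).
    """
    rng = np.random.default_rng(spec.seed)
    vox = spec.voxel_size_um
    zz, yy, xx = _world_grids(spec.shape, vox)
    pos = np.stack([zz, yy, xx], axis=-1)
    normal = _unit(spec.normal_direction)
    total = spec.total_thickness_um

    if spec.offset_um is not None:
        offset = spec.offset_um
    else:
        # center the wall; land the endo surface on a voxel boundary
        extent = pos.reshape(-1, 3) @ normal
        mid_vox = (extent.min() + extent.max()) / 2 / vox
        offset = (np.floor(mid_vox - total / (2 * vox)) - 0.5) * vox

    if spec.curvature_radius_um is None:
        s = pos @ normal - offset
    else:
        center = offset * normal - (spec.curvature_radius_um - total / 2) * normal
        s = np.linalg.norm(pos - center, axis=-1) - (
            spec.curvature_radius_um - total / 2
        )

    t1, t2, t3 = spec.thicknesses_um
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[(s >= 0) & (s < t1)] = LAYER_ENDO
    labels[(s >= t1) & (s < t1 + t2)] = LAYER_MYO
    labels[(s >= t1 + t2) & (s < total)] = LAYER_EPI

    levels = {
        BACKGROUND: spec.intensity_background,
        LAYER_ENDO: spec.intensity_endo,
        LAYER_MYO: spec.intensity_myo,
        LAYER_EPI: spec.intensity_epi,
    }
    intensity = np.vectorize(levels.get, otypes=[float])(labels)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return (
        ImageVolume(data=intensity.astype(np.float32), voxel_size_um=vox),
        LabelMap(data=labels, voxel_size_um=vox),
    )


@dataclass(frozen=True)
class MADPhantomSpec:
    """Hinge/crest curve pair with a prescribed axial displacement.

    The crest curve lies on a circle of ``annulus_radius_um`` in the plane
    through ``center_um`` normal to ``axis_direction``; the hinge curve is
    the crest displaced along the axis by ``displacement_um`` (a constant
    or a callable of angle in degrees, >= 0).  Curves are sampled at
    ``sample_step_deg`` (1 degree by default, so a 5-degree analysis step
    is always a sub-sampling).
    """

    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    annulus_radius_um: float = 15000.0
    arc_span_deg: float = 240.0
    displacement_um: float | Callable[[np.ndarray], np.ndarray] = 0.0
    sample_step_deg: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.arc_span_deg <= 360.0:
            raise ValueError("arc span must lie in (0, 360] degrees")
        if self.annulus_radius_um <= 0:
            raise ValueError("annulus radius must be > 0")
        if self.sample_step_deg <= 0:
            raise ValueError("sample step must be > 0")

    def displacement_at(self, angles_deg: np.ndarray) -> np.ndarray:
        if callable(self.displacement_um):
            d = np.asarray(self.displacement_um(np.asarray(angles_deg, float)), float)
        else:
            d = np.full(np.shape(angles_deg), float(self.displacement_um))
        if np.any(d < 0):
            raise ValueError("disjunction displacements must be >= 0")
        return d


def generate_mad_phantom(
    spec: MADPhantomSpec,
) -> tuple[LandmarkCurve, LandmarkCurve]:
    """Sample the hinge and crest landmark curves around the annulus arc."""
    angles = np.arange(
        0.0, spec.arc_span_deg + spec.sample_step_deg / 2, spec.sample_step_deg
    )
    axis = _unit(spec.axis_direction)
    b1, b2 = _perp_basis(axis)
    center = np.asarray(spec.center_um, dtype=float)
    theta = np.radians(angles)
    ring = (
        center
        + spec.annulus_radius_um
        * (np.cos(theta)[:, None] * b1 + np.sin(theta)[:, None] * b2)
    )
    disp = spec.displacement_at(angles)
    crest = LandmarkCurve(points_um=ring, angles_deg=angles)
    hinge = LandmarkCurve(points_um=ring + disp[:, None] * axis, angles_deg=angles)
    return hinge, crest


def add_noise(volume: ImageVolume, sd: float, seed: int) -> ImageVolume:
    """Additive zero-mean Gaussian noise, deterministic for a fixed seed."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return ImageVolume(data=volume.data.copy(), voxel_size_um=volume.voxel_size_um)
    rng = np.random.default_rng(seed)
    noisy = volume.data + rng.normal(0.0, sd, size=volume.shape).astype(
        volume.data.dtype if np.issubdtype(volume.data.dtype, np.floating) else float
    )
    return ImageVolume(data=noisy, voxel_size_um=volume.voxel_size_um)
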