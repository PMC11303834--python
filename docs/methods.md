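# Methods

This note documents the models, numerical choices and limitations of the
package in one place. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)`, 0-based, voxel centers at integer
indices, and every vector quantity stores its components in the same
`(z, y, x)` order (the cross product is computed through a component
reversal, since `(z, y, x)` is an odd permutation of `(x, y, z)`).
World coordinates are micrometres; voxels are isotropic. Anisotropic
inputs are rejected at read time unless an explicit voxel-size override
is given — measurements are calibrated, so guessing would corrupt every
downstream number.

## Structure-tensor orientation

The fiber direction is the eigenvector of the smallest eigenvalue of
`T = G_σs ∗ (∇I ∇Iᵀ)`, with Gaussian-derivative gradients at scale σ_g
and componentwise tensor smoothing at σ_s, both with mirror padding.

* **Defaults σ_g = 1.0, σ_s = 2.5 voxels.** The integration scale must
  exceed the derivative scale for the tensor to accumulate gradient
  directions over a neighborhood; these values suit textures with
  transverse features of roughly 4–12 voxels, which is where the phantom
  generator and micro-CT myocardium at ~20 µm both sit. Both are
  configurable per run.
* **Validity flags instead of guesses.** A voxel is invalid when λ₁ ≤ 0,
  when `(λ₂ − λ₃)/λ₁ < eig_tol` (default 1e-3 — no unique direction of
  least change), when any tensor component is NaN, within `ceil(3 σ_s)`
  voxels of the volume border (incomplete filter support), or outside
  the analysis mask. Consumers propagate the flags; radial-looking
  fibers are additionally rejected at the helix-angle stage.
* **Masked analysis.** When a mask (the myocardial wall) is supplied,
  intensities outside it are replaced by a normalized-convolution
  extension `G(I·M)/G(M)` before filtering. Without this, the sharp
  wall/lumen/background steps dominate the tensor within ~3σ of the
  surfaces and bias near-surface orientations toward the surface normal.
* **Sign handling.** e₃ is an axis. For storage it is canonicalized
  (largest-magnitude component positive); every consumer is
  sign-invariant, and a test flips the whole field and checks the helix
  map is unchanged.
* **PSD tolerance.** Tensors are stored in float32; eigenvalues of
  numerically empty voxels carry rounding dust at the 1e-16 level of the
  field scale. The positive-semidefiniteness check therefore allows
  `λ_min ≥ −1e-9·λ₁ − 1e-12·max(λ₁)`.

## Cylindrical geometry and the helical angle

The LV centerline is fit as a straight line: per-slice mask centroids
(empty slices skipped, at least three required) followed by a
total-least-squares axis. A straight axis, not a curved spline, is the
deliberate default — the transverse plane is taken normal to this single
fitted axis, which is what matters for tilted hearts; a user-supplied
centerline file overrides the fit. A curved-centerline variant would
change the frame only near the apex and is noted as an extension.

The per-voxel triad is `ẑ` = axis direction, `r̂` = unit perpendicular
from the axis, `ĉ = ẑ × r̂` (right-handed; verified orthonormal to
1e-9). Voxels within one voxel of the axis are undefined. The helical
angle is `atan2(e₃·ẑ, e₃·ĉ)` folded into [−90°, +90°]; the sign
convention is right-handed (positive α_h = longitudinal component along
+ẑ accompanying positive circumferential component), with the axis
orientation normalized so its z-component is positive. Projections with
tangential norm < 0.2 are flagged (near-radial fiber: the angle would be
numerically meaningless).

Transmural depth is the two-distance normalization
`d = D_endo/(D_endo + D_epi)` from Euclidean distance transforms, with
half a voxel subtracted from each distance so the surfaces themselves
sit at d = 0 and d = 1. This definition is well behaved on curved walls
and reduces to linear depth in slabs; a brute-force point-to-set
distance oracle verifies it in the tests.

## The phantom generators

The phantoms define the study conditions; their defaults are fixed and
are not tuned per experiment.

**LV phantom** (default 128³ voxels at 20 µm): an annular wall, inner
radius 600 µm, outer 1100 µm, around an axis through the grid center;
helix law `α(d) = α_endo + (α_epi − α_endo)·d` with defaults +60° → −60°
(the physiological endo-to-epi range); wall/lumen/background intensity
levels 100/20/0; texture sd 50; optional Gaussian noise specified either
as an sd or as an SNR (texture sd ÷ noise sd).

The fiber texture is a bundle of discrete myocyte-aggregate-like tubes:
random helices seeded area-uniformly in the wall, each following the
exact helix of its own radius, splatted trilinearly at 0.25-voxel arc
steps and blurred with a 0.8-voxel Gaussian cross-section; mean tube
spacing is half the texture wavelength (default 160 µm = 8 voxels).
Intensity is exactly constant along each tube and oscillates transverse
to it in both normal directions, so the structure tensor's two leading
eigenvalues stay well separated from the smallest. Lamina-style
textures built from a global helical phase were evaluated and rejected:
their phase accumulates radial frequency with azimuth and twist until it
aliases, corrupting the gradient field.

Two depth definitions coexist by design: the analytic radial depth
`(ρ − r_in)/(r_out − r_in)` drives the tube geometry and the ground-truth
vectors (it is exact for the cylindrical geometry), while the shipped
depth map is the EDT-based two-distance normalization used on arbitrary
walls. On this geometry they agree to half a voxel.

**Wall slab**: three contiguous sublayers (endocardium / myocardium /
epicardium, defaults 200/2000/400 µm) assigned by signed distance along
a configurable normal, or radially from a curvature center for curved
walls. The default placement puts the endocardial surface on a voxel
boundary, so axis-aligned slabs have exact integer label runs and the
thickness measurement has a zero-error reference case.

**MAD phantom**: crest curve on a circle in the plane normal to the
annular axis; hinge curve displaced along the axis by a prescribed
per-angle function (constant or callable, ≥ 0). Curves are sampled at
1°, so the 5° analysis step is always a strict sub-sampling. The
construction is deterministic — there is no randomness to seed.

What the phantoms do *not* emulate: phase-contrast fringes, beam
hardening, ring artifacts, multi-chamber anatomy, trabeculation, or
fiber dispersion within a location. Passing recovery tests therefore
demonstrates correctness of the estimators under controlled geometry and
noise, not performance on artifact-laden real scans.

## Accuracy of helix-angle recovery, and why the bounds differ

On the constant-law phantom (no transmural twist) the noise-free median
angular error between recovered and true fiber directions at default
scales is ≈ 2.4°, and the masked mean helix angle matches the
prescribed level within 0.5° at SNR 10 for levels −60°, 0°, +60°.

On the default twisted phantom (+60° → −60° across a 25-voxel wall,
i.e. 4.8°/voxel) the median *helix-angle* error at SNR 10 is ≈ 4.3°.
The extra error is geometric, not estimator noise: any finite
integration window mixes fibers whose orientation differs across the
wall, and near the surfaces the window sees tubes on one side only,
attenuating the recovered angle toward mid-wall values. This shrinks
with wall thickness (the 64³ phantom is ~2× worse than 128³) and is why
the twisted-phantom bound is 5° while the pure-estimator bound is 3°.
SNR 10 noise is negligible against the texture at these scales — the
noise-free and SNR-10 errors are nearly identical.

## Thickness measurement

Locations are spread with equal spacing along the principal extent of
the wall mid-surface (the set of wall voxels where the side-to-side
depth field crosses 0.5 between 6-neighbors), keeping only candidates
whose normal ray can traverse the estimated wall chord without leaving
the volume; ties are broken with the seeded generator, so sampling is
reproducible. The local normal is the gradient of the smoothed depth
field. Rays march in 0.25-voxel steps with nearest-voxel label lookup,
offset half a step so axis-aligned boundaries (at half-integer
positions) never coincide with sample points — this makes the
axis-aligned case exact rather than merely close. Rays that exit the
volume mid-wall or miss a sublayer are skipped with a warning; fewer
usable locations than requested is an error that reports the usable
count. This is a caliper-style chord measurement, not sphere-fitting
local thickness, mirroring how such measurements are made manually.

## MAD profiling

Both curves are parameterized by their angle about the annular axis
(origin at the first hinge point), checked for monotonicity and for
angular gaps larger than the analysis step (interpolation is refused and
the gap reported), then linearly interpolated at each 5° node of the
overlapping arc. The default distance is the axial displacement —
disjunction is a separation along the LV long axis — with a Euclidean
mode available; the Euclidean distance is never smaller than the axial
one.

## CNR

`CNR = |μ_tissue − μ_background| / σ_background` with a single
background region (embedding agar) and replicate tissue ROIs (five per
region by convention; any number is accepted). This is the most common
single-background CNR definition; it is documented prominently here
because competing definitions exist, and it is checked to be exactly
invariant under positive-gain affine intensity maps. Sample sd uses
ddof = 1. Zero background sd and overlapping ROIs are hard errors.

## Statistics

Pooled-variance unpaired t tests by default (Welch behind a flag — which
variant commercial packages use by default is ambiguous, so both are
provided). The Holm-Sidak adjustment is implemented directly from the
step-down closed form and cross-checked in the tests against an
independent reference implementation to 1e-12. Families are formed per
sublayer across the single-factor contrasts (control vs diseased within
each chamber, left vs right within each heart); a Monte-Carlo experiment
with 1000 seeded replicates of a 4-group global null (n = 15 per group,
matching the 15 measurement locations) confirms the family-wise error
rate stays within two binomial standard errors of α = 0.05.

## Problem sizes and determinism

The shipped tests and the acceptance script use the 128³ phantom for
helix recovery and tensor checks, 64³ phantoms for invariance tests,
160-deep slabs for thickness, and 1000 replicates for the error-rate
simulation — sizes chosen so the whole suite completes in well under a
minute of compute while keeping every estimate's Monte-Carlo error far
below its tolerance. All generators and samplers take explicit seeds;
a fixed (config, seed) pair reproduces every output byte for byte, and
the pipeline manifest records a SHA-256 per file to make that checkable.

## Known limitations

* The straight-axis cylindrical frame misrepresents the apex of a real
  ventricle; a curved centerline is a planned extension.
* Near-surface helix angles are biased toward mid-wall values by
  one-sided support (see above); analyses of thin walls should treat
  the outermost and innermost depth bins with care.
* Secondary/tertiary eigenvector (sheetlet) analysis, tractography, and
  automatic segmentation of layers or landmark curves are out of scope:
  label maps and curves are inputs.
* The CNR formula is a documented stand-in for whichever exact variant a
  given acquisition pipeline reports; compare absolute values across
  tools with caution.
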