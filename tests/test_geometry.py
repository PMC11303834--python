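"""Centerline fitting, cylindrical frames, and helix-angle mapping."""

import numpy as np
import pytest

import myomap
from myomap.geometry import (
    Centerline,
    estimate_centerline,
    local_cylindrical_frame,
    transmural_profile,
)
from myomap.orientation import OrientationConfig, OrientationField
from myomap.volume import LabelMap


def _annulus_mask(shape, cy, cx, r_in, r_out):
    y, x = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    ring = ((y - cy) ** 2 + (x - cx) ** 2 >= r_in**2) & (
        (y - cy) ** 2 + (x - cx) ** 2 <= r_out**2
    )
    return np.broadcast_to(ring, shape).copy()


class TestCenterline:
    def test_axis_aligned_annulus_recovers_exact_center(self):
        mask = _annulus_mask((20, 40, 40), cy=19.5, cx=19.5, r_in=8, r_out=14)
        cl = estimate_centerline(mask, voxel_size_um=10.0)
        assert np.allclose(cl.direction, [1.0, 0.0, 0.0], atol=1e-12)
        # every per-slice centroid sits at the analytic center
        assert np.allclose(cl.centroids_um[:, 1:], 19.5 * 10.0, atol=1e-9)

    def test_tilted_annulus_axis_recovered_within_half_degree(self):
        # cylinder tilted 10 degrees in the z-x plane
        tilt = np.radians(10.0)
        shape = (48, 48, 48)
        z, y, x = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                              indexing="ij")
        axis = np.array([np.cos(tilt), 0.0, np.sin(tilt)])
        rel = np.stack([z - 24, y - 24, x - 24], axis=-1)
        axial = rel @ axis
        rho = np.linalg.norm(rel - axial[..., None] * axis, axis=-1)
        mask = (rho >= 8) & (rho <= 14)
        cl = estimate_centerline(mask, voxel_size_um=20.0)
        angle = np.degrees(np.arccos(np.clip(abs(cl.direction @ axis), 0, 1)))
        assert angle < 0.5

    def test_empty_mid_slice_is_skipped_without_changing_axis(self):
        mask = _annulus_mask((20, 40, 40), cy=20, cx=20, r_in=8, r_out=14)
        cl_full = estimate_centerline(mask, voxel_size_um=10.0)
        gap = mask.copy()
        gap[10] = False
        cl_gap = estimate_centerline(gap, voxel_size_um=10.0)
        assert np.allclose(cl_full.direction, cl_gap.direction, atol=1e-12)
        assert np.allclose(cl_full.point_um[1:], cl_gap.point_um[1:], atol=1e-9)

    def test_fewer_than_three_slices_is_an_error(self):
        mask = np.zeros((5, 16, 16), dtype=bool)
        mask[2, 4:12, 4:12] = True
        with pytest.raises(ValueError, match="3 nonempty slices"):
            estimate_centerline(mask, voxel_size_um=10.0)


class TestCylindricalFrame:
    @pytest.fixture()
    def axis_z(self):
        return Centerline(
            point_um=np.zeros(3), direction=np.array([1.0, 0.0, 0.0]),
            centroids_um=np.zeros((3, 3)),
        )

    def test_axis_aligned_triad_matches_analytic_directions(self, axis_z):
        # a point on the +x side: r_hat = x, c_hat = z x x = y
        frame = local_cylindrical_frame(np.array([[0.0, 0.0, 5.0]]), axis_z)
        assert np.allclose(frame.r_hat[0], [0.0, 0.0, 1.0], atol=1e-12)
        assert np.allclose(frame.c_hat[0], [0.0, 1.0, 0.0], atol=1e-12)
        assert np.allclose(frame.z_hat[0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_triads_are_right_handed_and_orthonormal(self, axis_z, rng):
        pos = rng.uniform(-100, 100, size=(1000, 3))
        pos = pos[np.linalg.norm(pos[:, 1:], axis=1) > 2.0]
        frame = local_cylindrical_frame(pos, axis_z, min_radius_um=1.0)
        for u in (frame.r_hat, frame.c_hat, frame.z_hat):
            assert np.allclose(np.linalg.norm(u, axis=1), 1.0, atol=1e-9)
        assert np.allclose(
            np.einsum("ij,ij->i", frame.r_hat, frame.c_hat), 0.0, atol=1e-9
        )
        assert np.allclose(
            np.einsum("ij,ij->i", frame.r_hat, frame.z_hat), 0.0, atol=1e-9
        )
        cross = np.cross(frame.r_hat[:, ::-1], frame.c_hat[:, ::-1])[:, ::-1]
        assert np.allclose(cross, frame.z_hat, atol=1e-6)

    def test_points_on_the_axis_are_flagged_undefined(self, axis_z):
        frame = local_cylindrical_frame(
            np.array([[3.0, 0.0, 0.5]]), axis_z, min_radius_um=1.0
        )
        assert not frame.valid[0]
        assert np.isnan(frame.r_hat[0]).all()


class TestHelixAngle:
    def _field_with_vector(self, shape, vec):
        vectors = np.broadcast_to(np.asarray(vec, float), shape + (3,)).copy()
        eigenvalues = np.broadcast_to([3.0, 2.0, 1.0], shape + (3,)).copy()
        return OrientationField(
            vectors=vectors.astype(np.float32),
            eigenvalues=eigenvalues.astype(np.float32),
            valid=np.ones(shape, dtype=bool),
        )

    @pytest.fixture()
    def centerline(self):
        return Centerline(
            point_um=np.array([0.0, 31.0, 31.0]),
            direction=np.array([1.0, 0.0, 0.0]),
            centroids_um=np.zeros((3, 3)),
        )

    @pytest.mark.parametrize(
        "angle_fn,expected",
        [
            (lambda c, z: c, 0.0),  # circumferential
            (lambda c, z: z, 90.0),  # longitudinal
            (lambda c, z: (c + z) / np.sqrt(2), 45.0),  # right-handed helix
        ],
    )
    def test_analytic_directions_map_to_their_angles(
        self, centerline, angle_fn, expected
    ):
        shape = (8, 8, 8)
        mask = np.zeros(shape, dtype=bool)
        mask[4, 2, 5] = True  # a point on the +x side of the axis
        c_hat = np.array([0.0, 1.0, 0.0])  # approx: exact only on the +x ray
        z_hat = np.array([1.0, 0.0, 0.0])
        # place the probe exactly on the +x ray from the axis
        probe_mask = np.zeros(shape, dtype=bool)
        probe_mask[4, 3, 6] = True
        cl = Centerline(
            point_um=np.array([0.0, 30.0, 20.0]),
            direction=np.array([1.0, 0.0, 0.0]),
            centroids_um=np.zeros((3, 3)),
        )
        field = self._field_with_vector(shape, angle_fn(c_hat, z_hat))
        h = myomap.compute_helix_angle_map(field, cl, probe_mask, voxel_size_um=10.0)
        assert h.valid[4, 3, 6]
        assert abs(h.angle_deg[4, 3, 6]) == pytest.approx(abs(expected), abs=1e-4)
        if 0 < expected < 90:
            assert h.angle_deg[4, 3, 6] == pytest.approx(expected, abs=1e-4)

    def test_near_radial_fibers_are_flagged_invalid(self, centerline):
        shape = (8, 8, 8)
        mask = np.zeros(shape, dtype=bool)
        mask[4, 3, 7] = True
        cl = Centerline(
            point_um=np.array([0.0, 30.0, 20.0]),
            direction=np.array([1.0, 0.0, 0.0]),
            centroids_um=np.zeros((3, 3)),
        )
        field = self._field_with_vector(shape, [0.0, 0.0, 1.0])  # radial at +x
        h = myomap.compute_helix_angle_map(field, cl, mask, voxel_size_um=10.0)
        assert not h.valid[4, 3, 7]
        assert np.isnan(h.angle_deg[4, 3, 7])

    def test_invalid_orientation_voxels_propagate(self, lv_small):
        spec, volume, labelmap, truth = lv_small
        field = myomap.compute_orientation(
            volume, OrientationConfig(mask=truth.wall_mask)
        )
        cl = myomap.estimate_centerline(labelmap, label=2)
        h = myomap.compute_helix_angle_map(
            field, cl, truth.wall_mask, voxel_size_um=20.0
        )
        assert not (h.valid & ~field.valid).any()
        assert np.isnan(h.angle_deg[~h.valid]).all()

    @pytest.mark.parametrize("level", [-60.0, 0.0, 60.0])
    def test_constant_law_mean_angle_matches_prescription(self, level):
        spec = myomap.LVPhantomSpec(
            shape=(64, 64, 64), inner_radius_um=280.0, outer_radius_um=520.0,
            alpha_endo_deg=level, alpha_epi_deg=level, snr=10.0, seed=3,
        )
        volume, labelmap, truth = myomap.generate_lv_phantom(spec)
        field = myomap.compute_orientation(
            volume, OrientationConfig(mask=truth.wall_mask)
        )
        cl = myomap.estimate_centerline(labelmap, label=2)
        h = myomap.compute_helix_angle_map(
            field, cl, truth.wall_mask, voxel_size_um=20.0
        )
        assert abs(float(np.mean(h.angle_deg[h.valid])) - level) < 2.0

    def test_rotation_of_volume_and_centerline_preserves_angles(self, lv_small):
        """A 90-deg rotation about the LV axis leaves the helix map unchanged."""
        spec, volume, labelmap, truth = lv_small
        field = myomap.compute_orientation(
            volume, OrientationConfig(mask=truth.wall_mask)
        )
        cl = myomap.estimate_centerline(labelmap, label=2)
        h1 = myomap.compute_helix_angle_map(
            field, cl, truth.wall_mask, voxel_size_um=20.0
        )

        rot = myomap.ImageVolume(
            np.rot90(volume.data, k=1, axes=(1, 2)).copy(), 20.0
        )
        mask_r = np.rot90(truth.wall_mask, k=1, axes=(1, 2)).copy()
        lab_r = LabelMap(np.rot90(labelmap.data, k=1, axes=(1, 2)).copy(), 20.0)
        field_r = myomap.compute_orientation(rot, OrientationConfig(mask=mask_r))
        cl_r = myomap.estimate_centerline(lab_r, label=2)
        h2 = myomap.compute_helix_angle_map(field_r, cl_r, mask_r, voxel_size_um=20.0)

        a1 = np.rot90(h1.angle_deg, k=1, axes=(1, 2))
        both = np.rot90(h1.valid, k=1, axes=(1, 2)) & h2.valid
        diff = np.abs(a1[both] - h2.angle_deg[both])
        diff = np.minimum(diff, 180.0 - diff)
        assert np.percentile(diff, 99) < 1.0


class TestTransmuralProfile:
    def test_twisted_phantom_profile_decreases_with_depth(self, lv_small):
        spec, volume, labelmap, truth = lv_small
        field = myomap.compute_orientation(
            volume, OrientationConfig(mask=truth.wall_mask)
        )
        cl = myomap.estimate_centerline(labelmap, label=2)
        h = myomap.compute_helix_angle_map(
            field, cl, truth.wall_mask, voxel_size_um=20.0
        )
        prof = transmural_profile(h, truth.depth, n_bins=10)
        assert len(prof) == 10
        assert (prof["n"] > 100).all()
        assert np.all(np.diff(prof["mean_deg"]) < 0)

    def test_empty_selection_is_an_error(self):
        h = myomap.HelixAngleMap(
            angle_deg=np.full((4, 4, 4), np.nan, dtype=np.float32),
            valid=np.zeros((4, 4, 4), dtype=bool),
            voxel_size_um=20.0,
        )
        with pytest.raises(ValueError):
            transmural_profile(h, np.full((4, 4, 4), np.nan))
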