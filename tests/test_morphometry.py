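"""Thickness measurement, MAD profiling, and CNR quantification."""

import numpy as np
import pandas as pd
import pytest

import myomap
from myomap.geometry import Centerline
from myomap.morphometry import compute_cnr, compute_mad_profile, measure_layer_thickness
from myomap.volume import ImageVolume, LabelMap


class TestLayerThickness:
    def test_axis_aligned_slab_is_measured_exactly(self, flat_slab):
        spec, volume, labelmap = flat_slab
        result = measure_layer_thickness(labelmap, n_locations=15, seed=0)
        t = result.table
        assert sorted(t["sublayer"].unique()) == [
            "endocardium", "epicardium", "myocardium",
        ]
        assert t.groupby("location").size().eq(3).all()
        assert len(t) == 45
        for name, expected in [
            ("endocardium", 200.0), ("myocardium", 2000.0), ("epicardium", 400.0),
        ]:
            vals = t.loc[t["sublayer"] == name, "thickness_um"]
            assert np.allclose(vals, expected), name

    def test_rotated_slab_recovered_within_one_voxel(self):
        spec = myomap.WallSlabSpec(
            shape=(160, 96, 48),
            normal_direction=(np.cos(np.radians(30)), np.sin(np.radians(30)), 0.0),
        )
        _, labelmap = myomap.generate_wall_slab(spec)
        result = measure_layer_thickness(labelmap, n_locations=15, seed=0)
        for name, expected in [
            ("endocardium", 200.0), ("myocardium", 2000.0), ("epicardium", 400.0),
        ]:
            vals = result.table.loc[result.table["sublayer"] == name, "thickness_um"]
            assert np.all(np.abs(vals - expected) <= 20.0), name

    def test_curved_wall_matches_brute_force_ray_oracle(self):
        spec = myomap.WallSlabSpec(
            shape=(160, 96, 96),
            thickness_endo_um=200.0,
            thickness_myo_um=600.0,
            thickness_epi_um=400.0,
            curvature_radius_um=10000.0,
            offset_um=600.0,
        )
        _, labelmap = myomap.generate_wall_slab(spec)
        result = measure_layer_thickness(labelmap, n_locations=15, seed=1)
        t = result.table
        assert t.groupby("location").size().eq(3).all()
        assert len(t) == 45
        # on the curved slab every radial chord has the prescribed layer
        # thicknesses; allow one voxel of discretization
        for name, expected in [
            ("endocardium", 200.0), ("myocardium", 600.0), ("epicardium", 400.0),
        ]:
            vals = t.loc[t["sublayer"] == name, "thickness_um"]
            assert np.all(np.abs(vals - expected) <= 20.0), name

    def test_sublayer_sum_equals_total_wall_chord(self, flat_slab):
        spec, volume, labelmap = flat_slab
        result = measure_layer_thickness(labelmap, n_locations=10, seed=2)
        totals = result.table.groupby("location")["thickness_um"].sum()
        assert np.all(np.abs(totals - spec.total_thickness_um) <= 20.0)

    def test_sampling_is_reproducible_by_seed(self, flat_slab):
        spec, volume, labelmap = flat_slab
        a = measure_layer_thickness(labelmap, n_locations=7, seed=5)
        b = measure_layer_thickness(labelmap, n_locations=7, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_unreachable_locations_raise_with_count(self):
        # wall touching the volume border: every ray exits before traversal
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[0:3] = 1
        data[3:15] = 2
        data[15:20] = 3  # epicardium runs into the border: no background above
        labelmap = LabelMap(data, 20.0)
        with pytest.raises(ValueError):
            measure_layer_thickness(labelmap, n_locations=5, seed=0)


class TestMADProfile:
    AXIS = (np.zeros(3), np.array([1.0, 0.0, 0.0]))

    def test_coincident_curves_give_identically_zero_profile(self):
        hinge, crest = myomap.generate_mad_phantom(myomap.MADPhantomSpec())
        prof = compute_mad_profile(hinge, crest, self.AXIS)
        assert np.all(prof.distance_um == 0.0)
        assert np.allclose(np.diff(prof.angles_deg), 5.0)

    def test_constant_offset_recovered_exactly_at_every_node(self):
        spec = myomap.MADPhantomSpec(displacement_um=4000.0)
        hinge, crest = myomap.generate_mad_phantom(spec)
        prof = compute_mad_profile(hinge, crest, self.AXIS)
        assert np.allclose(prof.distance_um, 4000.0, atol=1e-9)

    def test_sinusoidal_offset_matches_prescription_within_a_micron(self):
        f = lambda a: 1000.0 * (1.0 + np.sin(np.radians(2.0 * a)))  # noqa: E731
        spec = myomap.MADPhantomSpec(arc_span_deg=240.0, displacement_um=f)
        hinge, crest = myomap.generate_mad_phantom(spec)
        prof = compute_mad_profile(hinge, crest, self.AXIS)
        assert np.all(np.abs(prof.distance_um - f(prof.angles_deg)) < 1.0)

    def test_euclidean_mode_bounds_axial_mode_from_above(self):
        f = lambda a: 500.0 + 5.0 * a  # noqa: E731
        spec = myomap.MADPhantomSpec(arc_span_deg=120.0, displacement_um=f)
        hinge, crest = myomap.generate_mad_phantom(spec)
        ax = compute_mad_profile(hinge, crest, self.AXIS, mode="axial")
        eu = compute_mad_profile(hinge, crest, self.AXIS, mode="euclidean")
        assert np.all(eu.distance_um >= ax.distance_um - 1e-9)

    def test_rigid_rotation_of_curves_and_axis_preserves_profile(self):
        f = lambda a: 1500.0 + 800.0 * np.cos(np.radians(a))  # noqa: E731
        spec = myomap.MADPhantomSpec(arc_span_deg=200.0, displacement_um=f)
        hinge, crest = myomap.generate_mad_phantom(spec)
        prof1 = compute_mad_profile(hinge, crest, self.AXIS)

        theta = np.radians(25.0)
        rot = np.array(
            [
                [np.cos(theta), np.sin(theta), 0.0],
                [-np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )  # rotation in the z-y plane, components (z, y, x)
        h2 = myomap.LandmarkCurve(hinge.points_um @ rot.T, hinge.angles_deg)
        c2 = myomap.LandmarkCurve(crest.points_um @ rot.T, crest.angles_deg)
        axis2 = (rot @ self.AXIS[0], rot @ self.AXIS[1])
        prof2 = compute_mad_profile(h2, c2, axis2)
        assert np.allclose(prof1.distance_um, prof2.distance_um, atol=1e-6)

    def test_non_overlapping_arcs_are_rejected(self):
        spec = myomap.MADPhantomSpec(arc_span_deg=90.0)
        hinge, crest = myomap.generate_mad_phantom(spec)
        # rotate the crest a half turn away so the arcs cannot overlap
        rot = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
        crest_far = myomap.LandmarkCurve(crest.points_um @ rot.T)
        with pytest.raises(ValueError):
            compute_mad_profile(hinge, crest_far, self.AXIS)

    def test_angular_gaps_larger_than_step_refuse_interpolation(self):
        spec = myomap.MADPhantomSpec(arc_span_deg=120.0, sample_step_deg=1.0)
        hinge, crest = myomap.generate_mad_phantom(spec)
        keep = np.ones(len(hinge), dtype=bool)
        keep[30:45] = False  # carve a 15-degree hole
        gappy = myomap.LandmarkCurve(hinge.points_um[keep], hinge.angles_deg[keep])
        with pytest.raises(ValueError, match="gap"):
            compute_mad_profile(gappy, crest, self.AXIS)

    def test_centerline_object_is_accepted_as_axis(self):
        hinge, crest = myomap.generate_mad_phantom(
            myomap.MADPhantomSpec(displacement_um=100.0)
        )
        cl = Centerline(
            point_um=np.zeros(3), direction=np.array([1.0, 0.0, 0.0]),
            centroids_um=np.zeros((3, 3)),
        )
        prof = compute_mad_profile(hinge, crest, cl)
        assert np.allclose(prof.distance_um, 100.0, atol=1e-9)


def _cnr_fixture(rng):
    """Volume with exact tissue/background statistics in labelled ROIs."""
    data = rng.normal(0.0, 1.0, size=(24, 24, 24))
    tissue = np.zeros((24, 24, 24), dtype=np.uint8)
    background = np.zeros((24, 24, 24), dtype=np.uint8)
    background[2:10, 2:10, 2:10] = 1
    for rep, z in enumerate(range(12, 22, 2), start=1):
        tissue[z, 12:20, 12:20] = rep

    # force the background sample to mean 50, sd 10 and tissue to mean 100
    b = data[background > 0]
    data[background > 0] = (b - b.mean()) / b.std(ddof=1) * 10.0 + 50.0
    for rep in range(1, 6):
        t = data[tissue == rep]
        data[tissue == rep] = t - t.mean() + 100.0
    return ImageVolume(data, 20.0), LabelMap(tissue, 20.0), LabelMap(background, 20.0)


class TestCNR:
    def test_worked_example_means_100_50_sd_10_gives_cnr_5(self, rng):
        volume, tissue, background = _cnr_fixture(rng)
        table = compute_cnr(volume, tissue, background)
        assert len(table) == 5
        assert np.allclose(table["cnr"], 5.0, atol=1e-9)
        assert np.allclose(table["background_mean"], 50.0)
        assert np.allclose(table["background_sd"], 10.0)

    def test_tissue_with_background_mean_gives_zero_cnr(self, rng):
        volume, tissue, background = _cnr_fixture(rng)
        shifted = volume.data.copy()
        shifted[tissue.data > 0] -= 50.0  # tissue mean now equals background
        table = compute_cnr(ImageVolume(shifted, 20.0), tissue, background)
        assert np.allclose(table["cnr"], 0.0, atol=1e-9)

    def test_affine_intensity_maps_leave_cnr_unchanged(self, rng):
        volume, tissue, background = _cnr_fixture(rng)
        base = compute_cnr(volume, tissue, background)["cnr"].to_numpy()
        for gain, offset in [(3.0, 0.0), (1.0, 123.0), (0.25, -7.0)]:
            mapped = ImageVolume(gain * volume.data + offset, 20.0)
            got = compute_cnr(mapped, tissue, background)["cnr"].to_numpy()
            assert np.max(np.abs(got - base) / base) < 1e-10

    def test_overlapping_rois_are_rejected(self, rng):
        volume, tissue, background = _cnr_fixture(rng)
        bad = background.data.copy()
        bad[tissue.data > 0] = 1
        with pytest.raises(ValueError, match="overlap"):
            compute_cnr(volume, tissue, LabelMap(bad, 20.0))

    def test_zero_background_sd_is_undefined(self):
        data = np.zeros((16, 16, 16))
        data[8:, :, :] = 100.0
        tissue = np.zeros((16, 16, 16), dtype=np.uint8)
        tissue[8:, :, :] = 1
        background = np.zeros((16, 16, 16), dtype=np.uint8)
        background[:4] = 1
        with pytest.raises(ValueError, match="undefined CNR"):
            compute_cnr(ImageVolume(data, 20.0), LabelMap(tissue, 20.0),
                        LabelMap(background, 20.0))
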