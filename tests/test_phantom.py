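"""Phantom generator: solids, rasterization, condition transforms, determinism."""

import numpy as np
import pytest

import kneestress as ks
from kneestress.errors import ConfigurationError, FieldOfViewError
from kneestress.phantom import (
    DEFAULT_CONDITION_EFFECTS,
    Cylinder,
    apply_condition_transform,
    bones_to_labeled_solids,
    build_bone_models,
    rasterize,
)
from conftest import exact_effects


class TestRasterize:
    def test_cylinder_slice_area(self):
        cyl = Cylinder(name="c", center=np.array([25.0, 25.0, 5.0]), R=np.eye(3),
                       radius=10.0, half_length=5.0)
        vol = rasterize([(cyl, 1)], (1.0, 1.0, 1.0), (51, 51, 11))
        area = (vol.labels[:, :, 5] == 1).sum()
        assert abs(area - np.pi * 10.0 ** 2) / (np.pi * 10.0 ** 2) < 0.05

    def test_empty_solid_list(self):
        vol = rasterize([], (1.0, 1.0, 1.0), (10, 10, 10))
        assert (vol.labels == 0).all()

    def test_voxel_extent_scales_inversely_with_spacing(self):
        cyl = Cylinder(name="c", center=np.array([18.0, 18.0, 16.5]), R=np.eye(3),
                       radius=7.0, half_length=12.0)
        fine = rasterize([(cyl, 1)], (0.36, 0.36, 3.3), (100, 100, 10))
        coarse = rasterize([(cyl, 1)], (1.0, 1.0, 1.0), (36, 36, 33))
        ext_fine = np.ptp(np.argwhere(fine.labels == 1), axis=0)
        ext_coarse = np.ptp(np.argwhere(coarse.labels == 1), axis=0)
        # mm extents agree to one sampling step per end, so voxel extents
        # scale like 1/spacing
        np.testing.assert_allclose(ext_fine[0] * 0.36, ext_coarse[0] * 1.0, atol=1.5)
        np.testing.assert_allclose(ext_fine[2] * 3.3, ext_coarse[2] * 1.0, atol=4.5)

    def test_field_of_view_error_names_solid(self):
        big = Cylinder(name="huge femoral shaft", center=np.array([5.0, 5.0, 5.0]),
                       R=np.eye(3), radius=50.0, half_length=50.0)
        with pytest.raises(FieldOfViewError, match="huge femoral shaft"):
            rasterize([(big, 1)], (1.0, 1.0, 1.0), (10, 10, 10))


class TestBoneModels:
    def test_femoral_axis_is_shaft_cylinder_axis(self):
        spec = ks.PhantomSpec(n_specimens=1, seed=0)
        bones = build_bone_models(spec, 0)
        shaft = bones.femur_solids[0]
        # the analytic femoral axis is the defining line of the shaft cylinder
        np.testing.assert_allclose(shaft.R[:, 2], bones.femoral_axis_direction, atol=1e-12)
        offset = shaft.center - bones.femoral_axis_point
        cross = np.cross(offset, bones.femoral_axis_direction)
        assert np.linalg.norm(cross) < 1e-9

    def test_tibial_landmark_is_anterior(self):
        spec = ks.PhantomSpec(n_specimens=3, seed=1)
        for i in range(3):
            bones = build_bone_models(spec, i)
            # landmark sits anterior (smaller y) of the axis line at its height
            s = (bones.tibial_landmark - bones.tibial_axis_point) @ bones.tibial_axis_direction
            axis_at = bones.tibial_axis_point + s * bones.tibial_axis_direction
            assert bones.tibial_landmark[1] < axis_at[1]

    def test_specimen_size_jitter_varies_radii(self):
        spec = ks.PhantomSpec(n_specimens=2, seed=5)
        b0, b1 = build_bone_models(spec, 0), build_bone_models(spec, 1)
        assert b0.tibia_solids[0].radius != b1.tibia_solids[0].radius
        for b in (b0, b1):
            assert abs(np.linalg.norm(b.femoral_axis_direction) - 1) < 1e-9
            assert abs(np.linalg.norm(b.tibial_axis_direction) - 1) < 1e-9

    def test_axis_points_inside_their_solids(self):
        spec = ks.PhantomSpec(n_specimens=1, seed=2)
        bones = build_bone_models(spec, 0)
        # points a few mm along each axis from the ABI lie inside the bone union
        for solids, abi, direction in [
                (bones.femur_solids, bones.femoral_abi, bones.femoral_axis_direction),
                (bones.tibia_solids, bones.tibial_abi, bones.tibial_axis_direction)]:
            probe = (abi + 5.0 * direction)[None, :]
            assert any(s.contains(probe)[0] for s in solids)


class TestConditionTransform:
    def test_intact_unloaded_zero_noise_is_identity(self):
        spec = ks.PhantomSpec(n_specimens=1, seed=0, noise_sd_mm=0.0)
        bones = build_bone_models(spec, 0)
        moved, gt = apply_condition_transform(
            bones, "intact", "d0", DEFAULT_CONDITION_EFFECTS,
            np.random.default_rng(0), noise_sd_mm=0.0)
        np.testing.assert_allclose(gt.translation_mm, 0.0)
        assert gt.rotation_deg == 0.0
        np.testing.assert_allclose(moved.tibial_abi, bones.tibial_abi)

    def test_zero_sd_complete_translation_is_exact(self):
        spec = ks.PhantomSpec(n_specimens=1, seed=0, noise_sd_mm=0.0)
        bones = build_bone_models(spec, 0)
        effects = exact_effects()
        moved, gt = apply_condition_transform(
            bones, "complete", "d1", effects, np.random.default_rng(0), noise_sd_mm=0.0)
        np.testing.assert_allclose(gt.translation_mm, [0.0, -12.6, 0.0], atol=1e-12)
        np.testing.assert_allclose(moved.tibial_abi - bones.tibial_abi,
                                   [0.0, -12.6, 0.0], atol=1e-12)
        # femur fixed
        np.testing.assert_allclose(moved.femoral_abi, bones.femoral_abi)

    def test_seeded_draw_matches_generator(self):
        from kneestress.phantom import ConditionEffect
        spec = ks.PhantomSpec(n_specimens=1, seed=0, noise_sd_mm=0.0)
        bones = build_bone_models(spec, 0)
        effects = dict(DEFAULT_CONDITION_EFFECTS)
        effects["partial"] = ConditionEffect(8.1, 2.0, 0.0, 0.0)
        _, gt = apply_condition_transform(
            bones, "partial", "d1", effects, np.random.default_rng(42), noise_sd_mm=0.0)
        expected = np.random.default_rng(42).normal(8.1, 2.0)
        np.testing.assert_allclose(-gt.translation_mm[1], expected)

    def test_unknown_labels_rejected(self):
        spec = ks.PhantomSpec(n_specimens=1, seed=0)
        bones = build_bone_models(spec, 0)
        with pytest.raises(ConfigurationError):
            apply_condition_transform(bones, "ruptured", "d1",
                                      DEFAULT_CONDITION_EFFECTS, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            apply_condition_transform(bones, "intact", "d2",
                                      DEFAULT_CONDITION_EFFECTS, np.random.default_rng(0))

    def test_rotation_pivots_on_tibial_abi(self):
        from kneestress.phantom import ConditionEffect
        spec = ks.PhantomSpec(n_specimens=1, seed=0, noise_sd_mm=0.0)
        bones = build_bone_models(spec, 0)
        effects = {c: ConditionEffect(0.0, 0.0, 10.0, 0.0)
                   for c in ("intact", "partial", "complete")}
        moved, gt = apply_condition_transform(
            bones, "complete", "d1", effects, np.random.default_rng(0), noise_sd_mm=0.0)
        assert gt.rotation_deg == 10.0
        # the ABI lies on the rotation line: it only feels the translation (none)
        np.testing.assert_allclose(moved.tibial_abi, bones.tibial_abi, atol=1e-9)
        # the axis direction is rotated by exactly 10 deg about z
        cos_xy = np.cos(np.deg2rad(10.0))
        a, b = bones.tibial_axis_direction[:2], moved.tibial_axis_direction[:2]
        np.testing.assert_allclose(
            a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), cos_xy, atol=1e-12)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = ks.PhantomSpec(n_specimens=1, seed=11, noise_sd_mm=0.0,
                              condition_effects=exact_effects())
        v1, a1, g1 = ks.synthesize_cell(spec, 0, "partial", "d1")
        v2, a2, g2 = ks.synthesize_cell(spec, 0, "partial", "d1")
        np.testing.assert_array_equal(v1.labels, v2.labels)
        assert a1 == a2
        np.testing.assert_array_equal(g1.translation_mm, g2.translation_mm)

    def test_ground_truth_consistent_with_annotations(self, intact_cell):
        _, ann, gt = intact_cell
        # with zero noise the annotation passes ground truth through verbatim
        np.testing.assert_allclose(ann["tibia"]["landmark"], gt.tibial_landmark)
        np.testing.assert_allclose(ann["femur"]["axis"]["direction"],
                                   gt.femoral_axis_direction)
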