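"""Facility masking from depth and the dual-view fuser."""

import numpy as np

import pigpen as pp
from pigpen.scene_synth import _facility_raster


class TestFacilityMaskFromDepth:
    def test_two_level_depth_recovers_band(self):
        depth = np.full((20, 20), 40, np.uint8)
        depth[5:9, :] = 220
        mask = pp.facility_mask_from_depth(depth)
        assert (mask[5:9, :] == 255).all()
        assert (np.delete(mask, range(5, 9), axis=0) == 0).all()

    def test_uniform_depth_gives_empty_mask(self):
        assert pp.facility_mask_from_depth(np.full((8, 8), 77, np.uint8)).max() == 0

    def test_values_are_binary(self, rng):
        depth = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        assert set(np.unique(pp.facility_mask_from_depth(depth))) <= {0, 255}

    def test_recovers_simulator_raster_exactly(self, noise_free_scene):
        cfg, scene = noise_free_scene
        mask = pp.facility_mask_from_depth(scene.depth_plate)
        assert ((mask > 0) == _facility_raster(cfg)).all()


class TestApplyFacilityMask:
    def test_facility_pixel_becomes_white(self):
        frame = np.zeros((2, 2, 3), np.uint8)
        frame[0, 0] = (12, 34, 56)
        facility = np.zeros((2, 2), np.uint8)
        facility[0, 0] = 255
        out = pp.apply_facility_mask(frame, facility)
        assert tuple(out[0, 0]) == (255, 255, 255)
        assert (out[facility == 0] == frame[facility == 0]).all()

    def test_empty_and_full_masks(self, rng):
        frame = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        assert (pp.apply_facility_mask(frame, np.zeros((8, 8), np.uint8)) == frame).all()
        assert (pp.apply_facility_mask(frame, np.full((8, 8), 255, np.uint8)) == 255).all()


class TestBackgroundModel:
    def test_round_trip_save_load(self, noise_free_scene, tmp_path):
        cfg, scene = noise_free_scene
        model = pp.build_background_model(scene.background_plate, scene.depth_plate, "seen")
        model.save(tmp_path / "m")
        loaded = pp.BackgroundModel.load(tmp_path / "m")
        assert loaded.env_id == "seen"
        assert (loaded.background == model.background).all()
        assert (loaded.depth == model.depth).all()
        assert (loaded.facility_mask == model.facility_mask).all()

    def test_uniform_depth_yields_empty_facility(self):
        bg = np.full((8, 8, 3), 90, np.uint8)
        model = pp.build_background_model(bg, np.full((8, 8), 50, np.uint8), "flat")
        assert model.facility_mask.max() == 0

    def test_explicit_empty_mask_supported(self, noise_free_scene):
        cfg, scene = noise_free_scene
        model = pp.build_background_model(
            scene.background_plate, scene.depth_plate, "open-pen",
            facility_mask=np.zeros(scene.depth_plate.shape, np.uint8),
        )
        pair = pp.fuse_inputs(scene.frame, model)
        assert (pair.input_view == scene.frame).all()

    def test_temporal_median_recovers_plate(self):
        cfg = pp.seen_config(noise_std=0.0)
        frames = [pp.generate_scene(cfg, s).frame for s in range(7)]
        plate = pp.generate_scene(cfg, 0).background_plate
        est = pp.estimate_background(frames)
        assert (est == plate).mean() > 0.97  # animals overlap somewhere


class TestFuseInputs:
    def test_both_views_white_on_facility(self, noise_free_scene):
        cfg, scene = noise_free_scene
        model = pp.build_background_model(scene.background_plate, scene.depth_plate, "seen")
        pair = pp.fuse_inputs(scene.frame, model, use_fig=True)
        fac = model.facility_mask > 0
        assert (pair.input_view[fac] == 255).all()
        assert (pair.suppressed_view[fac] == 255).all()

    def test_background_frame_suppresses_to_facility_only(self, noise_free_scene):
        cfg, scene = noise_free_scene
        model = pp.build_background_model(scene.background_plate, scene.depth_plate, "seen")
        pair = pp.fuse_inputs(scene.background_plate, model, use_fig=True)
        fac = model.facility_mask > 0
        assert (pair.suppressed_view[fac] == 255).all()
        assert (pair.suppressed_view[~fac] == 0).all()

    def test_fig_off_passes_frame_through(self, noise_free_scene):
        cfg, scene = noise_free_scene
        model = pp.build_background_model(scene.background_plate, scene.depth_plate, "seen")
        pair = pp.fuse_inputs(scene.frame, model, use_fig=False)
        assert (pair.input_view == scene.frame).all()

    def test_difference_mode_replicates_gray(self, noise_free_scene):
        cfg, scene = noise_free_scene
        model = pp.build_background_model(scene.background_plate, scene.depth_plate, "seen")
        pair = pp.fuse_inputs(scene.frame, model, use_fig=False, input_mode="difference")
        diff = pp.difference_image(scene.frame, scene.background_plate)
        assert (pair.suppressed_view == diff[:, :, None]).all()

    def test_facility_region_invariant_to_frame_content(self, noise_free_scene, rng):
        cfg, scene = noise_free_scene
        model = pp.build_background_model(scene.background_plate, scene.depth_plate, "seen")
        fac = model.facility_mask > 0
        other = rng.integers(0, 256, scene.frame.shape, dtype=np.uint8)
        p1 = pp.fuse_inputs(scene.frame, model, use_fig=True)
        p2 = pp.fuse_inputs(other, model, use_fig=True)
        assert (p1.input_view[fac] == p2.input_view[fac]).all()
        assert (p1.suppressed_view[fac] == p2.suppressed_view[fac]).all()

    def test_idempotent_on_facility_region(self, noise_free_scene):
        cfg, scene = noise_free_scene
        model = pp.build_background_model(scene.background_plate, scene.depth_plate, "seen")
        once = pp.apply_facility_mask(scene.frame, model.facility_mask)
        twice = pp.apply_facility_mask(once, model.facility_mask)
        assert (once == twice).all()
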