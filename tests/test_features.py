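import warnings

import numpy as np
import pytest

from conftest import gt_footprint_region, run_reference_pipeline
from lamescan import synthetic
from lamescan.depth_io import FRAME_COLS, FRAME_ROWS
from lamescan.features import (
    BackboneProfile,
    GaussianSpec,
    HeightField,
    backbone_profile,
    featurize_track,
    feature_table,
    gaussian_smooth,
    height_transform,
    select_full_width_frames,
)
from lamescan.tracking import Track


class TestSelectFullWidth:
    def _track(self, boxes):
        from test_tracking import box_region

        track = Track(track_id=1)
        for f, box in enumerate(boxes):
            track.append(f, box_region(box, frame_index=f))
        return track

    def test_keeps_only_full_width_boxes_in_order(self):
        track = self._track(
            [(0, 20, 176, 110), (3, 20, 176, 110), (0, 25, 176, 115)]
        )
        kept = select_full_width_frames(track)
        assert [f for f, _ in kept] == [0, 2]

    def test_all_partial_track_gives_empty_selection(self):
        track = self._track([(3, 20, 176, 110), (0, 20, 170, 110)])
        assert select_full_width_frames(track) == []


class TestHeightTransform:
    def test_arithmetic(self):
        grid = np.full((FRAME_ROWS, FRAME_COLS), 1.6)
        field = height_transform(grid, distance=2.8)
        np.testing.assert_allclose(field.values, 1.2)

    def test_depth_at_reference_gives_zero_height(self):
        grid = np.full((FRAME_ROWS, FRAME_COLS), 2.8)
        mask = np.ones_like(grid, dtype=bool)
        field = height_transform(grid, distance=2.8, mask=mask)
        np.testing.assert_array_equal(field.values, 0.0)

    def test_below_floor_clamps_to_zero(self):
        grid = np.full((FRAME_ROWS, FRAME_COLS), 3.1)
        mask = np.ones_like(grid, dtype=bool)
        field = height_transform(grid, distance=2.8, mask=mask)
        assert field.values.min() == 0.0

    def test_outside_mask_is_zero_regardless_of_depth(self):
        grid = np.full((FRAME_ROWS, FRAME_COLS), 1.0)
        mask = np.zeros_like(grid, dtype=bool)
        mask[10:20, 10:20] = True
        field = height_transform(grid, distance=2.8, mask=mask)
        assert field.values[~mask].sum() == 0.0
        np.testing.assert_allclose(field.values[mask], 1.8)

    def test_matches_rendered_surface_on_synthetic_cow(self, noise_free_scene):
        config, frames, truth = noise_free_scene
        frame, obj = frames[10], truth[10].objects[0]
        region = gt_footprint_region(frame, obj)
        field = height_transform(
            frame.values * region.mask,
            distance=config.camera_height_m,
            mask=region.mask,
        )
        expected = config.camera_height_m - frame.values
        np.testing.assert_allclose(
            field.values[region.mask], expected[region.mask], atol=1e-6
        )


class TestGaussianSmooth:
    def test_constant_field_unchanged(self):
        field = HeightField(values=np.full((FRAME_ROWS, FRAME_COLS), 1.3))
        out = gaussian_smooth(field, GaussianSpec(sigma=2.0))
        np.testing.assert_allclose(out.values, 1.3, atol=1e-12)

    def test_impulse_response_is_the_normalised_kernel(self):
        spec = GaussianSpec(sigma=1.0)
        field_values = np.zeros((FRAME_ROWS, FRAME_COLS))
        field_values[60, 80] = 1.0
        out = gaussian_smooth(HeightField(values=field_values), spec)
        kernel = spec.kernel()
        r = spec.effective_radius
        np.testing.assert_allclose(
            out.values[60 - r : 60 + r + 1, 80 - r : 80 + r + 1], kernel, atol=1e-9
        )
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_kernel_is_normalised_for_any_sigma(self):
        for sigma in (0.3, 1.0, 2.5):
            assert GaussianSpec(sigma=sigma).kernel().sum() == pytest.approx(1.0)

    def test_smoothing_never_raises_the_maximum(self):
        rng = np.random.default_rng(1)
        field = HeightField(values=rng.uniform(0, 2, (FRAME_ROWS, FRAME_COLS)))
        out = gaussian_smooth(field, GaussianSpec(sigma=1.5))
        assert out.values.max() <= field.values.max() + 1e-12


class TestBackboneProfile:
    def test_single_pixel(self):
        values = np.zeros((FRAME_ROWS, FRAME_COLS))
        values[40, 100] = 1.27
        profile = backbone_profile(HeightField(values=values))
        assert profile.heights[100] == 1.27
        assert profile.heights.sum() == pytest.approx(1.27)

    def test_toy_grid_column_maxima(self):
        values = np.array([[1, 0, 2, 0], [0, 3, 0, 0], [1, 1, 1, 4]], dtype=float)
        profile = backbone_profile(HeightField(values=values))
        np.testing.assert_array_equal(profile.heights, [1, 3, 2, 4])

    def test_brute_force_equivalence_on_random_grids(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = rng.uniform(0, 2, (FRAME_ROWS, FRAME_COLS))
            profile = backbone_profile(HeightField(values=values))
            brute = [max(values[i, j] for i in range(FRAME_ROWS))
                     for j in range(FRAME_COLS)]
            np.testing.assert_allclose(profile.heights, brute)

    def test_unsmoothed_profile_equals_dorsal_curve(self, noise_free_scene):
        config, frames, truth = noise_free_scene
        tpl = config.cows[0].template
        dorsal = synthetic.dorsal_profile(tpl)
        for frame, rec in zip(frames, truth):
            obj = rec.objects[0] if rec.objects else None
            if obj is None or obj.box[0] != 0 or obj.box[2] != FRAME_COLS:
                continue
            region = gt_footprint_region(frame, obj)
            field = height_transform(
                frame.values * region.mask,
                distance=config.camera_height_m,
                mask=region.mask,
            )
            profile = backbone_profile(field)
            window = dorsal[-obj.body_offset : -obj.body_offset + FRAME_COLS]
            np.testing.assert_allclose(profile.heights, window, atol=1e-6)


class TestFeaturizeTrack:
    def _profiles(self, template, seed=21):
        config = synthetic.SceneConfig(
            n_frames=24,
            cows=[synthetic.CowPlacement(template, 0, 66)],
            noise_sd_m=0.0,
            seed=seed,
        )
        frames, _ = synthetic.render_scene(config)
        frame_map = {f.index: f for f in frames}
        (track,), _ = run_reference_pipeline(frames)
        return featurize_track(
            track, frame_map, distance=config.camera_height_m
        )

    def test_sound_cow_profiles_top_the_boundary(self, sound_template):
        profiles = self._profiles(sound_template)
        assert profiles
        for p in profiles:
            assert len(p.heights) == FRAME_COLS
            assert p.max_height > synthetic.LAME_CUTOFF_M

    def test_lame_cow_profiles_stay_below_the_boundary(self, lame_template):
        profiles = self._profiles(lame_template)
        assert profiles
        for p in profiles:
            assert p.max_height < synthetic.LAME_CUTOFF_M

    def test_deterministic(self, sound_template):
        a = self._profiles(sound_template)
        b = self._profiles(sound_template)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.heights, pb.heights)

    def test_empty_selection_warns_and_returns_empty(self):
        from test_tracking import box_region

        track = Track(track_id=9)
        track.append(0, box_region((3, 20, 170, 110)))
        frames = {0: box_region((3, 20, 170, 110)).mask}  # unused
        from lamescan.depth_io import DepthFrame

        frame_map = {
            0: DepthFrame(index=0, values=np.full((FRAME_ROWS, FRAME_COLS), 3.0))
        }
        with pytest.warns(UserWarning, match="no full-width"):
            assert featurize_track(track, frame_map) == []

    def test_scaling_heights_scales_profiles(self):
        rng = np.random.default_rng(5)
        values = np.zeros((FRAME_ROWS, FRAME_COLS))
        values[30:90, :] = rng.uniform(0.5, 1.5, (60, FRAME_COLS))
        spec = GaussianSpec(sigma=1.0)
        base = backbone_profile(gaussian_smooth(HeightField(values=values), spec))
        scaled = backbone_profile(
            gaussian_smooth(HeightField(values=2.5 * values), spec)
        )
        np.testing.assert_allclose(scaled.heights, 2.5 * base.heights, rtol=1e-10)


def test_feature_table_layout():
    profiles = [
        BackboneProfile(heights=np.linspace(0, 1, FRAME_COLS), track_id=1,
                        frame_index=4),
        BackboneProfile(heights=np.linspace(1, 0, FRAME_COLS), track_id=2,
                        frame_index=5),
    ]
    table = feature_table(profiles, labels={1: "sound"})
    assert list(table.columns[:2]) == ["track_id", "frame_index"]
    assert table.shape == (2, 2 + FRAME_COLS + 1)
    assert table.loc[0, "label"] == "sound"
    assert table.loc[0, "h_175"] == 1.0
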