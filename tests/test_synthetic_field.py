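import numpy as np
import pytest

from roboyield import optics, plotframes as pf
from roboyield import synthetic_field as sf
from roboyield.synthetic_field import FieldSpec, PlacementError, SceneSpec

SMALL_INTR = optics.CameraIntrinsics(
    fx=60, fy=60, cx=60, cy=40, k=(-0.05, 0.01, 0, 0), native_size=(128, 80)
)


class TestSceneRendering:
    def test_no_seeds_no_points(self):
        spec = SceneSpec(n_foreground_seeds=0, image_size=(64, 64))
        _, pts = sf.render_plot_image(spec, 0)
        assert len(pts) == 0

    def test_unoccluded_seeds_all_annotated(self):
        spec = SceneSpec(n_foreground_seeds=50, occlusion_fraction=0.0,
                         image_size=(128, 128), seed_radius_px=(2, 4))
        _, pts = sf.render_plot_image(spec, 3)
        assert len(pts) == 50

    def test_annotations_match_pixel_visibility_oracle(self):
        """The annotation set equals an independent pixel count of each
        seed's unoccluded, still-on-top area against the 50% rule."""
        spec = SceneSpec(n_foreground_seeds=50, occlusion_fraction=0.3,
                         image_size=(128, 128), seed_radius_px=(2, 4))
        r = sf.render_scene(spec, 11)
        h, w = r.top_label.shape
        occ = r.occluder_mask.ravel()
        top = r.top_label.ravel()
        expected = []
        for i, pix in enumerate(r.seed_pixels):
            visible = int(((top[pix] == i + 1) & ~occ[pix]).sum())
            expected.append(visible >= 0.5 * len(pix))
        assert np.array_equal(r.annotated, expected)
        assert 0 < len(r.points) < 50
        assert np.array_equal(r.points.xy, r.fg_centers[r.annotated])

    def test_annotated_points_lie_on_their_blob(self):
        spec = SceneSpec(n_foreground_seeds=30, image_size=(96, 96),
                         seed_radius_px=(2, 4))
        r = sf.render_scene(spec, 5)
        h, w = r.top_label.shape
        for i in np.flatnonzero(r.annotated):
            x, y = r.fg_centers[i]
            flat = np.ravel_multi_index((int(round(y)), int(round(x))), (h, w))
            assert flat in set(r.seed_pixels[i].tolist())

    def test_points_inside_image_bounds(self):
        spec = SceneSpec(n_foreground_seeds=40, image_size=(64, 64),
                         seed_radius_px=(2, 3.5))
        _, pts = sf.render_plot_image(spec, 9)
        assert (pts.xy >= 0).all()
        assert (pts.xy[:, 0] < 64).all() and (pts.xy[:, 1] < 64).all()

    def test_render_deterministic(self):
        spec = SceneSpec(n_foreground_seeds=20, occlusion_fraction=0.2,
                         image_size=(64, 64), seed_radius_px=(2, 3.5))
        img1, pts1 = sf.render_plot_image(spec, 42)
        img2, pts2 = sf.render_plot_image(spec, 42)
        assert img1.tobytes() == img2.tobytes()
        assert np.array_equal(pts1.xy, pts2.xy)

    def test_overfull_scene_raises_placement_error(self):
        spec = SceneSpec(n_foreground_seeds=200, image_size=(32, 32),
                         seed_radius_px=(2, 4))
        with pytest.raises(PlacementError, match="image_size"):
            sf.render_scene(spec, 0)

    @pytest.mark.parametrize("kwargs", [
        {"n_foreground_seeds": -1},
        {"occlusion_fraction": 1.5},
        {"seed_radius_px": (3.0, 2.0)},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneSpec(**kwargs)


class TestFieldSimulation:
    def test_flat_field_equals_genotype_effects(self):
        spec = FieldSpec(n_ranges=4, n_passes=4, noise_sd=0.0,
                         genotype_effects=np.array([2.0, 3.0]), rng_seed=0)
        layout = sf.simulate_field(spec)
        assert np.allclose(layout.df["true_yield"], layout.df["genotype_effect"])

    def test_pure_trend_reproduced_exactly(self):
        spec = FieldSpec(n_ranges=5, n_passes=3, noise_sd=0.0,
                         genotype_effects=np.array([0.0]),
                         spatial_trend=lambda r, p: 0.1 * r + 0.2 * p,
                         rng_seed=1)
        layout = sf.simulate_field(spec)
        expected = 0.1 * layout.df["range"] + 0.2 * layout.df["pass"]
        assert np.allclose(layout.df["true_yield"], expected)

    def test_nonpositive_yields_clipped_with_warning(self):
        spec = FieldSpec(n_ranges=3, n_passes=3, noise_sd=0.0,
                         genotype_effects=np.array([-1.0]), rng_seed=1)
        with pytest.warns(UserWarning, match="clipped"):
            layout = sf.simulate_field(spec)
        assert (layout.df["true_yield"] == spec.clip_min).all()

    def test_matches_straight_line_recomputation(self):
        """Per-plot values agree with an independent direct evaluation of
        effect + trend + noise drawn from the same seed stream."""
        effects = np.linspace(1.5, 3.5, 10)
        spec = FieldSpec(n_ranges=10, n_passes=10, noise_sd=0.1,
                         genotype_effects=effects,
                         spatial_trend=lambda r, p: 0.05 * r, rng_seed=21)
        layout = sf.simulate_field(spec)
        rng = np.random.default_rng(21)
        entries = np.tile(np.arange(10), 11)[:100]
        rng.shuffle(entries)
        noise = rng.normal(0, 0.1, 100)
        expected = effects[entries] + 0.05 * layout.df["range"].to_numpy() + noise
        assert np.allclose(layout.df["true_yield"], expected)
        assert np.array_equal(layout.df["entry"], entries)

    def test_seed_count_conservation(self):
        spec = FieldSpec(n_ranges=6, n_passes=6, rng_seed=2,
                         spatial_trend=sf.linear_gaussian_trend())
        layout = sf.simulate_field(spec)
        total = layout.df["true_seed_count"].sum()
        recomputed = np.round(
            layout.df["true_yield"].to_numpy() * spec.seeds_per_MT
        ).sum()
        assert total == recomputed
        assert (layout.df["true_yield"] > 0).all()

    def test_layout_deterministic(self):
        spec = FieldSpec(n_ranges=5, n_passes=5, rng_seed=3)
        a = sf.simulate_field(spec).df
        b = sf.simulate_field(spec).df
        assert a.equals(b)


class TestCollectionSimulation:
    def test_single_plot_yields_four_sequences(self):
        layout = sf.simulate_field(FieldSpec(n_ranges=1, n_passes=1,
                                             seeds_per_MT=10.0, rng_seed=0))
        sim = sf.simulate_collection(layout, SMALL_INTR, frames_per_plot=10,
                                     render_frames=False)
        assert len(sim.frames) == 40
        keys = {(f.row, f.side) for f in sim.frames}
        assert keys == {(1, "A"), (1, "B"), (2, "A"), (2, "B")}
        for key in keys:
            assert sum(1 for f in sim.frames if (f.row, f.side) == key) == 10

    def test_intervals_nonoverlapping_and_contain_frames(self):
        layout = sf.simulate_field(FieldSpec(n_ranges=2, n_passes=1,
                                             seeds_per_MT=10.0, rng_seed=0))
        sim = sf.simulate_collection(layout, SMALL_INTR, render_frames=False)
        iv = sim.intervals.sort_values("start_s")
        assert len(iv) == 2
        assert (iv["start_s"].to_numpy()[1:] >= iv["stop_s"].to_numpy()[:-1]).all()
        for f in sim.frames:
            row = iv[(iv["range"] == f.plot_id[0]) & (iv["pass"] == f.plot_id[1])]
            assert row["start_s"].iloc[0] <= f.timestamp < row["stop_s"].iloc[0]

    def test_timestamps_strictly_increase_within_each_collection(self):
        layout = sf.simulate_field(FieldSpec(n_ranges=3, n_passes=2,
                                             seeds_per_MT=10.0, rng_seed=1))
        sim = sf.simulate_collection(layout, SMALL_INTR, render_frames=False)
        for key in {(f.row, f.side) for f in sim.frames}:
            ts = [f.timestamp for f in sim.frames if (f.row, f.side) == key]
            assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_assignment_round_trip_recovers_all_labels(self):
        layout = sf.simulate_field(FieldSpec(n_ranges=3, n_passes=2,
                                             seeds_per_MT=10.0, rng_seed=1))
        sim = sf.simulate_collection(layout, SMALL_INTR, render_frames=False)
        assigned = pf.assign_frames_to_plots(
            [f.timestamp for f in sim.frames], sim.intervals
        )
        assert all(a == f.plot_id for a, f in zip(assigned, sim.frames))

    def test_rendered_frames_carry_distorted_truth_points(self):
        layout = sf.simulate_field(FieldSpec(n_ranges=1, n_passes=1,
                                             seeds_per_MT=30.0, rng_seed=2))
        sim = sf.simulate_collection(
            layout, SMALL_INTR, frames_per_plot=8,
            scene_template=SceneSpec(n_background_seeds=2, seed_radius_px=(2, 3)),
            rng_seed=4,
        )
        frame = next(f for f in sim.frames if len(f.true_points))
        h, w = frame.image.shape[:2]
        assert (w, h) == SMALL_INTR.native_size
        assert frame.image.min() >= 0 and frame.image.max() <= 1
        # truth points are in distorted coordinates: undistorting them should
        # land inside the frame too
        back = optics.undistort_points(frame.true_points.xy, SMALL_INTR)
        assert np.isfinite(back).all()

    def test_too_few_frames_rejected(self):
        layout = sf.simulate_field(FieldSpec(n_ranges=1, n_passes=1, rng_seed=0))
        with pytest.raises(ValueError, match="frames_per_plot"):
            sf.simulate_collection(layout, SMALL_INTR, frames_per_plot=4)
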