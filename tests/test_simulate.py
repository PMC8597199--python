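"""Simulator: spore placement, growth kinematics, rendering, tiling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mycometry as m
from mycometry.simulate import rasterize_mask, tile_layout


class TestSimConfig:
    def test_defaults_valid(self):
        cfg = m.SimConfig()
        assert cfg.n_spores == 687
        assert cfg.frame_times_h == (0.0, 23.0, 26.0, 29.0, 46.5, 49.5, 52.0)

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_spores": 0},
            {"frame_times_h": (1.0, 2.0)},
            {"frame_times_h": (0.0, 5.0, 5.0)},
            {"overlap_frac": 0.5},
            {"px_size_um": 0.0},
            {"tip_speed_um_h": -1.0},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            m.SimConfig(**kw)

    def test_scaled_config_preserves_density(self):
        base, small = m.SimConfig(), m.scaled_study_config(0.2)
        dens = lambda c: c.n_spores / c.droplet_radius_um**2
        assert dens(small) == pytest.approx(dens(base), rel=0.1)


class TestInitSporeField:
    def test_study_scale_spore_count_and_placement(self):
        cfg = m.SimConfig(n_spores=687, seed=1)
        state = m.init_spore_field(cfg)
        assert len(state.centers_um) == 687
        cx, cy = cfg.field_center_um
        d = np.hypot(state.centers_um[:, 0] - cx, state.centers_um[:, 1] - cy)
        assert np.all(d <= cfg.droplet_radius_um)

    def test_single_spore_inside_droplet(self):
        cfg = m.SimConfig(n_spores=1, droplet_radius_um=100.0,
                          field_size_px=256, seed=3)
        state = m.init_spore_field(cfg)
        cx, cy = cfg.field_center_um
        assert math.hypot(*(state.centers_um[0] - (cx, cy))) <= 100.0

    def test_deterministic_for_seed(self):
        cfg = m.SimConfig(n_spores=50, seed=42)
        a, b = m.init_spore_field(cfg), m.init_spore_field(cfg)
        np.testing.assert_array_equal(a.centers_um, b.centers_um)
        np.testing.assert_array_equal(a.lag_h, b.lag_h)

    def test_area_sampler_mean_within_3se(self):
        cfg = m.SimConfig(n_spores=500, spore_area_mean_um2=560.0,
                          spore_area_cv=0.1, seed=0)
        state = m.init_spore_field(cfg)
        areas = math.pi * state.radii_um**2
        se = areas.std(ddof=1) / math.sqrt(len(areas))
        assert abs(areas.mean() - 560.0) < 3 * se

    def test_sampler_moments_at_large_n(self):
        # spore areas and lag times both match their configured
        # distributions within Monte-Carlo error at n = 10^4
        cfg = m.SimConfig(
            n_spores=10_000, droplet_radius_um=60_000.0, field_size_px=256,
            spore_area_cv=0.25, seed=9,
        )
        state = m.init_spore_field(cfg)
        areas = math.pi * state.radii_um**2
        assert areas.mean() == pytest.approx(560.0, rel=0.02)
        assert areas.std() == pytest.approx(0.25 * 560.0, rel=0.05)
        assert state.lag_h.mean() == pytest.approx(cfg.lag_mean_h, rel=0.02)
        assert state.lag_h.std() == pytest.approx(cfg.lag_sd_h, rel=0.06)

    def test_overcrowded_droplet_raises_naming_constraint(self):
        cfg = m.SimConfig(n_spores=500, droplet_radius_um=100.0,
                          field_size_px=256, seed=0)
        with pytest.raises(ValueError, match="droplet too small"):
            m.init_spore_field(cfg)


class TestAdvanceColony:
    def test_no_growth_before_any_lag(self):
        cfg = m.SimConfig(n_spores=20, droplet_radius_um=600.0,
                          field_size_px=1024, seed=2)
        state = m.init_spore_field(cfg)
        m.advance_colony(state, 0.9 * state.lag_h.min(), cfg)
        assert state.n_segments == 0
        assert not state.germinated.any()

    def test_negative_step_rejected(self):
        cfg = m.SimConfig(n_spores=5, droplet_radius_um=400.0,
                          field_size_px=512, seed=2)
        state = m.init_spore_field(cfg)
        m.advance_colony(state, 5.0, cfg)
        with pytest.raises(ValueError, match="backward"):
            m.advance_colony(state, 4.0, cfg)

    def test_single_tip_kinematics_without_branching(self):
        # displacement along the germ tube equals speed * elapsed time,
        # within the envelope allowed by angular diffusion
        cfg = m.SimConfig(
            n_spores=1, droplet_radius_um=50.0, field_size_px=2048,
            lag_mean_h=2.0, lag_sd_h=0.01, tip_speed_um_h=12.0,
            branch_rate_per_tip_h=0.0, tip_angle_sd_rad=0.05, seed=8,
        )
        state = m.init_spore_field(cfg)
        lag = float(state.lag_h[0])
        dt = 6.0
        m.advance_colony(state, lag + dt, cfg)
        assert state.n_active_tips == 1
        path = sum(
            math.hypot(x1 - x0, y1 - y0) for x0, y0, x1, y1 in state.seg_coords
        )
        # path length equals speed * growth time (germination snaps to the
        # sub-step grid); displacement is shortened only by the small
        # heading diffusion
        assert path == pytest.approx(cfg.tip_speed_um_h * dt, rel=0.1)
        start = np.asarray(state.seg_coords[0][:2])
        end = np.asarray(state.seg_coords[-1][2:])
        assert math.hypot(*(end - start)) > 0.85 * path

    def test_split_schedule_identical(self):
        cfg = m.SimConfig(n_spores=12, droplet_radius_um=500.0,
                          field_size_px=1024, noise_sd=0.0,
                          illum_gradient_amp=0.0, seed=2)
        one = m.init_spore_field(cfg)
        m.advance_colony(one, 29.0, cfg)
        several = m.init_spore_field(cfg)
        for t in (11.0, 23.0, 26.5, 29.0):
            m.advance_colony(several, t, cfg)
        np.testing.assert_allclose(
            np.asarray(one.seg_coords), np.asarray(several.seg_coords)
        )

    def test_segments_trace_back_to_germinated_spores(self, noisy_series):
        # regenerate the final state cheaply to inspect lineage
        cfg = m.scaled_study_config(0.1, seed=21, frame_times_h=(0.0, 29.0))
        state = m.init_spore_field(cfg)
        m.advance_colony(state, 29.0, cfg)
        founders = np.unique(state.seg_spore)
        assert state.germinated[founders].all()

    def test_full_coalescence_between_29_and_465(self, noisy_series):
        # by the first post-countable frame the simulated mycelium has
        # merged into a single object, while distinct objects remain at 29 h
        _, truth = noisy_series
        by_time = {f.time_h: f for f in truth.frames}
        assert by_time[29.0].n_objects > 1
        assert by_time[46.5].n_objects == 1


class TestRasterize:
    def test_empty_state_renders_background(self):
        cfg = m.SimConfig(n_spores=1, droplet_radius_um=50.0,
                          field_size_px=128, noise_sd=0.0,
                          illum_gradient_amp=0.0, seed=1)
        state = m.init_spore_field(cfg)
        state.centers_um = np.empty((0, 2))
        state.radii_um = np.empty(0)
        img, mask = m.rasterize_frame(state, cfg)
        assert not mask.any()
        assert np.all(img == cfg.background_level)

    def test_clean_frame_is_two_level_with_mask_support(self, clean_series):
        tilesets, truth = clean_series
        cfg_px = tilesets[0].px_size_um
        img = m.stitch_tiles(tilesets[0], blend="none").image
        mask = truth.frames[0].mask
        levels = np.unique(img)
        assert len(levels) == 2
        np.testing.assert_array_equal(img == levels[1], mask)
        assert cfg_px == 1.3

    def test_disc_pixel_area_conversion(self):
        # a rasterised disc's area in um^2 is its pixel count times 1.69;
        # a ~560 um^2 spore covers ~331 px at 1.3 um/px
        cfg = m.SimConfig(n_spores=1, droplet_radius_um=30.0,
                          field_size_px=96, noise_sd=0.0,
                          illum_gradient_amp=0.0, seed=1,
                          spore_area_mean_um2=560.0, spore_area_cv=0.0)
        state = m.init_spore_field(cfg)
        mask = rasterize_mask(state, cfg)
        n_px = int(mask.sum())
        assert n_px * 1.3**2 == pytest.approx(560.0, rel=0.05)
        assert 331 * 1.3**2 == pytest.approx(559.39, abs=0.01)


class TestTiles:
    def test_study_layout_25_tiles_step_ratio(self):
        tw, offsets = tile_layout(12288, 5, 0.10)
        assert len(offsets) == 5
        step = offsets[1] - offsets[0]
        assert step == pytest.approx(0.9 * tw, abs=1.0)
        assert offsets[-1] + tw >= 12288

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        size=st.integers(64, 4096),
        n=st.integers(1, 8),
        overlap=st.floats(0.0, 0.45),
    )
    def test_layout_always_covers_frame(self, size, n, overlap):
        tw, offsets = tile_layout(size, n, overlap)
        assert offsets[0] == 0
        assert offsets[-1] + tw >= size
        assert tw <= size

    def test_single_tile_equals_frame(self, rng):
        frame = rng.integers(0, 255, (96, 96)).astype(np.uint8)
        cfg = m.SimConfig(n_spores=1, droplet_radius_um=10.0,
                          field_size_px=96, tile_grid=(1, 1), seed=0)
        ts = m.render_tiles(frame, cfg)
        assert len(ts.tiles) == 1
        np.testing.assert_array_equal(ts.tiles[0], frame)

    def test_reassembly_from_nominal_offsets_is_exact(self, rng):
        frame = rng.integers(0, 255, (300, 300)).astype(np.uint8)
        cfg = m.SimConfig(n_spores=1, droplet_radius_um=10.0,
                          field_size_px=300, tile_grid=(3, 3),
                          overlap_frac=0.1, seed=0)
        ts = m.render_tiles(frame, cfg)
        out = np.zeros_like(frame)
        for tile, (oy, ox) in zip(ts.tiles, ts.nominal_offsets):
            out[oy : oy + tile.shape[0], ox : ox + tile.shape[1]] = tile
        np.testing.assert_array_equal(out, frame)


class TestGenerateSeries:
    def test_default_schedule_has_seven_frames(self, noisy_series):
        tilesets, truth = noisy_series
        assert len(tilesets) == 7 and len(truth.frames) == 7
        assert [t.time_h for t in tilesets] == [0, 23, 26, 29, 46.5, 49.5, 52]

    def test_time_zero_only_spores(self):
        cfg = m.scaled_study_config(0.1, seed=4, frame_times_h=(0.0,))
        tilesets, truth = m.generate_series(cfg)
        assert len(tilesets) == 1
        assert truth.frames[0].n_objects == cfg.n_spores
        assert truth.frames[0].germinated_count == 0

    def test_seed_changes_layout_not_count(self):
        mk = lambda s: m.scaled_study_config(0.1, seed=s, frame_times_h=(0.0,))
        (_, t1), (_, t2) = m.generate_series(mk(1)), m.generate_series(mk(2))
        assert len(t1.centers_um) == len(t2.centers_um)
        assert not np.array_equal(t1.centers_um, t2.centers_um)

    def test_fixed_seed_bit_identical(self):
        cfg = m.scaled_study_config(0.08, seed=6, frame_times_h=(0.0, 23.0))
        ts1, tr1 = m.generate_series(cfg)
        ts2, tr2 = m.generate_series(cfg)
        for a, b in zip(ts1[1].tiles, ts2[1].tiles):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(tr1.frames[1].mask, tr2.frames[1].mask)

    def test_object_count_nonincreasing_area_nondecreasing(self, noisy_series):
        _, truth = noisy_series
        counts = [f.n_objects for f in truth.frames]
        areas = [f.occupied_px for f in truth.frames]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_single_spore_radius_tracks_front_speed(self):
        # with no branching, colony radius grows at the tip speed within
        # one hypha width
        cfg = m.SimConfig(
            n_spores=1, droplet_radius_um=30.0, field_size_px=512,
            lag_mean_h=1.0, lag_sd_h=0.01, tip_speed_um_h=15.0,
            branch_rate_per_tip_h=0.0, tip_angle_sd_rad=0.0, seed=3,
        )
        state = m.init_spore_field(cfg)
        lag = float(state.lag_h[0])
        t = lag + 10.0
        t = math.ceil(t / cfg.dt_h) * cfg.dt_h  # land on the step grid
        m.advance_colony(state, t, cfg)
        end = np.asarray(state.seg_coords[-1][2:])
        center = state.centers_um[0]
        radius = math.hypot(*(end - center)) - float(state.radii_um[0])
        assert abs(radius - cfg.tip_speed_um_h * (t - lag)) <= (
            cfg.hypha_width_um + cfg.tip_speed_um_h * cfg.dt_h
        )
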