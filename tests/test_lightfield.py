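"""Stimulus generator: spot profile, spot walk, noise, composition, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schoolsense.lightfield import (
    FieldConfig,
    FieldFrame,
    NoiseProcess,
    compose_frame,
    export_field,
    field_gradient,
    generate_field,
    load_field,
    noise_field,
    sample_light,
    spot_field,
    step_spot,
)

from fieldtools import base_config, ramp_sequence, uniform_sequence


class TestSpotField:
    def test_profile_matches_gaussian_decay(self):
        cfg = base_config(nx=128, ny=72)
        center = np.array([91.5, 51.0])
        grid = spot_field(center, cfg)
        xs, ys = cfg.pixel_centers()
        # fully dark at the centre, approaching white far away
        j, i = np.argmin(np.abs(ys - center[1])), np.argmin(np.abs(xs - center[0]))
        r_center = np.hypot(xs[i] - center[0], ys[j] - center[1])
        assert grid[j, i] == pytest.approx(1 - np.exp(-r_center**2 / (2 * 38.1**2)), abs=1e-12)
        corner_r2 = (xs[0] - center[0]) ** 2 + (ys[0] - center[1]) ** 2
        assert grid[0, 0] == pytest.approx(1 - np.exp(-corner_r2 / (2 * 38.1**2)))
        # one length scale out: 1 - e^{-1/2}
        i_l = np.argmin(np.abs(xs - (center[0] + 38.1)))
        r = np.hypot(xs[i_l] - center[0], ys[j] - center[1])
        assert grid[j, i_l] == pytest.approx(1 - np.exp(-r**2 / (2 * 38.1**2)), abs=1e-12)
        assert abs(1 - np.exp(-0.5) - 0.3935) < 1e-4  # the r = l landmark value

    def test_center_outside_arena_rejected(self):
        cfg = base_config()
        with pytest.raises(ValueError):
            spot_field(np.array([-1.0, 50.0]), cfg)


class TestSpotWalk:
    def test_step_length_is_speed_over_frame_rate(self):
        cfg = base_config(spot_turn_sd_rad=0.0, frame_rate=30.0, n_frames=31)
        rng = np.random.default_rng(0)
        c0, h0 = np.array([91.5, 51.0]), np.array([1.0, 0.0])
        c1, h1 = step_spot(c0, h0, cfg, rng)
        assert np.linalg.norm(c1 - c0) == pytest.approx(5.7 / 30.0, abs=1e-12)
        assert np.allclose(h1, h0)  # zero turn noise: straight line

    def test_reflection_keeps_spot_inside_and_mirrors_heading(self):
        cfg = base_config(spot_turn_sd_rad=0.0)
        rng = np.random.default_rng(0)
        c0 = np.array([0.05, 51.0])  # closer to the wall than one step
        c1, h1 = step_spot(c0, np.array([-1.0, 0.0]), cfg, rng)
        assert 0 <= c1[0] <= cfg.arena_width_cm
        assert h1[0] > 0  # normal component negated

    def test_track_speed_conserved_except_reflections(self, small_field):
        cfg = small_field.config
        step = cfg.spot_speed_cm_s / cfg.frame_rate_hz
        d = np.linalg.norm(np.diff(small_field.spot_track, axis=0), axis=1)
        assert (d <= step + 1e-9).all()
        assert np.mean(np.isclose(d, step, atol=1e-9)) > 0.9


class TestNoise:
    def test_same_seed_same_frame(self):
        cfg = base_config(nx=48, ny=32, noise_corr_px=2.0)
        a = noise_field(3, cfg, np.random.default_rng(7))
        b = noise_field(3, cfg, np.random.default_rng(7))
        assert np.array_equal(a, b)
        c = noise_field(4, cfg, np.random.default_rng(7))
        assert not np.array_equal(a, c)

    def test_bounded_zero_mean_and_correlated(self):
        cfg = base_config(nx=96, ny=64, noise_corr_px=3.0, noise_persistence=0.9)
        proc = NoiseProcess(cfg, np.random.default_rng(5))
        n0 = proc.current
        assert (np.abs(n0) <= 0.5).all()
        assert abs(n0.mean()) < 0.05
        # spatial smoothness: strong correlation between adjacent pixels
        r_spatial = np.corrcoef(n0[:, :-1].ravel(), n0[:, 1:].ravel())[0, 1]
        assert r_spatial > 0.5
        proc.advance()
        r_temporal = np.corrcoef(n0.ravel(), proc.current.ravel())[0, 1]
        assert r_temporal > 0.5


class TestCompose:
    def test_eta_zero_gives_spot_plus_border(self):
        cfg = base_config(border=4, noise_level=0.0)
        spot = spot_field(np.array([91.5, 51.0]), cfg)
        frame = compose_frame(spot, np.full(spot.shape, 0.37), cfg)
        interior = frame.values[4:-4, 4:-4]
        assert np.array_equal(interior, spot[4:-4, 4:-4])
        assert (frame.values[:4, :] == 1.0).all()
        assert (frame.values[:, -4:] == 1.0).all()

    def test_weighted_sum_value(self):
        cfg = base_config(noise_level=0.25)
        frame = compose_frame(
            np.full((cfg.grid_ny, cfg.grid_nx), 0.6),
            np.full((cfg.grid_ny, cfg.grid_nx), -0.4),
            cfg,
        )
        assert frame.values[10, 10] == pytest.approx(0.6 + 0.25 * (-0.4), abs=1e-12)

    def test_clipping_and_shape_mismatch(self):
        cfg = base_config(noise_level=0.25)
        shape = (cfg.grid_ny, cfg.grid_nx)
        frame = compose_frame(np.ones(shape), np.full(shape, 0.4), cfg)
        assert (frame.values <= 1.0).all() and (frame.values >= 0.0).all()
        with pytest.raises(ValueError):
            compose_frame(np.ones(shape), np.ones((3, 3)), cfg)

    def test_generated_frames_in_unit_interval_with_white_border(self, small_field):
        b = small_field.config.border_px
        for frame in small_field.frames[::20]:
            assert (frame.values >= 0).all() and (frame.values <= 1).all()
            assert (frame.values[:b, :] == 1.0).all()
            assert (frame.values[-b:, :] == 1.0).all()


class TestSampling:
    def test_uniform_and_pixel_center(self):
        cfg = base_config()
        vals = np.full((cfg.grid_ny, cfg.grid_nx), 0.5)
        vals[10, 20] = 0.9
        frame = FieldFrame(vals, 0.0, None, cfg)
        assert sample_light(frame, np.array([50.0, 50.0])) == pytest.approx(0.5)
        px = np.array([(20 + 0.5) * cfg.dx, (10 + 0.5) * cfg.dy])
        assert sample_light(frame, px) == pytest.approx(0.9)

    def test_midpoint_of_mixed_pixels(self):
        cfg = base_config()
        vals = np.zeros((cfg.grid_ny, cfg.grid_nx))
        vals[10:, :] = 1.0  # rows 0-9 dark, 10+ bright
        frame = FieldFrame(vals, 0.0, None, cfg)
        mid = np.array([30 * cfg.dx, 10.0 * cfg.dy])  # midway between rows 9 and 10
        assert sample_light(frame, mid) == pytest.approx(0.5, abs=1e-12)

    def test_outside_arena_rejected(self):
        cfg = base_config()
        frame = FieldFrame(np.zeros((cfg.grid_ny, cfg.grid_nx)), 0.0, None, cfg)
        with pytest.raises(ValueError):
            sample_light(frame, np.array([-0.1, 10.0]))


class TestGradient:
    def test_uniform_is_zero(self):
        seq = uniform_sequence(0.5)
        g = field_gradient(seq.frames[0], np.array([40.0, 30.0]))
        assert np.allclose(g, 0.0)

    def test_linear_ramp_exact(self):
        seq = ramp_sequence()
        W = seq.config.arena_width_cm
        g = field_gradient(seq.frames[0], np.array([60.0, 40.0]))
        assert g[0] == pytest.approx(1.0 / W, rel=1e-9)
        assert g[1] == pytest.approx(0.0, abs=1e-12)

    def test_spot_matches_closed_form_within_one_percent(self):
        cfg = base_config(nx=256, ny=144)
        center = np.array([91.5, 51.0])
        frame = FieldFrame(spot_field(center, cfg), 0.0, center, cfg)
        l = cfg.spot_scale_cm
        for ang in np.linspace(0, 2 * np.pi, 7, endpoint=False):
            x = center + l * np.array([np.cos(ang), np.sin(ang)])
            num = field_gradient(frame, x)
            r_vec = x - center
            ana = (r_vec / l**2) * np.exp(-l**2 / (2 * l**2))
            assert np.linalg.norm(num - ana) < 0.01 * np.linalg.norm(ana)


class TestSequence:
    def test_seed_determinism_bit_for_bit(self, small_field_config):
        a = generate_field(small_field_config, keep_frames=True)
        b = generate_field(small_field_config, keep_frames=True)
        assert np.array_equal(a.spot_track, b.spot_track)
        assert np.array_equal(a.center_light, b.center_light)
        for fa, fb in zip(a.frames[::25], b.frames[::25]):
            assert np.array_equal(fa.values, fb.values)

    def test_temporal_average_is_frame_mean(self, small_field):
        mean = np.mean(
            [np.asarray(f.values, dtype=np.float64) for f in small_field.frames], axis=0
        )
        assert np.allclose(small_field.temporal_average, mean, atol=1e-6)

    def test_streaming_matches_in_memory(self, small_field_config):
        streamed = generate_field(small_field_config, keep_frames=False)
        assert streamed.frames is None
        full = generate_field(small_field_config, keep_frames=True)
        assert np.allclose(streamed.temporal_average, full.temporal_average, atol=1e-6)
        assert np.array_equal(streamed.center_light, full.center_light)

    def test_export_roundtrip(self, tmp_path):
        cfg = FieldConfig(
            grid_nx=48, grid_ny=32, border_px=3, noise_corr_px=1.0,
            duration_s=0.5, frame_rate_hz=8.0, seed=9,
        )
        seq = generate_field(cfg, keep_frames=True)
        export_field(seq, tmp_path / "field")
        back = load_field(tmp_path / "field")
        assert back.config == cfg
        assert np.allclose(back.spot_track, seq.spot_track)
        for fa, fb in zip(seq.frames, back.frames):
            assert np.allclose(fa.values, fb.values, atol=1e-7)


@given(
    x=st.floats(5.0, 178.0),
    y=st.floats(5.0, 97.0),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_sampled_light_always_in_unit_interval(x, y):
    cfg = base_config(border=2, noise_level=0.25)
    rng = np.random.default_rng(3)
    frame = compose_frame(
        spot_field(np.array([91.5, 51.0]), cfg),
        np.clip(rng.normal(0, 0.25, (cfg.grid_ny, cfg.grid_nx)), -0.5, 0.5),
        cfg,
    )
    L = sample_light(frame, np.array([x, y]))
    assert 0.0 <= L <= 1.0
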