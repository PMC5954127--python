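"""Hand-built field sequences for tests: uniform, linear-ramp and static-spot."""

import numpy as np

from schoolsense.lightfield import FieldConfig, FieldFrame, FieldSequence, spot_field


def base_config(n_frames=4, frame_rate=8.0, nx=64, ny=36, border=0, **kw):
    return FieldConfig(
        grid_nx=nx,
        grid_ny=ny,
        border_px=border,
        duration_s=(n_frames - 1) / frame_rate,
        frame_rate_hz=frame_rate,
        noise_level=kw.pop("noise_level", 0.0),
        **kw,
    )


def sequence_from_grid(values, config, n_frames=None, spot_center=None):
    """Repeat one grid as a static sequence (frames share the array)."""
    if n_frames is None:
        n_frames = config.n_frames
    values = np.asarray(values, dtype=np.float64)
    frames = [
        FieldFrame(values, k / config.frame_rate_hz, spot_center, config)
        for k in range(n_frames)
    ]
    return FieldSequence.from_frames(frames)


def uniform_sequence(value=1.0, n_frames=4, **kw):
    cfg = base_config(n_frames=n_frames, **kw)
    return sequence_from_grid(np.full((cfg.grid_ny, cfg.grid_nx), value), cfg, n_frames)


def ramp_sequence(n_frames=4, **kw):
    """L = x / arena_width: brightens toward +x, gradient exactly (1/W, 0)."""
    cfg = base_config(n_frames=n_frames, **kw)
    xs, _ = cfg.pixel_centers()
    grid = np.tile(xs / cfg.arena_width_cm, (cfg.grid_ny, 1))
    return sequence_from_grid(grid, cfg, n_frames)


def static_spot_sequence(center=(91.5, 51.0), n_frames=4, **kw):
    """Noise-free dark spot frozen in place, spot track attached."""
    cfg = base_config(n_frames=n_frames, **kw)
    center = np.asarray(center, dtype=float)
    return sequence_from_grid(spot_field(center, cfg), cfg, n_frames, spot_center=center)
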