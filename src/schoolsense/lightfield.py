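"""Dynamic noisy light-field stimulus.

The environment is a bright shallow arena carrying a single dark circular
spot whose brightness rises from 0 at the centre back to 1 with a Gaussian
profile, ``L_spot(x) = 1 - exp(-|x - c|^2 / (2 l^2))``.  The spot performs a
persistent random walk at constant speed, reflecting off the arena walls.
On top of the spot sits a spatiotemporally correlated zero-mean greyscale
noise field whose amplitude is set by the noise level ``eta``; composed
frames are clipped to [0, 1] and a white border band is imposed so animals
(and agents) are discouraged from hugging the walls.

Light level ``L`` is dimensionless in [0, 1] with 0 = dark, 1 = bright.
Arena coordinates are continuous, in cm, origin at the lower-left corner
with x along the long (183 cm) axis.  The grid stores pixel centres at
``(i + 0.5) * dx`` (row-major, row = y).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "FieldConfig",
    "FieldFrame",
    "FieldSequence",
    "spot_field",
    "step_spot",
    "NoiseProcess",
    "noise_field",
    "compose_frame",
    "generate_field",
    "sample_light",
    "field_gradient",
    "export_field",
    "load_field",
]


@dataclass(frozen=True)
class FieldConfig:
    """Geometry, kinematics and noise parameters of the projected field.

    Defaults reproduce the experimental stimulus: a 183 x 102 cm arena
    rendered at 940 x 540 px and 30 Hz, a dark spot of Gaussian length
    scale 38.1 cm moving at 5.7 cm/s, noise level ``eta`` = 0.25 and a
    50 px white border.  The noise synthesis scales (``noise_corr_px``,
    ``noise_persistence``, ``spot_turn_sd_rad``) are this package's
    stand-ins for stimulus internals and are exposed so other dialects of
    the stimulus can be matched.
    """

    arena_width_cm: float = 183.0
    arena_height_cm: float = 102.0
    grid_nx: int = 940
    grid_ny: int = 540
    spot_scale_cm: float = 38.1
    spot_speed_cm_s: float = 5.7
    frame_rate_hz: float = 30.0
    noise_level: float = 0.25
    border_px: int = 50
    duration_s: float = 300.0
    seed: int = 0
    # noise synthesis (documented stand-ins, configurable)
    noise_corr_px: float = 10.0
    noise_persistence: float = 0.9
    spot_turn_sd_rad: float = 0.2

    def __post_init__(self) -> None:
        positive = (
            "arena_width_cm", "arena_height_cm", "grid_nx", "grid_ny",
            "spot_scale_cm", "spot_speed_cm_s", "frame_rate_hz",
            "duration_s", "noise_corr_px",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must lie in [0, 1]")
        if not 0 <= self.border_px < min(self.grid_nx, self.grid_ny) / 2:
            raise ValueError("border_px must satisfy 0 <= border_px < min(nx, ny)/2")
        if not 0.0 <= self.noise_persistence < 1.0:
            raise ValueError("noise_persistence must lie in [0, 1)")
        if self.spot_turn_sd_rad < 0:
            raise ValueError("spot_turn_sd_rad must be non-negative")

    @property
    def dx(self) -> float:
        return self.arena_width_cm / self.grid_nx

    @property
    def dy(self) -> float:
        return self.arena_height_cm / self.grid_ny

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz)) + 1

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x-coordinates of column centres, y-coordinates of row centres (cm)."""
        xs = (np.arange(self.grid_nx) + 0.5) * self.dx
        ys = (np.arange(self.grid_ny) + 0.5) * self.dy
        return xs, ys


@dataclass
class FieldFrame:
    """One rendered light field: grid of L in [0, 1] plus its timestamp."""

    values: np.ndarray              # (ny, nx)
    t: float                        # s
    spot_center: np.ndarray | None  # (2,) cm, None for synthetic frames
    config: FieldConfig
    _gradients: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def gradients(self) -> tuple[np.ndarray, np.ndarray]:
        """(dL/dy, dL/dx) grids in 1/cm; central differences, one-sided at edges."""
        if self._gradients is None:
            g = np.asarray(self.values, dtype=np.float64)
            gy, gx = np.gradient(g, self.config.dy, self.config.dx)
            self._gradients = (gy, gx)
        return self._gradients


@dataclass
class FieldSequence:
    """A time-ordered stimulus: frames, spot track and the temporal average.

    ``frames`` may be ``None`` when a sequence was generated in streaming
    mode (``generate_field(..., keep_frames=False)``); the temporal average,
    the spot-centre track and the light level sampled at the spot centre
    are always retained, which is all the spot-tracking benchmark needs.
    """

    config: FieldConfig
    times: np.ndarray                    # (T,) s
    spot_track: np.ndarray | None        # (T, 2) cm
    temporal_average: np.ndarray         # (ny, nx)
    center_light: np.ndarray | None = None   # (T,) L at the spot centre
    frames: list[FieldFrame] | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def average_frame(self) -> FieldFrame:
        return FieldFrame(self.temporal_average, float("nan"), None, self.config)

    def frame_index(self, t: float) -> int:
        idx = int(round(t * self.config.frame_rate_hz))
        if not 0 <= idx < self.n_frames:
            raise ValueError(f"time {t} s outside the field sequence")
        return idx

    def frame_at_time(self, t: float) -> FieldFrame:
        if self.frames is None:
            raise ValueError("frames were not retained for this sequence")
        return self.frames[self.frame_index(t)]

    @classmethod
    def from_frames(cls, frames: list[FieldFrame]) -> "FieldSequence":
        """Build a sequence (with averages and track) from in-memory frames."""
        if not frames:
            raise ValueError("at least one frame required")
        config = frames[0].config
        times = np.array([f.t for f in frames], dtype=float)
        avg = np.mean([np.asarray(f.values, dtype=np.float64) for f in frames], axis=0)
        if all(f.spot_center is not None for f in frames):
            track = np.array([f.spot_center for f in frames], dtype=float)
            clight = np.array(
                [float(sample_light(f, f.spot_center)) for f in frames]
            )
        else:
            track, clight = None, None
        return cls(config, times, track, avg, clight, list(frames))


# ---------------------------------------------------------------------------
# geometry helpers


def _as_points(x: np.ndarray) -> tuple[np.ndarray, bool]:
    pts = np.asarray(x, dtype=np.float64)
    single = pts.ndim == 1
    return np.atleast_2d(pts), single


def _check_inside(pts: np.ndarray, config: FieldConfig, what: str = "point") -> None:
    if (
        (pts[:, 0] < 0).any()
        or (pts[:, 0] > config.arena_width_cm).any()
        or (pts[:, 1] < 0).any()
        or (pts[:, 1] > config.arena_height_cm).any()
    ):
        raise ValueError(f"{what} outside the arena")


def _bilinear(grid: np.ndarray, pts: np.ndarray, config: FieldConfig) -> np.ndarray:
    """Bilinear interpolation on the pixel-centre lattice.

    Within half a pixel of the grid edge values are clamped to the nearest
    pixel column/row (equivalent to one-sided evaluation there).
    """
    u = pts[:, 0] / config.dx - 0.5
    v = pts[:, 1] / config.dy - 0.5
    i0 = np.clip(np.floor(u).astype(int), 0, config.grid_nx - 2)
    j0 = np.clip(np.floor(v).astype(int), 0, config.grid_ny - 2)
    fx = np.clip(u - i0, 0.0, 1.0)
    fy = np.clip(v - j0, 0.0, 1.0)
    g = np.asarray(grid, dtype=np.float64)
    return (
        (1 - fy) * ((1 - fx) * g[j0, i0] + fx * g[j0, i0 + 1])
        + fy * ((1 - fx) * g[j0 + 1, i0] + fx * g[j0 + 1, i0 + 1])
    )


def reflect_at_walls(
    pos: np.ndarray, vec: np.ndarray, width: float, height: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror positions back inside [0, width] x [0, height].

    The component of ``vec`` (a heading or velocity) normal to each crossed
    wall is negated.  Handles both single points and (N, 2) arrays.
    """
    p = np.atleast_2d(np.array(pos, dtype=np.float64))
    v = np.atleast_2d(np.array(vec, dtype=np.float64))
    for _ in range(16):  # a step never crosses the arena more than a few times
        done = True
        for d, size in ((0, width), (1, height)):
            low = p[:, d] < 0
            if low.any():
                p[low, d] = -p[low, d]
                v[low, d] = -v[low, d]
                done = False
            high = p[:, d] > size
            if high.any():
                p[high, d] = 2 * size - p[high, d]
                v[high, d] = -v[high, d]
                done = False
        if done:
            break
    if np.asarray(pos).ndim == 1:
        return p[0], v[0]
    return p, v


def _rotate(vec: np.ndarray, angle: np.ndarray | float) -> np.ndarray:
    """Rotate 2-D vectors counter-clockwise by ``angle`` radians."""
    v = np.atleast_2d(np.asarray(vec, dtype=np.float64))
    a = np.broadcast_to(np.asarray(angle, dtype=np.float64), v.shape[0])
    c, s = np.cos(a), np.sin(a)
    out = np.empty_like(v)
    out[:, 0] = c * v[:, 0] - s * v[:, 1]
    out[:, 1] = s * v[:, 0] + c * v[:, 1]
    if np.asarray(vec).ndim == 1:
        return out[0]
    return out


# ---------------------------------------------------------------------------
# field construction


def spot_field(center: np.ndarray, config: FieldConfig) -> np.ndarray:
    """Grid of the noise-free dark spot, ``1 - exp(-r^2 / (2 l^2))``."""
    c, _ = _as_points(center)
    _check_inside(c, config, "spot center")
    cx, cy = c[0]
    xs, ys = config.pixel_centers()
    r2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    return 1.0 - np.exp(-r2 / (2.0 * config.spot_scale_cm**2))


def step_spot(
    center: np.ndarray,
    heading: np.ndarray,
    config: FieldConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the spot one frame: wrapped-Gaussian turn, constant speed, wall reflection."""
    c, _ = _as_points(center)
    _check_inside(c, config, "spot center")
    h = np.asarray(heading, dtype=np.float64)
    h = h / np.linalg.norm(h)
    h = _rotate(h, rng.normal(0.0, config.spot_turn_sd_rad))
    step = config.spot_speed_cm_s / config.frame_rate_hz
    new = c[0] + step * h
    new, h = reflect_at_walls(new, h, config.arena_width_cm, config.arena_height_cm)
    return new, h


class NoiseProcess:
    """Spatially low-pass-filtered white noise evolved as an AR(1) process.

    Each innovation is a Gaussian white-noise grid smoothed with an
    isotropic Gaussian kernel of ``noise_corr_px`` pixels, standardised to
    zero mean and unit variance.  The field evolves as
    ``n_t = a n_{t-1} + sqrt(1 - a^2) e_t`` with per-frame persistence
    ``a``, which keeps the marginal variance stationary.  ``current``
    returns the field scaled to standard deviation 0.25 and clipped to
    [-0.5, 0.5], i.e. unit peak-to-peak amplitude to be multiplied by eta.
    """

    def __init__(self, config: FieldConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.rng = rng
        self._state = self._innovation()

    def _innovation(self) -> np.ndarray:
        w = self.rng.standard_normal((self.config.grid_ny, self.config.grid_nx))
        s = gaussian_filter(w, self.config.noise_corr_px, mode="reflect", truncate=3.0)
        s -= s.mean()
        sd = s.std()
        return s / sd if sd > 0 else s

    def advance(self) -> None:
        a = self.config.noise_persistence
        self._state = a * self._state + np.sqrt(1.0 - a * a) * self._innovation()

    @property
    def current(self) -> np.ndarray:
        return np.clip(0.25 * self._state, -0.5, 0.5)


def noise_field(t: int, config: FieldConfig, rng: np.random.Generator) -> np.ndarray:
    """The noise grid at frame index ``t`` for a freshly seeded generator.

    Iterates the AR(1) recursion from its initial state, so the cost is
    O(t); use :class:`NoiseProcess` directly for long sequences.
    """
    proc = NoiseProcess(config, rng)
    for _ in range(int(t)):
        proc.advance()
    return proc.current


def compose_frame(
    spot: np.ndarray,
    noise: np.ndarray,
    config: FieldConfig,
    t: float = 0.0,
    spot_center: np.ndarray | None = None,
) -> FieldFrame:
    """``L = clip(spot + eta * noise, 0, 1)`` with the white border imposed last."""
    spot = np.asarray(spot, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    shape = (config.grid_ny, config.grid_nx)
    if spot.shape != shape or noise.shape != shape:
        raise ValueError(
            f"grid shape mismatch: spot {spot.shape}, noise {noise.shape}, "
            f"expected {shape}"
        )
    values = np.clip(spot + config.noise_level * noise, 0.0, 1.0)
    _apply_border(values, config.border_px)
    center = None if spot_center is None else np.asarray(spot_center, dtype=float)
    return FieldFrame(values, t, center, config)


def _apply_border(values: np.ndarray, border_px: int) -> None:
    if border_px > 0:
        values[:border_px, :] = 1.0
        values[-border_px:, :] = 1.0
        values[:, :border_px] = 1.0
        values[:, -border_px:] = 1.0


def generate_field(
    config: FieldConfig,
    keep_frames: bool = True,
    dtype: np.dtype = np.float32,
) -> FieldSequence:
    """Render the full stimulus for one seed.

    The spot starts uniformly inside the arena with a uniform heading; the
    seed deterministically fixes the whole sequence (spot walk and noise
    use independent child streams of ``config.seed``).  With
    ``keep_frames=False`` frames are discarded on the fly and only the
    temporal average, spot track and centre light level are kept.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_spot, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    center = np.array(
        [
            rng_spot.uniform(0.0, config.arena_width_cm),
            rng_spot.uniform(0.0, config.arena_height_cm),
        ]
    )
    theta = rng_spot.uniform(0.0, 2.0 * np.pi)
    heading = np.array([np.cos(theta), np.sin(theta)])
    noise = NoiseProcess(config, rng_noise)

    xs, ys = config.pixel_centers()
    n = config.n_frames
    eta = config.noise_level
    two_l2 = 2.0 * config.spot_scale_cm**2
    acc = np.zeros((config.grid_ny, config.grid_nx), dtype=np.float64)
    track = np.empty((n, 2))
    clight = np.empty(n)
    frames: list[FieldFrame] | None = [] if keep_frames else None

    for k in range(n):
        r2 = (xs[None, :] - center[0]) ** 2 + (ys[:, None] - center[1]) ** 2
        values = np.clip(1.0 - np.exp(-r2 / two_l2) + eta * noise.current, 0.0, 1.0)
        _apply_border(values, config.border_px)
        acc += values
        track[k] = center
        clight[k] = _bilinear(values, center[None, :], config)[0]
        if frames is not None:
            frames.append(
                FieldFrame(
                    values.astype(dtype), k / config.frame_rate_hz, center.copy(), config
                )
            )
        if k < n - 1:
            center, heading = step_spot(center, heading, config, rng_spot)
            noise.advance()

    times = np.arange(n) / config.frame_rate_hz
    return FieldSequence(config, times, track, acc / n, clight, frames)


# ---------------------------------------------------------------------------
# continuous evaluation


def sample_light(frame: FieldFrame, x: np.ndarray) -> np.ndarray | float:
    """Bilinearly interpolated light level at arena position(s) ``x`` (cm)."""
    pts, single = _as_points(x)
    _check_inside(pts, frame.config)
    out = _bilinear(frame.values, pts, frame.config)
    return float(out[0]) if single else out


def field_gradient(frame: FieldFrame, x: np.ndarray) -> np.ndarray:
    """``(dL/dx, dL/dy)`` at arena position(s) ``x``, in 1/cm.

    Central finite differences on the grid (one-sided at the outermost
    pixels), bilinearly interpolated at ``x``.
    """
    pts, single = _as_points(x)
    _check_inside(pts, frame.config)
    gy, gx = frame.gradients
    out = np.column_stack(
        [_bilinear(gx, pts, frame.config), _bilinear(gy, pts, frame.config)]
    )
    return out[0] if single else out


# ---------------------------------------------------------------------------
# export / reload


def export_field(seq: FieldSequence, outdir: str | Path) -> None:
    """Write an 8-bit PNG frame sequence, a JSON sidecar and a packed array file."""
    import imageio.v3 as iio

    if seq.frames is None:
        raise ValueError("cannot export a sequence generated without frames")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = np.stack([np.asarray(f.values, dtype=np.float32) for f in seq.frames])
    for k, frame in enumerate(stack):
        iio.imwrite(
            outdir / f"frame_{k:05d}.png",
            np.round(frame * 255).astype(np.uint8)[::-1],  # row 0 at the bottom
        )
    sidecar = {
        "config": asdict(seq.config),
        "times_s": seq.times.tolist(),
        "spot_track_cm": None if seq.spot_track is None else seq.spot_track.tolist(),
    }
    (outdir / "field.json").write_text(json.dumps(sidecar, indent=1))
    np.savez_compressed(
        outdir / "packed.npz",
        frames=stack,
        times=seq.times,
        spot_track=np.array([]) if seq.spot_track is None else seq.spot_track,
        temporal_average=seq.temporal_average,
    )


def load_field(outdir: str | Path) -> FieldSequence:
    """Reload a sequence written by :func:`export_field` from its packed container."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "field.json").read_text())
    config = FieldConfig(**sidecar["config"])
    data = np.load(outdir / "packed.npz")
    track = data["spot_track"]
    track = None if track.size == 0 else track
    frames = [
        FieldFrame(vals, float(t), None if track is None else track[k], config)
        for k, (vals, t) in enumerate(zip(data["frames"], data["times"]))
    ]
    seq = FieldSequence(
        config, data["times"], track, data["temporal_average"], None, frames
    )
    if track is not None:
        seq.center_light = np.array(
            [float(sample_light(f, track[k])) for k, f in enumerate(frames)]
        )
    return seq
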