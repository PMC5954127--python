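"""Agent-based school navigating the dynamic light field.

Each agent combines a social desired direction (zonal rules) with an
individually sensed environmental direction — the negative light gradient
at its position, corrupted by a Gaussian angular error of standard
deviation ``sigma_w`` — through a single weight ``w``::

    d = d_social_hat + w * d_environmental_hat

The summed direction is normalised, limited by the maximum turning rate,
perturbed by the social error, and the agent advances with a speed set by
the local brightness, ``s = s_min + L (s_max - s_min)`` (slow in the dark,
fast in the bright — the speed-modulation rule behind emergent sensing).
With ``w = 0`` the model reduces to the purely social speed-modulated
(Berdahl–Couzin) school; for large ``w`` agents are independent gradient
climbers.

Where the local gradient magnitude falls below ``gradient_zero_tol`` the
environmental direction is the zero vector — inside the dark plateau of the
spot (where clipping makes L exactly 0) motion is social only.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .lightfield import (
    FieldFrame,
    FieldSequence,
    field_gradient,
    reflect_at_walls,
    sample_light,
)
from .social import (
    SocialParams,
    _normalize_rows,
    _rotate_rows,
    apply_social_error,
    limit_turn,
    social_directions,
)

__all__ = [
    "AgentState",
    "ModelConfig",
    "environmental_direction",
    "desired_direction",
    "speed_from_light",
    "step_school",
    "run_simulation",
]


@dataclass
class AgentState:
    """Position (cm), unit heading and speed (cm/s) of one agent."""

    position: np.ndarray
    heading: np.ndarray
    speed: float


@dataclass(frozen=True)
class ModelConfig:
    """School-model parameters.

    ``weight`` is the gradient-sensing weight w; ``gradient_error_sd`` is
    the per-step Gaussian angular error sigma_w applied to the sensed
    gradient direction.  Speeds are configured in body lengths per second
    (the defaults
    0.5 and 3.0 BL/s are this package's documented choice) and
    converted to cm/s with ``body_length_cm`` (default: the rummy-nose
    tetra, 3.4 cm).
    """

    n_agents: int = 32
    weight: float = 0.0
    gradient_error_sd: float = 0.0
    body_length_cm: float = 3.4
    s_min_bl_s: float = 0.5
    s_max_bl_s: float = 3.0
    social: SocialParams = dc_field(default_factory=SocialParams)
    steps: int = 10_000
    record_every: int = 100
    seed: int = 0
    gradient_zero_tol: float = 1e-6
    use_environment: bool = True
    init_box_fraction: float = 0.5  # linear fraction of each axis (0.5 -> central 25% area)

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.weight < 0 or self.gradient_error_sd < 0:
            raise ValueError("weight and gradient_error_sd must be non-negative")
        if not 0 < self.s_min_bl_s <= self.s_max_bl_s:
            raise ValueError("need 0 < s_min <= s_max")
        if self.body_length_cm <= 0:
            raise ValueError("body_length_cm must be positive")
        if self.steps < 1 or self.record_every < 1 or self.steps % self.record_every:
            raise ValueError("record_every must divide steps")
        if not 0 < self.init_box_fraction <= 1:
            raise ValueError("init_box_fraction must lie in (0, 1]")

    @property
    def s_min_cm_s(self) -> float:
        return self.s_min_bl_s * self.body_length_cm

    @property
    def s_max_cm_s(self) -> float:
        return self.s_max_bl_s * self.body_length_cm


def speed_from_light(
    L: np.ndarray | float, s_min: float, s_max: float
) -> np.ndarray | float:
    """Linear speed modulation ``s = s_min + L (s_max - s_min)``; L must be in [0, 1]."""
    L = np.asarray(L, dtype=np.float64)
    if (L < 0).any() or (L > 1).any():
        raise ValueError("light level outside [0, 1]")
    out = s_min + L * (s_max - s_min)
    return float(out) if out.ndim == 0 else out


def environmental_direction(
    frame: FieldFrame,
    x: np.ndarray,
    sigma_w: float,
    tol: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy unit vector down the light gradient at position(s) ``x``.

    Returns the zero vector wherever the gradient magnitude is below
    ``tol`` (the flat interior of the dark region).  One Gaussian angle is
    drawn per query point regardless of the gradient, so the random stream
    consumed is a function of the number of agents only.
    """
    pts = np.atleast_2d(np.asarray(x, dtype=np.float64))
    g = -np.atleast_2d(field_gradient(frame, pts))
    mag = np.linalg.norm(g, axis=1)
    use = mag >= tol
    out = np.zeros_like(g)
    if use.any():
        out[use] = g[use] / mag[use, None]
    angles = rng.normal(0.0, sigma_w, size=len(pts))
    if use.any():
        out[use] = _rotate_rows(out[use], angles[use])
    if np.asarray(x).ndim == 1:
        return out[0]
    return out


def desired_direction(
    d_social: np.ndarray, d_env: np.ndarray, w: float
) -> np.ndarray:
    """Weighted cue sum ``d = d_social_hat + w * d_environmental_hat`` (not normalised)."""
    return np.asarray(d_social, dtype=np.float64) + w * np.asarray(
        d_env, dtype=np.float64
    )


def step_school(
    positions: np.ndarray,
    headings: np.ndarray,
    frame: FieldFrame,
    config: ModelConfig,
    rng_social: np.random.Generator,
    rng_env: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One synchronous update of the whole school against one field frame.

    Returns ``(new_positions, new_headings, speeds, light_levels)`` where
    speeds and light levels are the values used for this step.
    """
    p = config.social
    d_soc = social_directions(positions, headings, p, config.body_length_cm)
    if config.use_environment:
        d_env = environmental_direction(
            frame, positions, config.gradient_error_sd, config.gradient_zero_tol, rng_env
        )
    else:
        d_env = np.zeros_like(d_soc)
    desired = _normalize_rows(desired_direction(d_soc, d_env, config.weight))
    undirected = (desired == 0).all(axis=1)
    desired[undirected] = headings[undirected]  # no cue: keep heading
    new_head = limit_turn(headings, desired, p)
    new_head = apply_social_error(new_head, p.social_error_sd_rad, rng_social)
    light = np.asarray(sample_light(frame, positions))
    speeds = speed_from_light(light, config.s_min_cm_s, config.s_max_cm_s)
    new_pos = positions + new_head * (speeds * p.dt_s)[:, None]
    new_pos, new_head = reflect_at_walls(
        new_pos, new_head, frame.config.arena_width_cm, frame.config.arena_height_cm
    )
    return new_pos, new_head, speeds, light


def _initial_school(
    config: ModelConfig, field: FieldSequence, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    fc = field.config
    f = config.init_box_fraction
    lo = np.array([fc.arena_width_cm, fc.arena_height_cm]) * (1 - f) / 2
    hi = np.array([fc.arena_width_cm, fc.arena_height_cm]) * (1 + f) / 2
    positions = rng.uniform(lo, hi, size=(config.n_agents, 2))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=config.n_agents)
    headings = np.column_stack([np.cos(theta), np.sin(theta)])
    return positions, headings


def run_simulation(config: ModelConfig, field: FieldSequence) -> pd.DataFrame:
    """Run the school through ``field`` and return the trajectory table.

    Records every ``record_every``-th step including step 0, giving
    ``steps / record_every + 1`` rows per agent with columns
    ``t, id, x, y, vx, vy, L``.  The field frame nearest in time to each
    model step is used (the field and model time steps need not match).
    Identical config (incl. seed) and field give bit-identical tables.
    """
    if field.frames is None:
        raise ValueError("run_simulation needs a field with retained frames")
    fc = field.config
    dt = config.social.dt_s
    last_idx = int(round(config.steps * dt * fc.frame_rate_hz))
    if last_idx >= field.n_frames:
        raise ValueError(
            f"field too short: need frame index {last_idx}, have {field.n_frames}"
        )
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_social, rng_env = (np.random.default_rng(c) for c in ss.spawn(3))
    positions, headings = _initial_school(config, field, rng_init)

    n_rec = config.steps // config.record_every + 1
    N = config.n_agents
    out_t = np.empty(n_rec * N)
    out_id = np.empty(n_rec * N, dtype=int)
    out_xy = np.empty((n_rec * N, 2))
    out_v = np.empty((n_rec * N, 2))
    out_L = np.empty(n_rec * N)
    ids = np.arange(N)
    row = 0

    for k in range(config.steps + 1):
        frame = field.frames[int(round(k * dt * fc.frame_rate_hz))]
        if k % config.record_every == 0:
            light = np.asarray(sample_light(frame, positions))
            speeds = speed_from_light(light, config.s_min_cm_s, config.s_max_cm_s)
            sl = slice(row * N, (row + 1) * N)
            out_t[sl] = k * dt
            out_id[sl] = ids
            out_xy[sl] = positions
            out_v[sl] = headings * speeds[:, None]
            out_L[sl] = light
            row += 1
        if k < config.steps:
            positions, headings, _, _ = step_school(
                positions, headings, frame, config, rng_social, rng_env
            )

    return pd.DataFrame(
        {
            "t": out_t,
            "id": out_id,
            "x": out_xy[:, 0],
            "y": out_xy[:, 1],
            "vx": out_v[:, 0],
            "vy": out_v[:, 1],
            "L": out_L,
        }
    )
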