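"""Zonal (repulsion / orientation / attraction) social interaction rules.

The canonical zonal schooling model: each agent reacts to neighbours by
distance band — repulsion inside ``r_repulsion`` (highest priority),
alignment with headings in the orientation shell, attraction toward
neighbours in the attraction shell — restricted to a frontal perception
wedge (the rear ``360 - perception`` degrees are blind).  Heading updates
are bounded by a maximum turning rate and perturbed by a small Gaussian
"social error" rotation.

Zone radii are expressed in body lengths (BL) and converted to cm with the
body length passed by the caller.  All directions are 2-D unit vectors; a
zero vector means "no social preference" and the caller keeps its heading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SocialParams",
    "social_direction",
    "social_directions",
    "limit_turn",
    "apply_social_error",
]


@dataclass(frozen=True)
class SocialParams:
    """Zonal-model parameters (defaults: the golden-shiner fit)."""

    r_repulsion_bl: float = 0.5
    r_orientation_bl: float = 3.0
    r_attraction_bl: float = 5.5
    perception_deg: float = 270.0
    turn_rate_deg_s: float = 100.0
    social_error_sd_rad: float = 0.01
    dt_s: float = 0.125

    def __post_init__(self) -> None:
        if not 0 < self.r_repulsion_bl < self.r_orientation_bl < self.r_attraction_bl:
            raise ValueError("need 0 < r_repulsion < r_orientation < r_attraction")
        if not 0 < self.perception_deg <= 360:
            raise ValueError("perception_deg must lie in (0, 360]")
        if self.turn_rate_deg_s <= 0 or self.dt_s <= 0:
            raise ValueError("turn_rate_deg_s and dt_s must be positive")
        if self.social_error_sd_rad < 0:
            raise ValueError("social_error_sd_rad must be non-negative")

    @property
    def max_turn_rad(self) -> float:
        """Largest heading change allowed in one time step."""
        return np.radians(self.turn_rate_deg_s) * self.dt_s

    @property
    def cos_half_perception(self) -> float:
        return float(np.cos(np.radians(self.perception_deg) / 2.0))


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros_like(v)


def _normalize_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, v / n, 0.0)
    return out


def _rotate_rows(v: np.ndarray, angles: np.ndarray | float) -> np.ndarray:
    a = np.broadcast_to(np.asarray(angles, dtype=np.float64), v.shape[0])
    c, s = np.cos(a), np.sin(a)
    return np.column_stack([c * v[:, 0] - s * v[:, 1], s * v[:, 0] + c * v[:, 1]])


def social_direction(
    focal_pos: np.ndarray,
    focal_heading: np.ndarray,
    positions: np.ndarray,
    headings: np.ndarray,
    params: SocialParams,
    bl: float = 1.0,
) -> np.ndarray:
    """Desired social direction of one focal agent (reference implementation).

    ``positions``/``headings`` are the neighbours only (focal excluded).
    Returns a unit vector, or the zero vector when no neighbour is visible.
    The vectorised :func:`social_directions` must agree with this exactly.
    """
    focal_pos = np.asarray(focal_pos, dtype=np.float64)
    focal_heading = np.asarray(focal_heading, dtype=np.float64)
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    headings = np.atleast_2d(np.asarray(headings, dtype=np.float64))
    rr = params.r_repulsion_bl * bl
    ro = params.r_orientation_bl * bl
    ra = params.r_attraction_bl * bl
    repel, orient, attract = [], [], []
    for xj, hj in zip(positions, headings):
        d = xj - focal_pos
        r = np.linalg.norm(d)
        if r == 0:
            warnings.warn("coincident neighbour skipped in social_direction")
            continue
        if np.dot(d, focal_heading) / r < params.cos_half_perception:
            continue  # behind, in the blind wedge
        if r < rr:
            repel.append(-d / r)
        elif r < ro:
            orient.append(hj)
        elif r < ra:
            attract.append(d / r)
    if repel:
        return _normalize(np.sum(repel, axis=0))
    parts = []
    if orient:
        parts.append(_normalize(np.sum(orient, axis=0)))
    if attract:
        parts.append(_normalize(np.sum(attract, axis=0)))
    if not parts:
        return np.zeros(2)
    return _normalize(np.sum(parts, axis=0))


def social_directions(
    positions: np.ndarray,
    headings: np.ndarray,
    params: SocialParams,
    bl: float = 1.0,
) -> np.ndarray:
    """Desired social directions of all agents at once (all-pairs, vectorised)."""
    positions = np.asarray(positions, dtype=np.float64)
    headings = np.asarray(headings, dtype=np.float64)
    n = len(positions)
    if n < 2:
        return np.zeros((n, 2))
    sep = positions[None, :, :] - positions[:, None, :]   # sep[i, j] = x_j - x_i
    dist = np.linalg.norm(sep, axis=2)
    np.fill_diagonal(dist, np.inf)
    coincident = dist == 0
    if coincident.any():
        warnings.warn("coincident agent pair skipped in social_directions")
        dist[coincident] = np.inf
    unit = sep / dist[:, :, None]        # rows with inf distance become 0
    cos_ang = np.einsum("ijk,ik->ij", unit, headings)
    dist_v = np.where(cos_ang >= params.cos_half_perception, dist, np.inf)

    rr, ro, ra = (
        params.r_repulsion_bl * bl,
        params.r_orientation_bl * bl,
        params.r_attraction_bl * bl,
    )
    rep = (dist_v < rr).astype(np.float64)
    ori = ((dist_v >= rr) & (dist_v < ro)).astype(np.float64)
    att = ((dist_v >= ro) & (dist_v < ra)).astype(np.float64)

    rep_dir = -np.einsum("ij,ijk->ik", rep, unit)
    ori_dir = ori @ headings
    att_dir = np.einsum("ij,ijk->ik", att, unit)

    combined = _normalize_rows(_normalize_rows(ori_dir) + _normalize_rows(att_dir))
    out = np.where(rep.any(axis=1)[:, None], _normalize_rows(rep_dir), combined)
    return out


def limit_turn(
    current: np.ndarray, desired: np.ndarray, params: SocialParams
) -> np.ndarray:
    """Rotate ``current`` toward ``desired`` by at most ``turn_rate * dt``.

    Zero-length desired directions leave the current heading unchanged.
    An exactly antiparallel desired direction is a tie; it is broken by
    turning counter-clockwise.
    """
    cur = np.atleast_2d(np.asarray(current, dtype=np.float64))
    des = np.atleast_2d(np.asarray(desired, dtype=np.float64))
    des_n = _normalize_rows(des)
    max_t = params.max_turn_rad
    dot = np.einsum("ij,ij->i", cur, des_n)
    cross = cur[:, 0] * des_n[:, 1] - cur[:, 1] * des_n[:, 0]
    ang = np.arctan2(cross, dot)
    # antiparallel (|ang| == pi): arctan2's sign of -0.0 would turn clockwise
    antiparallel = np.isclose(np.abs(ang), np.pi, atol=1e-12)
    sign = np.where(antiparallel, 1.0, np.sign(ang))
    zero_des = (des_n == 0).all(axis=1)
    within = np.abs(ang) <= max_t
    turned = _rotate_rows(cur, sign * max_t)
    out = np.where(within[:, None], des_n, turned)
    out = np.where(zero_des[:, None], cur, out)
    if np.asarray(current).ndim == 1:
        return out[0]
    return out


def apply_social_error(
    direction: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate heading(s) by independent Gaussian angles of standard deviation ``sd``."""
    d = np.atleast_2d(np.asarray(direction, dtype=np.float64))
    out = _rotate_rows(d, rng.normal(0.0, sd, size=len(d)))
    if np.asarray(direction).ndim == 1:
        return out[0]
    return out
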