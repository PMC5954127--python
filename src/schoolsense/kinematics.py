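"""Trajectory kinematics and cue-correlation analysis.

Velocities and accelerations are obtained by convolving position
time-series with the first and second derivatives of a Gaussian kernel
(smoothing and differentiation in one pass).  The kernels enforce exact
moment conditions — the derivative kernel rejects constants and recovers
the slope of a linear series exactly; the second-derivative kernel rejects
constants and linear trends and recovers a quadratic's curvature exactly.

Two cue vectors are attached to every fish at every frame: the social
vector S (sum of unit vectors toward neighbours within the interaction
range r_s, default 7 BL) and the environmental vector G (negative light
gradient at the fish's position).  The directional response to each cue is
the mean dot product between the unit cue vector and the unit acceleration,
binned by cue magnitude:

    C_social        = < S_hat . a_hat >
    C_environmental = < G_hat . a_hat >

A species that steers socially shows C_social rising with |S|; a species
that senses the gradient individually shows C_environmental rising with
|G|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lightfield import FieldFrame, FieldSequence, field_gradient

__all__ = [
    "KernelSpec",
    "gaussian_kernels",
    "gaussian_derivatives",
    "social_vector",
    "social_vectors",
    "environmental_vector",
    "cue_table",
    "binned_correlation",
]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian differentiation kernel: sd and support in frames."""

    sigma_frames: float = 1.5
    window_frames: int = 11
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if self.sigma_frames <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("sigma_frames and frame_rate_hz must be positive")
        if self.window_frames < 3 or self.window_frames % 2 == 0:
            raise ValueError("window_frames must be odd and >= 3")
        if self.window_frames < 4 * self.sigma_frames:
            warnings.warn(
                "kernel window shorter than 4 sigma; derivatives will be biased"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def half(self) -> int:
        return self.window_frames // 2


def gaussian_kernels(spec: KernelSpec) -> tuple[np.ndarray, np.ndarray]:
    """(first, second)-derivative kernels, moment-corrected.

    Applied as a sliding correlation: ``v_n = sum_m k1[m] x_{n+m}`` over the
    window offsets m = -h..h.  For x = s*t the result is exactly s; for
    x = a t^2 / 2 the second kernel returns exactly a.
    """
    m = np.arange(-spec.half, spec.half + 1, dtype=np.float64)
    g = np.exp(-(m**2) / (2.0 * spec.sigma_frames**2))
    k1 = m * g / (np.sum(m**2 * g) * spec.dt)
    c = np.sum(m**2 * g) / np.sum(g)
    q = (m**2 - c) * g  # zero mean: rejects constants and (by symmetry) linears
    k2 = 2.0 * q / (np.sum(m**2 * q) * spec.dt**2)
    return k1, k2


def gaussian_derivatives(traj: pd.DataFrame, spec: KernelSpec) -> pd.DataFrame:
    """Velocity and acceleration series per agent id.

    ``traj`` needs columns ``t, id, x, y`` with regular sampling at the
    kernel's frame rate.  Edge frames without full kernel support are
    dropped; series shorter than the window yield no rows for that id.
    """
    k1, k2 = gaussian_kernels(spec)
    h = spec.half
    out = []
    for agent_id, g in traj.groupby("id"):
        g = g.sort_values("t")
        t = g["t"].to_numpy(dtype=float)
        if len(t) < spec.window_frames:
            continue
        dts = np.diff(t)
        if not np.allclose(dts, spec.dt, rtol=0, atol=1e-6):
            raise ValueError(
                f"id {agent_id}: sampling is irregular or does not match the "
                f"kernel frame rate ({spec.frame_rate_hz} Hz); split the series at gaps"
            )
        cols = {"t": t[h:-h], "id": agent_id}
        for axis in ("x", "y"):
            p = g[axis].to_numpy(dtype=float)
            cols[axis] = p[h:-h]
            cols["v" + axis] = np.correlate(p, k1, mode="valid")
            cols["a" + axis] = np.correlate(p, k2, mode="valid")
        out.append(pd.DataFrame(cols))
    if not out:
        return pd.DataFrame(columns=["t", "id", "x", "y", "vx", "vy", "ax", "ay"])
    return pd.concat(out, ignore_index=True)


def social_vector(
    focal: np.ndarray,
    neighbours: np.ndarray,
    r_s_bl: float = 7.0,
    bl: float = 1.0,
) -> np.ndarray:
    """S: sum of unit vectors toward neighbours within ``r_s_bl`` body lengths."""
    focal = np.asarray(focal, dtype=np.float64)
    neighbours = np.atleast_2d(np.asarray(neighbours, dtype=np.float64))
    if neighbours.size == 0:
        return np.zeros(2)
    sep = neighbours - focal
    dist = np.linalg.norm(sep, axis=1)
    if (dist == 0).any():
        warnings.warn("coincident neighbour skipped in social_vector")
    mask = (dist > 0) & (dist <= r_s_bl * bl)
    if not mask.any():
        return np.zeros(2)
    return (sep[mask] / dist[mask, None]).sum(axis=0)


def social_vectors(
    positions: np.ndarray, r_s_bl: float = 7.0, bl: float = 1.0
) -> np.ndarray:
    """S for every agent in one frame (all-pairs, vectorised)."""
    positions = np.asarray(positions, dtype=np.float64)
    n = len(positions)
    if n < 2:
        return np.zeros((n, 2))
    sep = positions[None, :, :] - positions[:, None, :]
    dist = np.linalg.norm(sep, axis=2)
    np.fill_diagonal(dist, np.inf)
    if (dist == 0).any():
        warnings.warn("coincident agent pair skipped in social_vectors")
        dist[dist == 0] = np.inf
    unit = sep / dist[:, :, None]
    within = (dist <= r_s_bl * bl).astype(np.float64)
    return np.einsum("ij,ijk->ik", within, unit)


def environmental_vector(frame: FieldFrame, x: np.ndarray) -> np.ndarray:
    """G = -grad L at position(s) ``x``: toward darkness, magnitude preserved (1/cm)."""
    return -field_gradient(frame, x)


def cue_table(
    traj: pd.DataFrame,
    field: FieldSequence,
    spec: KernelSpec,
    r_s_bl: float = 7.0,
    bl: float = 1.0,
) -> pd.DataFrame:
    """Per-(t, id) table of S, G and acceleration for correlation analysis.

    Accelerations come from :func:`gaussian_derivatives` on ``traj``; the
    social vector uses all agents present in the frame (including those
    whose own derivative rows were trimmed at the edges).
    """
    deriv = gaussian_derivatives(traj, spec)
    if deriv.empty:
        return deriv
    rows = []
    by_time = dict(tuple(traj.groupby("t")))
    for t, g in deriv.groupby("t"):
        full = by_time[t]
        pos_all = np.column_stack([full["x"], full["y"]])
        ids_all = full["id"].to_numpy()
        S_all = social_vectors(pos_all, r_s_bl, bl)
        S_by_id = dict(zip(ids_all, S_all))
        frame = field.frame_at_time(t)
        pts = np.column_stack([g["x"], g["y"]])
        G = environmental_vector(frame, pts)
        S = np.array([S_by_id[i] for i in g["id"]])
        rows.append(
            pd.DataFrame(
                {
                    "t": t,
                    "id": g["id"].to_numpy(),
                    "Sx": S[:, 0],
                    "Sy": S[:, 1],
                    "Gx": G[:, 0],
                    "Gy": G[:, 1],
                    "ax": g["ax"].to_numpy(),
                    "ay": g["ay"].to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def binned_correlation(
    table: pd.DataFrame,
    which: str = "social",
    bin_by: str = "social",
    bins: int | np.ndarray = 12,
) -> pd.DataFrame:
    """Mean cue-acceleration alignment, binned by cue magnitude.

    ``which`` selects the vector correlated with the acceleration
    (``"social"`` for S, ``"environmental"`` for G); ``bin_by`` selects the
    magnitude on the x-axis.  Rows where the selected cue or the
    acceleration is zero are excluded.  An integer ``bins`` lays out that
    many equal-width bins spanning the central 98% of the observed
    magnitudes; an array gives explicit edges.  Empty bins are reported
    with count 0 and NaN mean.
    """
    comp = {"social": ("Sx", "Sy"), "environmental": ("Gx", "Gy")}
    if which not in comp or bin_by not in comp:
        raise ValueError("which/bin_by must be 'social' or 'environmental'")
    cue = table[list(comp[which])].to_numpy(dtype=float)
    mag_vec = table[list(comp[bin_by])].to_numpy(dtype=float)
    acc = table[["ax", "ay"]].to_numpy(dtype=float)
    cue_n = np.linalg.norm(cue, axis=1)
    acc_n = np.linalg.norm(acc, axis=1)
    keep = (cue_n > 0) & (acc_n > 0)
    corr = np.einsum("ij,ij->i", cue[keep], acc[keep]) / (cue_n[keep] * acc_n[keep])
    mag = np.linalg.norm(mag_vec[keep], axis=1)

    if np.isscalar(bins):
        lo, hi = np.percentile(mag, [1.0, 99.0])
        if hi <= lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.digitize(mag, edges) - 1
    records = []
    for b in range(len(edges) - 1):
        sel = corr[idx == b]
        n = len(sel)
        records.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": n,
                "mean": float(np.mean(sel)) if n else float("nan"),
                "se": float(np.std(sel, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "which": which,
                "bin_by": bin_by,
            }
        )
    return pd.DataFrame(records)
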