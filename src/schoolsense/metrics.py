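"""Group-level performance, cohesion and sweep-summary statistics.

Gradient-tracking performance: psi = <<1 - L>_fish>_t averages darkness over
the group per frame, then over time; psi_null repeats the averaging with L
taken from the temporal average of the light field; the unbiased
performance is Psi = psi / psi_null.  Psi = 1 means no better than sitting
in the time-averaged darkness; Psi > 1 means genuine tracking of the moving
dark region.  Psi_max is the Psi of a virtual point tracker pinned to the
spot centre for the whole trial.

Cohesion: d_nn is the mean distance from each agent to its nearest
neighbour; group geometry reports the convex-hull area A_group and number
density rho = A_group / (N BL^2).

Sweep summaries: Psi and d_nn replicate means and standard errors over a
(w, N, eta) grid, the performance gain dPsi = max_w Psi - Psi(w -> 0), the
half-maximum weight w0, and the cohesion-optimal weight w_min that
minimises the summed squared excess of d_nn above each group size's own
minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .lightfield import FieldSequence, _bilinear, sample_light

__all__ = [
    "PerformanceRecord",
    "GroupGeometry",
    "raw_performance",
    "null_performance",
    "tracking_performance",
    "max_performance",
    "nearest_neighbour_distance",
    "trajectory_dnn",
    "group_area_density",
    "summarise_sweep",
    "performance_gain",
    "half_max_weight",
    "select_w_min",
]


@dataclass(frozen=True)
class PerformanceRecord:
    """psi, psi_null and Psi for one trial, with its sweep coordinates."""

    psi: float
    psi_null: float
    Psi: float
    n_agents: int = 0
    weight: float = float("nan")
    noise: float = float("nan")
    seed: int = -1


@dataclass(frozen=True)
class GroupGeometry:
    """Convex-hull area (cm^2), nearest-neighbour distance (cm) and density."""

    area_cm2: float
    d_nn_cm: float
    rho: float
    bl_cm: float


def _per_frame_darkness(traj: pd.DataFrame, sampler) -> float:
    """Mean over frames of the per-frame mean of (1 - L)."""
    if traj.empty:
        raise ValueError("empty trajectory")
    vals = []
    for t, group in traj.groupby("t", sort=True):
        L = sampler(t, np.column_stack([group["x"], group["y"]]))
        vals.append(float(np.mean(1.0 - L)))
    return float(np.mean(vals))


def raw_performance(traj: pd.DataFrame, field: FieldSequence) -> float:
    """psi: darkness experienced on the actual (dynamic) field."""
    return _per_frame_darkness(
        traj, lambda t, pts: sample_light(field.frame_at_time(t), pts)
    )


def null_performance(traj: pd.DataFrame, field: FieldSequence) -> float:
    """psi_null: darkness the same trajectories would see on the temporal average."""
    avg = field.average_frame
    return _per_frame_darkness(traj, lambda t, pts: sample_light(avg, pts))


def tracking_performance(psi: float, psi_null: float) -> float:
    """Psi = psi / psi_null."""
    if psi_null <= 0:
        raise ValueError("psi_null must be positive")
    return psi / psi_null


def max_performance(field: FieldSequence) -> float:
    """Psi of the virtual point trajectory pinned to the spot centre.

    Uses the centre light levels retained at generation time when frames
    were discarded; otherwise samples the stored frames along the track.
    """
    if field.spot_track is None:
        raise ValueError("field sequence carries no spot-centre track")
    if field.center_light is not None:
        psi = float(np.mean(1.0 - field.center_light))
    else:
        if field.frames is None:
            raise ValueError("need either center_light or frames")
        psi = float(
            np.mean(
                [
                    1.0 - sample_light(f, c)
                    for f, c in zip(field.frames, field.spot_track)
                ]
            )
        )
    null_L = _bilinear(field.temporal_average, field.spot_track, field.config)
    psi_null = float(np.mean(1.0 - null_L))
    return tracking_performance(psi, psi_null)


def nearest_neighbour_distance(positions: np.ndarray) -> float:
    """Mean over agents of the distance to the nearest other agent (cm)."""
    positions = np.asarray(positions, dtype=np.float64)
    if len(positions) < 2:
        raise ValueError("nearest-neighbour distance needs at least 2 agents")
    dist, _ = cKDTree(positions).query(positions, k=2)
    return float(dist[:, 1].mean())


def trajectory_dnn(traj: pd.DataFrame, min_time: float | None = None) -> float:
    """Trial-level d_nn (cm): mean of per-frame d_nn over recorded frames.

    ``min_time`` discards an initial transient (frames with t < min_time),
    e.g. the settling of the school from its random initial condition.
    """
    if min_time is not None:
        traj = traj[traj["t"] >= min_time]
    if traj.empty:
        raise ValueError("no frames left after transient cut")
    vals = [
        nearest_neighbour_distance(np.column_stack([g["x"], g["y"]]))
        for _, g in traj.groupby("t", sort=True)
    ]
    return float(np.mean(vals))


def group_area_density(positions: np.ndarray, bl: float) -> GroupGeometry:
    """Convex-hull area, d_nn and number density rho = A / (N BL^2)."""
    positions = np.asarray(positions, dtype=np.float64)
    n = len(positions)
    if n < 3:
        raise ValueError("group area needs at least 3 agents")
    try:
        area = float(ConvexHull(positions).volume)  # 2-D: volume is the area
    except QhullError:
        warnings.warn("degenerate (collinear) school: group area set to 0")
        area = 0.0
    return GroupGeometry(
        area_cm2=area,
        d_nn_cm=nearest_neighbour_distance(positions),
        rho=area / (n * bl**2),
        bl_cm=bl,
    )


# ---------------------------------------------------------------------------
# sweep summaries


def summarise_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and standard error of Psi and d_nn per (w, N, eta) cell.

    Expects tidy per-run rows with columns ``w, N, eta, replicate, Psi, d_nn``.
    """

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    out = (
        df.groupby(["w", "N", "eta"])
        .agg(
            Psi_mean=("Psi", "mean"),
            Psi_se=("Psi", _sem),
            dnn_mean=("d_nn", "mean"),
            dnn_se=("d_nn", _sem),
            n=("Psi", "size"),
        )
        .reset_index()
    )
    return out


def _cell_curve(summary: pd.DataFrame, N: int, eta: float) -> pd.DataFrame:
    sub = summary[(summary["N"] == N) & np.isclose(summary["eta"], eta)]
    if len(sub) < 2:
        raise ValueError("need at least two weights in the sweep")
    return sub.sort_values("w").reset_index(drop=True)


def performance_gain(summary: pd.DataFrame, N: int, eta: float) -> float:
    """dPsi = max_w mean Psi - mean Psi at the smallest grid weight."""
    sub = _cell_curve(summary, N, eta)
    return float(sub["Psi_mean"].max() - sub["Psi_mean"].iloc[0])


def half_max_weight(summary: pd.DataFrame, N: int, eta: float) -> float:
    """w0: first upward crossing of Psi(w->0) + dPsi/2, log-linear in w."""
    sub = _cell_curve(summary, N, eta)
    base = float(sub["Psi_mean"].iloc[0])
    gain = performance_gain(summary, N, eta)
    if gain <= 0:
        raise ValueError("performance gain is non-positive; w0 undefined")
    target = base + 0.5 * gain
    w = sub["w"].to_numpy(dtype=float)
    y = sub["Psi_mean"].to_numpy(dtype=float)
    for i in range(1, len(y)):
        if y[i] >= target and y[i - 1] < target:
            lw = np.log10(w[i - 1]) + (np.log10(w[i]) - np.log10(w[i - 1])) * (
                target - y[i - 1]
            ) / (y[i] - y[i - 1])
            return float(10**lw)
    raise ValueError("Psi(w) never crosses its half-maximum")


def select_w_min(summary: pd.DataFrame, sizes: list[int]) -> float:
    """Cohesion-optimal weight: argmin_w sum_N (d_nn(w,N) - min_w' d_nn(w',N))^2."""
    sub = summary[summary["N"].isin(sizes)]
    pivot = sub.pivot_table(index="w", columns="N", values="dnn_mean")
    if sorted(pivot.columns) != sorted(sizes) or pivot.isna().any().any():
        raise ValueError("sweep grid incomplete for the requested group sizes")
    excess = pivot - pivot.min(axis=0)
    objective = (excess**2).sum(axis=1)
    return float(objective.idxmin())
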