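"""Canonical desk-scale study protocols.

These functions bundle the package's reference computations at problem
sizes a single CPU handles in minutes, keeping the physical study
conditions fixed (arena geometry, spot scale and speed, eta = 0.25, the
shiner-fit zonal parameters):

* :func:`spot_tracking_benchmark` — the performance ceiling Psi_max: the
  Psi of a virtual point tracker pinned to the spot centre, averaged over
  five 5-minute stimulus sequences with distinct seeds.  The field grid is
  rendered at a quarter of the projector resolution (235 x 135 px,
  ~0.78 cm/px) with the noise correlation length held fixed in cm; the
  spot (38.1 cm) and noise (~2 cm) structures stay well resolved.

* :func:`cohesion_sweep` — the weight sweep behind the cohesion-optimal
  gradient-sensing weight w_min: N in {16, 32, 64, 128} over an 11-point
  log-spaced weight grid from 1e-2 to 1e3 (half-decade spacing), 5
  replicates, 2000 steps of 0.125 s.  The stimulus for these runs is
  rendered at 8 Hz (one frame per model step) and 188 x 108 px with the
  noise correlation time and length held fixed in physical units.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .lightfield import FieldConfig, generate_field
from .metrics import max_performance, select_w_min, summarise_sweep
from .simulate import ModelConfig
from .sweep import derive_seed, run_sweep

__all__ = [
    "spot_tracking_field_config",
    "spot_tracking_benchmark",
    "sweep_field_config",
    "sweep_model_config",
    "SWEEP_WEIGHTS",
    "SWEEP_SIZES",
    "cohesion_sweep",
]

#: 11 log-spaced weights, half-decade spacing, spanning the reference grid's range.
SWEEP_WEIGHTS: tuple[float, ...] = tuple(float(w) for w in np.logspace(-2, 3, 11))
SWEEP_SIZES: tuple[int, ...] = (16, 32, 64, 128)


def spot_tracking_field_config(seed: int, noise_level: float = 0.25) -> FieldConfig:
    """Full 5-minute stimulus at quarter resolution (0.78 cm/px)."""
    return FieldConfig(
        grid_nx=235,
        grid_ny=135,
        border_px=12,          # 50 px at full resolution
        noise_corr_px=2.5,     # 10 px at full resolution (~1.95 cm)
        noise_level=noise_level,
        duration_s=300.0,
        frame_rate_hz=30.0,
        seed=seed,
    )


def spot_tracking_benchmark(master_seed: int = 1, n_fields: int = 5) -> dict:
    """Mean Psi_max over ``n_fields`` stimulus sequences with distinct seeds."""
    values = []
    for k in range(n_fields):
        cfg = spot_tracking_field_config(seed=derive_seed(master_seed, 11, k))
        field = generate_field(cfg, keep_frames=False)
        values.append(max_performance(field))
    values = np.asarray(values)
    return {
        "psi_max_mean": float(values.mean()),
        "psi_max_sd": float(values.std(ddof=1)),
        "values": values.tolist(),
        "n": n_fields,
    }


def sweep_field_config(noise_level: float = 0.25) -> FieldConfig:
    """Simulation stimulus: 8 Hz frames, ~1 cm/px, physical noise scales preserved."""
    return FieldConfig(
        grid_nx=188,
        grid_ny=108,
        border_px=10,                       # 50 px at full resolution
        noise_corr_px=2.0,                  # ~1.95 cm
        noise_persistence=0.9 ** (30.0 / 8.0),  # same ~0.32 s correlation time as 0.9 @ 30 Hz
        noise_level=noise_level,
        frame_rate_hz=8.0,
        duration_s=250.0,
        seed=0,
    )


def sweep_model_config(steps: int = 2000) -> ModelConfig:
    return ModelConfig(steps=steps, record_every=50)


def cohesion_sweep(
    master_seed: int = 1,
    weights: tuple[float, ...] = SWEEP_WEIGHTS,
    sizes: tuple[int, ...] = SWEEP_SIZES,
    replicates: int = 5,
    steps: int = 2000,
    eta: float = 0.25,
    progress: bool = False,
) -> dict:
    """Weight sweep and the cohesion-optimal weight selection.

    Returns the tidy per-run table, its (w, N) summary, the selected
    ``w_min`` and the grid spacing in decades.
    """
    df = run_sweep(
        weights=weights,
        sizes=sizes,
        etas=(eta,),
        replicates=replicates,
        master_seed=master_seed,
        field_config=sweep_field_config(noise_level=eta),
        model_config=sweep_model_config(steps=steps),
        progress=progress,
    )
    summary = summarise_sweep(df)
    w_min = select_w_min(summary, list(sizes))
    spacing = float(np.mean(np.diff(np.log10(weights))))
    return {
        "runs": df,
        "summary": summary,
        "w_min": w_min,
        "grid_spacing_dec": spacing,
        "n_runs": len(df),
    }
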