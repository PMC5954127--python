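"""Replicated parameter sweeps over (w, N, eta).

One light field is generated per (eta, replicate) cell and shared by every
(w, N) run inside it, mirroring the experimental design where the same
projected stimulus seeds are reused across conditions.  Per-run seeds are
derived deterministically from the master seed and the cell indices, so a
sweep is exactly reproducible and individual cells can be recomputed in
isolation.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lightfield import FieldConfig, generate_field
from .metrics import null_performance, raw_performance, trajectory_dnn
from .simulate import ModelConfig, run_simulation

__all__ = ["derive_seed", "run_sweep"]


def derive_seed(*keys: int) -> int:
    """Deterministic 31-bit seed from a tuple of non-negative integers."""
    return int(np.random.SeedSequence([int(k) for k in keys]).generate_state(1)[0] % (2**31))


def run_sweep(
    weights: Sequence[float],
    sizes: Sequence[int],
    etas: Sequence[float],
    replicates: int,
    master_seed: int,
    field_config: FieldConfig,
    model_config: ModelConfig,
    transient_fraction: float = 0.25,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full factorial sweep; returns tidy per-run rows.

    Columns: ``w, N, eta, replicate, Psi, d_nn`` with d_nn in body lengths
    and averaged over recorded frames after the initial
    ``transient_fraction`` of the run.
    """
    rows = []
    total_time = model_config.steps * model_config.social.dt_s
    min_time = transient_fraction * total_time
    for ei, eta in enumerate(etas):
        for rep in range(replicates):
            fseed = derive_seed(master_seed, 101, ei, rep)
            fld = generate_field(
                replace(field_config, noise_level=eta, seed=fseed), keep_frames=True
            )
            for ni, n_agents in enumerate(sizes):
                for wi, w in enumerate(weights):
                    mseed = derive_seed(master_seed, 202, ei, rep, ni, wi)
                    mc = replace(
                        model_config, n_agents=n_agents, weight=float(w), seed=mseed
                    )
                    traj = run_simulation(mc, fld)
                    psi = raw_performance(traj, fld)
                    psi_null = null_performance(traj, fld)
                    dnn_bl = trajectory_dnn(traj, min_time=min_time) / mc.body_length_cm
                    rows.append(
                        {
                            "w": float(w),
                            "N": int(n_agents),
                            "eta": float(eta),
                            "replicate": rep,
                            "Psi": psi / psi_null,
                            "d_nn": dnn_bl,
                        }
                    )
            if progress:
                print(f"eta={eta} replicate={rep + 1}/{replicates} done", flush=True)
    return pd.DataFrame(rows)
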