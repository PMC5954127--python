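# schoolsense

Collective gradient sensing in fish schools: a dynamic noisy light-field
stimulus generator, an agent-based zonal schooling model with a tunable
individual gradient-sensing weight, and the metric suite for group
gradient-tracking performance and cohesion.

## The problem

Schooling fish can find dark (safe) water in a noisy, moving light field
in two distinct ways.  A school can track the gradient *collectively*
without any individual sensing, purely because individuals swim slower in
the dark and faster in the bright while interacting socially (emergent
sensing, the Berdahl–Couzin mechanism, as in golden shiners); or each fish
can sense the local gradient *individually* (as rummy-nose tetras do).
This package implements the model that spans both: each agent combines a
social desired direction from the canonical zonal (repulsion /
orientation / attraction) rules with the direction of steepest descent of
the light field,

    d = d̂_social + w · d̂_environmental ,      v = s d̂ ,  s = s_min + L (s_max − s_min)

where the weight `w` interpolates from a purely social school (w = 0) to
independent gradient climbers (w → ∞), and an angular error σ_w can
corrupt the sensed gradient.  Group performance is measured as

    Ψ = ψ / ψ_null ,   ψ = ⟨⟨1 − L⟩_fish⟩_t ,

the darkness the group actually experienced, normalised by the darkness
the same trajectories would have collected on the *time-averaged* field;
Ψ > 1 means genuine tracking of the moving dark spot.  Cohesion is the
mean nearest-neighbour distance d_nn; the weight that keeps d_nn minimal
across group sizes locates the balance point between social and private
information.

It is intended for researchers in collective animal behaviour who want a
reproducible, scriptable implementation of this stimulus + model + metric
stack, including the trajectory analysis (Gaussian-kernel differentiation,
social/environmental cue correlations) used to classify real trajectories.

## Worked example

```python
from schoolsense import (FieldConfig, ModelConfig, generate_field,
                         run_simulation, raw_performance, null_performance,
                         trajectory_dnn)

# a 2-minute stimulus at reduced resolution, noise level 0.25
field = generate_field(FieldConfig(grid_nx=188, grid_ny=108, border_px=10,
                                   noise_corr_px=2.0, frame_rate_hz=8.0,
                                   noise_persistence=0.9**(30/8),
                                   duration_s=125.0, seed=7))
for w in (0.0, 31.6):
    cfg = ModelConfig(n_agents=32, weight=w, steps=1000,
                      record_every=50, seed=11)
    traj = run_simulation(cfg, field)
    psi, psi_null = raw_performance(traj, field), null_performance(traj, field)
    dnn_bl = trajectory_dnn(traj, min_time=31.25) / cfg.body_length_cm
    print(f"w={w:5}: Psi = {psi/psi_null:.3f}   d_nn = {dnn_bl:.2f} BL")
```

prints

```
w=  0.0: Psi = 1.486   d_nn = 0.55 BL
w= 31.6: Psi = 1.922   d_nn = 1.13 BL
```

— the purely social school already tracks the spot collectively through
the speed–light coupling (Ψ ≈ 1.5 > 1), giving agents a strongly weighted
gradient sense lifts performance further (Ψ ≈ 1.9), and on this stimulus
the extra performance costs a looser school (d_nn roughly doubles) — the
trade-off the weight sweep quantifies.

The same pipeline runs from the shell:

```
schoolsense fieldgen --seed 7 --out field/       # PNG frames + JSON + packed array
schoolsense simulate --config cfg.yaml --seed 11 --out traj.csv
schoolsense sweep    --config cfg.yaml --seed 1  --out sweep/
schoolsense metrics  --traj traj.csv --field field/ --out metrics.json
schoolsense analyze  --traj traj.csv --field field/ --out curves.csv
```

Externally produced trajectory tables (CSV with `t,id,x,y`) are accepted
wherever the simulator's own output is.

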