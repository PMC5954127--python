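# Methods

## The system

`schoolsense` models a school of fish navigating a dynamic, noisy light
field in a shallow rectangular arena (183 × 102 cm), asking how group-level
gradient tracking depends on the balance between *social* information
(zonal schooling interactions) and *individual environmental* information
(direct sensing of the local light gradient).  Two biological strategies
anchor the model's limits: golden shiners track darkness only collectively,
through a speed–light coupling (emergent sensing, the Berdahl–Couzin
mechanism), while rummy-nose tetras sense the gradient individually.

## Stimulus

Each frame of the light field is

    L(x, t) = clip( L_spot(x, t) + η · n(x, t), 0, 1 ),

with a white border band imposed after clipping (the border must be exactly
white).  The dark spot is a Gaussian well,
`L_spot = 1 − exp(−|x − c(t)|² / 2ℓ²)` with length scale ℓ = 38.1 cm
(read as the Gaussian σ), whose centre performs a persistent random walk at
5.7 cm/s — a wrapped-Gaussian turn of sd 0.2 rad per frame, reflecting off
the arena walls.  Frames render at 30 Hz on a 940 × 540 px grid with a
50 px white border; light level is dimensionless in [0, 1].

The noise field n is this package's stand-in for unspecified stimulus
internals: Gaussian white noise smoothed with an isotropic Gaussian kernel
(default 10 px ≈ 1.95 cm), evolved as an AR(1) process with per-frame
persistence 0.9 at 30 Hz (correlation time ≈ 0.32 s), standardised to zero
mean and scaled to sd 0.25 and range [−0.5, 0.5] (unit peak-to-peak), so
that η multiplies a unit-amplitude field.  All scales are configurable so
other stimulus dialects can be matched.  When protocols run the field at a
different frame rate, the persistence is re-expressed per frame
(0.9^(30/r)) so the physical correlation time is preserved.

One consequence worth knowing: near the spot centre the clipped sum
produces patches where L is exactly 0, so the gradient genuinely vanishes
there and agents in the dark core steer socially.

## Agent model

Each of N agents carries a position (cm), a unit heading and a speed.  Per
time step (dt = 0.125 s), synchronously:

1. **Social direction** (zonal rules, radii in body lengths, BL = 3.4 cm by
   default): neighbours in the rear 90° wedge (perception 270°) are
   invisible.  Any visible neighbour inside 0.5 BL triggers pure repulsion
   (normalised sum of −unit separation vectors) and overrides everything
   else.  Otherwise the normalised mean heading over the orientation shell
   [0.5, 3.0) BL and the normalised attraction sum over [3.0, 5.5) BL are
   added with equal weight and renormalised.  No visible neighbour ⇒ zero
   vector (keep heading).
2. **Environmental direction**: d_env = −∇L at the agent's position,
   normalised; the zero vector where |∇L| < 10⁻⁶ /cm.  A Gaussian angular
   error of sd σ_w (default 0) is applied each step to the sensed
   direction.
3. **Cue combination**: d = d̂_social + w · d̂_environmental.  If d = 0 the
   agent keeps its heading.  w = 0 reduces exactly (bit-for-bit, verified)
   to the purely social speed-modulated model; w → ∞ gives independent
   gradient climbers.
4. **Turning limit and social error**: the heading rotates toward d̂ by at
   most 100°/s × dt = 12.5° per step (an exactly antiparallel target turns
   counter-clockwise, a documented tie-break), then receives a Gaussian
   rotation of sd 0.01 rad.
5. **Speed and advance**: s = s_min + L·(s_max − s_min) sampled at the
   agent's position — slow in the dark, fast in the bright.  s_min, s_max
   default to 0.5 and 3.0 BL/s, this package's own choice of a realistic
   cruising range.  Walls reflect (normal velocity component negated).

Initial positions are uniform in the central 25% of the arena area,
headings uniform on the circle.  Three independent child streams of the
run seed drive initialisation, social error and gradient error, which is
what makes the w = 0 equivalence exact rather than statistical.  The field
frame nearest in time to each model step is used; field and model clocks
need not match.

## Metrics

* ψ = ⟨⟨1 − L⟩_fish⟩_t (darkness averaged over the group per frame, then
  over frames); ψ_null repeats this on the temporal average of the field;
  Ψ = ψ/ψ_null.  Ψ is exactly 1 on a static field (tested as an identity).
* Ψ_max: Ψ of a virtual point trajectory pinned to the spot centre — the
  performance ceiling for a volumeless tracker.
* d_nn: mean distance to the nearest neighbour, averaged over recorded
  frames; trial values discard the first 25% of the run (initial-condition
  transient; a short-run analogue of steady state).  Ψ, by contrast,
  averages all recorded frames, matching its definition as a whole-trial
  darkness average.
* Sweep aggregates over replicate means: ΔΨ = max_w Ψ − Ψ(smallest grid w)
  (the 10⁻² grid point proxies w = 0); w₀ is the first upward crossing of
  Ψ(0) + ΔΨ/2, interpolated log-linearly in w; w̃_min is the grid weight
  minimising Σ_N (d_nn(w, N) − min_w′ d_nn(w′, N))² — each size's excess
  over its own best cohesion, so per-size offsets cancel.  This reading of
  the selection rule is isolated in one function (`select_w_min`) so
  alternative objectives can be swapped in.
* Group geometry: A_group is the convex-hull area (one choice among many
  possible school-area definitions; comparisons against experimental
  densities should stay qualitative), ρ = A_group/(N·BL²).

## Trajectory kinematics

Velocities and accelerations come from correlating position series with
first- and second-derivative Gaussian kernels (σ = 1.5 frames, 11-frame
window).  The kernels are moment-corrected: the first-derivative kernel
has zero sum and unit first moment (a linear series yields its slope to
machine precision), the second has zero 0th and 1st moments and unit
second moment (a quadratic yields its exact curvature).  Edge frames
without full support are dropped; irregular sampling is rejected rather
than silently bridged.

The social vector S_i sums unit vectors toward neighbours within 7 BL; the
environmental vector G_i = −∇L keeps its magnitude.  Directional response
curves bin the mean of Ŝ·â (or Ĝ·â) by cue magnitude — default 12
equal-width bins over the central 98% of observed magnitudes; zero cues
and zero accelerations are excluded.  |S| thresholds are on the raw,
unnormalised sum.

In simulation these curves recover the two strategies: a w = 0 school
shows C_social rising with |S| and exceeding C_environmental, while a
school at w = 31.6 shows C_environmental well above C_social.  Because the
model normalises its gradient cue, the simulated environmental response is
only weakly magnitude-dependent — unlike a real gradient-sensing fish,
whose turning response may scale with gradient strength.

## Problem sizes for the reference computations

The bundled protocols run at sizes a single CPU finishes in minutes:

* Spot-tracking benchmark (Ψ_max): five 5-minute fields at η = 0.25,
  rendered at quarter resolution (235 × 135 px, ≈0.78 cm/px) with the
  noise correlation length held fixed in cm.  Convergence: on one seed,
  Ψ_max = 1.8553 at quarter vs 1.8548 at half resolution (0.03%).
* Cohesion sweep (w̃_min): 11 log-spaced weights (10⁻²–10³, half-decade
  spacing), N ∈ {16, 32, 64, 128}, 5 replicates, 2000 steps; the stimulus
  rendered at 8 Hz (one frame per model step) and 188 × 108 px with
  physical noise scales preserved.  One field per (η, replicate) is shared
  by all (w, N) runs, mirroring the reuse of stimulus seeds across
  experimental conditions.

## Known limitations

* The noise synthesis is a stand-in.  The *location* of the
  cohesion-optimal weight is acutely sensitive to the noise correlation
  structure: with the default ~2 cm correlation length, noise gradients
  are about twice the spot's peak gradient (0.030 vs 0.016 /cm), the
  gradient-following performance plateau sits near Ψ ≈ 1.5–1.7, and the
  d_nn minimum falls at w ≈ 1 before large-w dispersal sets in.  Smoother
  noise strengthens gradient following but removes the large-w
  fragmentation entirely (agents collapse into the dark core).  The
  *qualitative* laws — sigmoidal Ψ(w), ΔΨ shrinking with N, σ_w destroying
  high-w performance, the d_nn U-shape — are robust across this family;
  absolute weight scales are not.
* Repulsion cannot enforce spacing at large w, because the cue sum lets a
  strong gradient term override all social terms; overcrowding in the dark
  spot (d_nn ≪ 0.5 BL) is expected at high weights and coarse dt.
* Reflective walls for both spot and agents are a modelling choice; the
  turning-rate bound applies to the steering rule, not to wall
  reflections, which flip headings discontinuously.
* The synthetic stimulus and school share none of the sensory latencies,
  body mechanics or individual variability of real fish; passing tests
  show the algorithms implement the stated model, not that the model
  captures any particular species.
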