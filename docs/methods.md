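# Methods

## Model

The simulator computes the probability that an animal crossing the site of
a tethered tidal-kite energy device collides with it, resolved over the
device cross-section.  It is purely kinematic: prescribed rigid-body
motion, no hydrodynamics, no behaviour.

**Animal.**  A solid ellipsoid of revolution with major radius `L/2` and
minor radii `L/3` (`L` = body length), major axis along the current
direction (+x).  It translates at constant speed `v` from `(0, y0, z0)`;
orientation is fixed.  The default `L = 1.410 m`, `v = 1.8 m/s` describes
a seal-sized animal.

**Device.**  Two rigid components anchored at the seabed foundation (the
coordinate origin; z up, x downstream):

* *Tether*: a straight capsule from the origin to the kite attachment
  point.  Length 25 m; radius 0.02 m (configurable — a value in the range
  of a quarter-scale mooring line; the true line diameter is not public).
* *Kite*: a watertight rectangular-planform plate, span 3 m along the body
  lateral axis, default chord 0.75 m and thickness 0.15 m (configurable),
  centred on the attachment point.  The true hydrofoil shape of the
  commercial device is proprietary; the plate reproduces its swept-volume
  character without inventing aerofoil detail.  Consequences are discussed
  under *Limitations*.

**Flight path.**  The attachment point moves on the tether sphere as a 2:1
Lissajous figure-of-eight: vertical oscillation of half-height `h/2` about
the mean height `H − D` (water depth `H`, mean kite depth `D`) with period
`T/2`; lateral oscillation of half-width `w/2` with period `T`.  The pose
is a sequence of three rotations about the bottom joint — polar angle
`β = arccos((H − D + (h/2)·sin(4π(t−δ)/T)) / L_tether)`, azimuth
`γ = arcsin((w/2)·sin(2π(t−δ)/T)/(L_tether·sin β))`, and heading `α` about
the tether axis obtained from the previous two attachment positions so the
chord tracks the flight direction (bootstrapped at `t = 0` from the
parametric path at `−dt`).  The tether is straight (no catenary or drag
curvature), as in the source schematic.  Two readings of the path
equations were fixed deliberately: the `L` in both denominators is the
*tether* length (25 m) — with the animal length the arccos argument would
exceed 1 — and the angular frequencies are `4π/T` and `2π/T`, forced by
the stated periods `T/2` and `T`.  Note that the two centre-plane
crossings of the figure-of-eight per period coincide at the node height
`H − D`: the figure-of-eight self-intersects there.

**Trial.**  Time advances in steps `dt` from 0.  Each step poses the kite
first, then translates the animal, then evaluates the minimum distance
from the ellipsoid to each component.  A distance below the collision
threshold (1 mm) ends the trial; if both components are below threshold in
the same step the component is recorded as `both`.  Otherwise the trial
ends collision-free once the animal centre passes
`L_tether + (kite bounding-box diagonal) + L/2` downstream — tether length
plus the furthest the kite can protrude plus the animal's own half-length,
so the tail has also cleared the reachable volume.  The collision location
is the midpoint of the closest-point pair at the first sub-threshold step,
and the relative speed is the animal velocity minus the device material
point velocity (finite-differenced over one step), recorded for future
severity weighting.

**Ensemble.**  The deterministic trial is repeated for every launch
position on a cross-section grid and for `n_delays` phase lags
`δ = k·T/n_delays`.  Defaults are the study conditions of the quarter-scale
demonstration: heights 0–20 m and lateral positions −7–7 m in 1 m steps
(21 × 15 positions), 50 phase lags (probability resolution 1/50 = 2 %),
`NSim = 15750` trials.  Per-position collision fractions give the
probability map; `P_A = 100·NColl/NSim` averages over the whole grid and
`P_SweptA = 100·NColl/(NCollPos·n_delays)` over the `NCollPos`
collision-prone positions only.  The printed definition of the swept-area
metric in the source omits the `n_delays` factor, but every tabulated
value there is consistent only with the normalisation by trials launched
from collision-prone positions (e.g. 1510/(117·50) = 25.81 %); that
normalisation is implemented.  Per-component probabilities credit
simultaneous (`both`) hits to each component — that is the only reading
consistent with the published component tables — while the tether/kite
count ratio uses exclusive counts; the probability map exposes both
conventions.

## Numerics

**Distance kernel.**  Every collision test reduces to the minimum distance
between the solid ellipsoid and a convex primitive (segment or triangle).
It is computed by alternating projection between the two convex bodies,
which converges to a globally closest pair (or a common point when the
shapes intersect, reporting distance 0 with a containment flag — the
threshold test needs no signed distance).  Projection onto the solid
ellipsoid solves `Σ (a_i p_i)² / (t + a_i²)² = 1` by Newton iteration from
`t = 0` (convex and decreasing, hence monotone convergence); projection
onto triangles uses the standard Voronoi-region case analysis.  All
kernels are vectorised so one batch call resolves every triangle at every
candidate time step of a trial.  Iteration stops when the iterate moves
less than 1e−10 m (cap 400 iterations; a warning is issued if the residual
still exceeds 1e−4 m — the distance *value* converges roughly
quadratically faster than the iterate, so this still bounds the value
tightly).  Agreement with independent brute-force surface-sampling +
simplex-polish oracles is within 1e−3 m on randomised instances and
within 1e−9 m of closed forms for sphere specialisations.

**Step pruning.**  Cheap true lower bounds (animal centre to attachment
minus the kite's bounding-sphere radius and the animal's major semi-axis;
animal centre to tether segment minus radii) prove most time steps
collision-free; only the surviving candidate steps get exact distance
queries.  Because the bounds are rigorous the outcome is identical to
evaluating every step, and all trials of one phase lag share a
precomputed pose table.  The optional dead-position pruning flag
(default off) additionally skips grid positions whose cross-plane
clearance from the device's whole one-period trace exceeds the threshold
plus all bounds and a two-step motion margin — again a sound
over-approximation, verified in tests to leave every outcome unchanged.

**Time step.**  There is no sub-step (continuous) collision detection;
temporal fidelity is governed by `dt`, chosen by a convergence study
(`convergence_study` repeats the sweep over a dt ladder).  The default
`dt = 0.1 s` is where baseline-case counts stabilise.  The appropriate
step always depends on the fastest relative motion, so the study should be
repeated for faster kites or animals.

**Determinism.**  No randomness anywhere: sweeps are pure functions of the
configuration, output in canonical z-major/y/δ order, and reruns are
byte-identical (asserted in tests).  Trials are independent, so any
parallel scheduler may be used as long as results are emitted in canonical
order; the shipped implementation is serial — the full 15750-trial
baseline takes about two minutes on one core.

## Test ensembles

Unit and property tests use a reduced ensemble — 7 lateral × 5 height
positions, 10 phase lags, `dt = 0.2 s` (350 trials) — which covers the
mooring point, the tether corridor and part of the flight band; the
qualitative map-structure checks (V-shaped collision region, decay above
the anchor, rise again in the flight band, tether dominance, exact
left–right symmetry) run at the full 15750-trial resolution.  A degenerate
configuration (h = w = 0, `H − D` equal to the tether length, kite
disabled) makes the tether a static vertical capsule, for which collision
outcomes have a closed form used as an oracle; admitting `w = 0` for this
purpose is a deliberate relaxation of the path validation.

The synthetic ensembles emulate the study conditions exactly (geometry,
grids, phase lags); they do not emulate real animal behaviour — no
avoidance, no variable heading or speed, no depth preference — so passing
tests validate the geometric/kinematic machinery, not ecological realism.
Field application requires weighting the maps by species depth
distributions and transit rates, and ideally by collision severity; all
out of scope here.

## Limitations

* Absolute collision counts depend on the kite's exact shape.  With the
  published span but a generic plate for chord/thickness/profile, counts
  differ from those obtained with the proprietary CAD geometry (for the
  baseline: 1772 total collisions vs 1510 published, collision-prone
  positions 128 vs 117, tether/kite ratio 2.4 vs 1.7), while the spatial
  structure and both probability metrics are closely comparable
  (P_A 11.3 % vs 9.6 %, P_SweptA 27.7 % vs 25.8 %).  Metric arithmetic on
  the published bookkeeping reproduces every published probability
  exactly.
* Straight tether, rigid kite, constant-speed straight-line animal: no
  hydrodynamic deformation, evasion, or flow interaction.
* Collisions are scored by first contact only; multiple potential contacts
  per transit are not enumerated.
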