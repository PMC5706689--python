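# tidalkite

Transient 3-D (4-D: space × time) collision-probability simulation for
marine animals transiting a tethered tidal-kite energy device.

## The problem

For horizontal-axis tidal turbines, the chance that a transiting animal is
struck by a blade is classically estimated from the swept rotor disc:

    P_C = N · ω · L · cos(α) / v

with `N` blades at rotational velocity `ω`, animal length `L`, transit
speed `v` and angle `α` to the flow.  Devices such as sub-sea tidal kites
have no rotor disc: a winged hydrofoil on a 25 m tether flies a
figure-of-eight through the water column, and an animal that has safely
passed the tether may still meet the kite further downstream.  No
closed-form expression covers that geometry.

`tidalkite` instead simulates the encounter directly.  The animal is a
solid ellipsoid (major radius `L/2`, minor radii `L/3`) translating at
constant speed `v` along the current direction from a launch position
`(y0, z0)` on a cross-section grid.  The device is two rigid components — a
straight tether capsule anchored at the seabed foundation (the origin) and
a triangulated kite plate — posed at every time step by three rotations
about the bottom joint:

* `β(t) = arccos((H − D + (h/2)·sin(4π(t−δ)/T)) / L_tether)` — the polar
  angle; the kite centre oscillates about its mean height `H − D` with
  period `T/2`,
* `γ(t) = arcsin((w/2)·sin(2π(t−δ)/T) / (L_tether·sin β))` — the azimuth;
  the lateral position oscillates in `±w/2` with period `T`,
* `α` — the heading about the tether axis, taken from the previous two
  kite positions so the chord points along the flight path.

Together these trace a 2:1 Lissajous figure-of-eight of height `h` and
width `w`.  At each step the minimum distance between the ellipsoid and
each component is evaluated; any distance below a threshold (1 mm) is a
collision and ends the trial, recording the component, time, location and
relative speed.  A trial with phase lag `δ` between animal and kite motion
is deterministic; an ensemble over `n` evenly spaced phase lags and all
grid positions yields a spatial collision-probability map and two scalar
metrics:

    P_A      = 100 · NColl / NSim                       (whole cross-section)
    P_SweptA = 100 · NColl / (NCollPos · n_delays)      (collision-prone positions only)

where `NCollPos` counts grid positions with at least one collision.
`P_SweptA` is the quantity comparable to `P_C`.

## Worked example

A reduced ensemble (7 lateral × 5 height launch positions, 10 phase lags,
0.2 s steps — 350 trials) of the baseline device (`T = 8 s`, `D = 7 m`,
`H = 20 m`, `h = 3 m`, `w = 10 m`, 1.41 m animal at 1.8 m/s):

```python
from tidalkite import SimulationConfig, probability_map, run_sweep, summarize

cfg = SimulationConfig.baseline(
    y_grid=tuple(range(-3, 4)),
    z_grid=(0.0, 2.0, 4.0, 6.0, 8.0),
    n_delays=10,
    dt=0.2,
)
sweep = run_sweep(cfg)
print(summarize(sweep).to_series())
print(probability_map(sweep).p_total)
```

prints

```
NColl_Kite                   0.000000
NColl_Tether                66.000000
NColl_Both                   0.000000
NColl                       66.000000
NColl_Tether/NColl_Kite           NaN
NCollPos                    21.000000
NSim                       350.000000
P_A_Kite                     0.000000
P_A_Tether                  18.857143
P_A_Device                  18.857143
P_SweptA_Device             31.428571

[[0.  0.  0.  1.  0.  0.  0. ]
 [0.  0.  0.2 0.6 0.2 0.  0. ]
 [0.  0.1 0.3 0.4 0.3 0.1 0. ]
 [0.  0.2 0.4 0.4 0.4 0.2 0. ]
 [0.2 0.2 0.4 0.2 0.4 0.2 0.2]]
```

66 of 350 launches collide (all with the tether — this reduced grid stays
below the kite's flight band), so `P_A = 18.86 %`; averaged only over the
21 collision-prone positions the probability is `P_SweptA = 31.43 %`.  The
map (rows: height 0–8 m; columns: y = −3…3 m) shows the certain collision
at the mooring point — the tether blocks that passage at every phase lag —
probabilities decaying with height above it, and exact left–right
symmetry.  The full study resolution is 21 heights × 15 lateral positions
× 50 phase lags (`NSim = 15750`, probability resolution 2 %) at
`dt = 0.1 s`, identical code; it runs in about two minutes on one core.

The `examples/` directory walks through each capability (flight path,
single transit, sweep + metrics, rotor-disc comparison, time-step
convergence).  The same operations are exposed as a CLI for batch use:

```
tidalkite sweep config.yaml -o out/      # trials.csv, metrics.csv, map.csv, manifest.json
tidalkite converge config.yaml --dt 0.2 --dt 0.1
tidalkite metrics out/trials.csv --n-delays 50
tidalkite map out/trials.csv --n-delays 50 -o map.png
```

Everything is deterministic: rerunning a sweep reproduces the output files
byte for byte.

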