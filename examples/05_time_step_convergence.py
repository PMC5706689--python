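"""Time-step convergence of the collision counts.

Discrete stepping can miss brief near-contacts, so collision counts depend
on dt until the step is small enough.  This repeats a small ensemble at a
coarse-to-fine series of time steps; pick the coarsest dt whose counts have
stabilised (0.1 s for the baseline device at full resolution).
"""

from tidalkite import SimulationConfig, convergence_study

cfg = SimulationConfig.baseline(
    y_grid=(-1.0, 0.0, 1.0),
    z_grid=(0.0, 4.0, 8.0, 12.0),
    n_delays=5,
)
table = convergence_study(cfg, [0.4, 0.2, 0.1, 0.05])
print(table.to_string(float_format=lambda v: f"{v:.2f}"))
print()
print("Counts rise as the step shrinks (fewer missed grazing passes) and")
print("then plateau; the kite typically needs a finer step than the tether")
print("because its material speed is higher.")
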