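"""Shared fixtures: a reduced sweep ensemble reused across test modules."""

import numpy as np
import pytest

from tidalkite import SimulationConfig, run_sweep


def reduced_config(**overrides) -> SimulationConfig:
    """Down-scaled ensemble: 7 lateral x 5 height positions, 10 phase lags,
    0.2 s steps.  Covers the mooring point, the tether corridor and part of
    the kite's flight band while staying fast enough for unit tests."""
    kwargs = dict(
        y_grid=tuple(range(-3, 4)),
        z_grid=(0.0, 2.0, 4.0, 6.0, 8.0),
        n_delays=10,
        dt=0.2,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def reduced_sweep():
    return run_sweep(reduced_config())


@pytest.fixture(scope="session")
def reduced_sweep_df(reduced_sweep):
    return reduced_sweep.to_dataframe()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
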