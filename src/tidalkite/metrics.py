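"""Probability metrics over sweep ensembles.

Two scalar probabilities summarise a sweep.  ``P_A`` averages over the whole
investigated cross-section grid::

    P_A = 100 * NColl / NSim

while ``P_SweptA`` averages only over the swept area — the ``NCollPos`` grid
positions at which at least one phase lag produced a collision::

    P_SweptA = 100 * NColl / (NCollPos * n_delays)

``P_SweptA`` is the quantity comparable to the classic rotor-disc collision
probability ``P_C = N * omega * L * cos(alpha) / v`` used for horizontal-axis
turbines, which this module also provides for reference.

Component bookkeeping: a trial that touches kite and tether in the same time
step counts as ``both``.  Per-component probabilities attribute ``both``
trials to *each* component (so ``P_A_kite`` uses kite-only + both), while the
tether/kite collision-count ratio uses the exclusive counts; both
conventions are exposed for the probability maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulation import SimulationConfig, SweepResult

__all__ = [
    "MetricsSummary",
    "ProbabilityMap",
    "ClassicRotorParams",
    "p_a",
    "p_swept_a",
    "summarize",
    "summarize_frame",
    "component_probabilities",
    "probability_map",
    "probability_map_from_frame",
    "classic_rotor_probability",
]


def p_a(n_coll: int, n_sim: int) -> float:
    """Collision probability (%) across the entire cross-section."""
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    if not 0 <= n_coll <= n_sim:
        raise ValueError("need 0 <= n_coll <= n_sim")
    return 100.0 * n_coll / n_sim


def p_swept_a(n_coll: int, n_coll_pos: int, n_delays: int) -> float:
    """Collision probability (%) across the swept area only.

    Normalised by the number of trials launched from collision-prone
    positions, ``n_coll_pos * n_delays``.
    """
    if n_coll_pos <= 0:
        raise ValueError("n_coll_pos must be positive")
    if n_delays <= 0:
        raise ValueError("n_delays must be positive")
    if n_coll > n_coll_pos * n_delays:
        raise ValueError("more collisions than trials in the swept area")
    return 100.0 * n_coll / (n_coll_pos * n_delays)


@dataclass(frozen=True)
class MetricsSummary:
    """Scalar collision statistics of one sweep."""

    n_coll_kite_only: int
    n_coll_tether_only: int
    n_coll_both: int
    n_coll: int
    n_coll_pos: int
    n_sim: int
    n_delays: int
    p_a: float
    p_a_kite: float
    p_a_tether: float
    p_swept_a: float
    tether_kite_ratio: float  # exclusive counts, rounded to one decimal; nan if undefined

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "NColl_Kite": self.n_coll_kite_only,
                "NColl_Tether": self.n_coll_tether_only,
                "NColl_Both": self.n_coll_both,
                "NColl": self.n_coll,
                "NColl_Tether/NColl_Kite": self.tether_kite_ratio,
                "NCollPos": self.n_coll_pos,
                "NSim": self.n_sim,
                "P_A_Kite": self.p_a_kite,
                "P_A_Tether": self.p_a_tether,
                "P_A_Device": self.p_a,
                "P_SweptA_Device": self.p_swept_a,
            }
        )

    def to_csv(self, path) -> None:
        self.to_series().rename("value").rename_axis("metric").to_csv(path)


def _as_dataframe(sweep) -> tuple[pd.DataFrame, int]:
    if isinstance(sweep, SweepResult):
        return sweep.to_dataframe(), sweep.config.n_delays
    raise TypeError("expected a SweepResult; use summarize_frame for raw tables")


def summarize_frame(df: pd.DataFrame, n_delays: int) -> MetricsSummary:
    """Metrics from a trials table (as written to / read back from CSV)."""
    kite_only = int((df["component"] == "kite").sum())
    tether_only = int((df["component"] == "tether").sum())
    both = int((df["component"] == "both").sum())
    n_coll = kite_only + tether_only + both
    n_sim = len(df)
    collided = df[df["collided"]]
    n_coll_pos = int(collided.groupby(["z0", "y0"]).ngroups)
    ratio = round(tether_only / kite_only, 1) if kite_only > 0 else float("nan")
    return MetricsSummary(
        n_coll_kite_only=kite_only,
        n_coll_tether_only=tether_only,
        n_coll_both=both,
        n_coll=n_coll,
        n_coll_pos=n_coll_pos,
        n_sim=n_sim,
        n_delays=n_delays,
        p_a=p_a(n_coll, n_sim),
        p_a_kite=p_a(kite_only + both, n_sim),
        p_a_tether=p_a(tether_only + both, n_sim),
        p_swept_a=p_swept_a(n_coll, n_coll_pos, n_delays) if n_coll_pos else float("nan"),
        tether_kite_ratio=ratio,
    )


def summarize(sweep: SweepResult) -> MetricsSummary:
    """Scalar metrics of a sweep ensemble."""
    df, n_delays = _as_dataframe(sweep)
    return summarize_frame(df, n_delays)


# spec-facing alias: per-component probability bookkeeping
component_probabilities = summarize


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-position collision probabilities over the cross-section grid.

    Values are quantised to multiples of ``1/n_delays`` by construction
    (each position sees exactly ``n_delays`` trials).  Component maps are
    available in both conventions: inclusive (simultaneous hits credited to
    each component) and exclusive.
    """

    y: np.ndarray  # (ny,)
    z: np.ndarray  # (nz,)
    p_total: np.ndarray  # (nz, ny)
    p_kite: np.ndarray
    p_tether: np.ndarray
    p_kite_exclusive: np.ndarray
    p_tether_exclusive: np.ndarray
    n_delays: int

    def to_dataframe(self) -> pd.DataFrame:
        yy, zz = np.meshgrid(self.y, self.z)
        return pd.DataFrame(
            {
                "y": yy.ravel(),
                "z": zz.ravel(),
                "p_total": self.p_total.ravel(),
                "p_kite": self.p_kite.ravel(),
                "p_tether": self.p_tether.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def value_at(self, y0: float, z0: float) -> float:
        i = int(np.argmin(np.abs(self.z - z0)))
        j = int(np.argmin(np.abs(self.y - y0)))
        return float(self.p_total[i, j])


def probability_map(sweep: SweepResult) -> ProbabilityMap:
    """Collision probability per grid position (total and per component)."""
    df, n_delays = _as_dataframe(sweep)
    cfg = sweep.config
    return probability_map_from_frame(
        df, n_delays, y=np.asarray(cfg.y_grid), z=np.asarray(cfg.z_grid)
    )


def probability_map_from_frame(
    df: pd.DataFrame, n_delays: int, y=None, z=None
) -> ProbabilityMap:
    """Probability map from a trials table (e.g. read back from CSV)."""
    y = np.asarray(sorted(df["y0"].unique()) if y is None else y)
    z = np.asarray(sorted(df["z0"].unique()) if z is None else z)
    shape = (len(z), len(y))
    counts = {key: np.zeros(shape) for key in ("total", "kite", "tether", "both")}
    zi = {v: i for i, v in enumerate(z)}
    yi = {v: i for i, v in enumerate(y)}
    for row in df.itertuples():
        if not row.collided:
            continue
        i, j = zi[row.z0], yi[row.y0]
        counts["total"][i, j] += 1
        if row.component in ("kite", "both"):
            counts["kite"][i, j] += 1
        if row.component in ("tether", "both"):
            counts["tether"][i, j] += 1
        if row.component == "both":
            counts["both"][i, j] += 1
    return ProbabilityMap(
        y=y,
        z=z,
        p_total=counts["total"] / n_delays,
        p_kite=counts["kite"] / n_delays,
        p_tether=counts["tether"] / n_delays,
        p_kite_exclusive=(counts["kite"] - counts["both"]) / n_delays,
        p_tether_exclusive=(counts["tether"] - counts["both"]) / n_delays,
        n_delays=n_delays,
    )


@dataclass(frozen=True)
class ClassicRotorParams:
    """Inputs of the rotor-disc sweep probability for horizontal-axis
    turbines: ``N`` blades at rotational velocity ``omega`` (rev/s) versus an
    animal of length ``L`` crossing the disc at speed ``v`` and angle
    ``alpha`` to the flow."""

    N: int
    omega: float  # revolutions per second
    L: float
    v: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.N <= 0 or self.omega <= 0 or self.L <= 0 or self.v <= 0:
            raise ValueError("N, omega, L and v must be positive")
        if not 0 <= self.alpha <= np.pi / 2:
            raise ValueError("alpha must lie in [0, pi/2]")


def classic_rotor_probability(p: ClassicRotorParams) -> float:
    """Mean rotor-disc collision probability, clamped to [0, 1]."""
    raw = p.N * p.omega * p.L * np.cos(p.alpha) / p.v
    if raw > 1.0:
        warnings.warn(
            f"rotor-disc probability {raw:.3f} exceeds 1; clamped", stacklevel=2
        )
    return float(np.clip(raw, 0.0, 1.0))
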