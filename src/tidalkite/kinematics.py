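"""Kite flight-path kinematics and animal transit.

The kite hangs on a straight tether of length ``L`` anchored at the origin
(the seabed foundation) and flies a figure-of-eight: its attachment point
traces a 2:1 Lissajous pattern on the sphere of radius ``L``, with the
vertical oscillation (period ``T/2``, half-height ``h/2`` about the mean
height ``H - D`` above the seabed) twice as fast as the lateral one (period
``T``, half-width ``w/2``).  The pose at time ``t`` is a sequence of three
rotations about the bottom joint:

* ``beta``  — polar angle from the vertical, ``cos(beta) = z / L``,
* ``gamma`` — azimuthal offset from the downstream centre plane,
* ``alpha`` — heading about the tether axis, chosen from the previous two
  attachment positions so the chord points along the flight path.

Coordinates are right-handed with x downstream (the animal's direction of
motion), z up, and the origin at the foundation; a mean *depth* ``D`` in a
water column of depth ``H`` corresponds to height ``H - D`` above the
seabed.  The animal translates at constant speed along +x at a fixed
cross-section position ``(y0, z0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "ConfigurationError",
    "FlightPathParams",
    "AnimalParams",
    "PhaseLag",
    "KiteState",
    "beta_angle",
    "gamma_angle",
    "attachment_point",
    "alpha_heading",
    "kite_pose",
    "kite_frames",
    "animal_position",
    "phase_lags",
]


class ConfigurationError(ValueError):
    """A flight-path or simulation configuration is geometrically unreachable."""


@dataclass(frozen=True)
class FlightPathParams:
    """Kinematic constants of the figure-of-eight flight path.

    Parameters
    ----------
    T : float
        Kite period in seconds (time to fly the full figure-of-eight).
    D : float
        Mean kite depth below the surface, m.
    H : float
        Water depth, m.
    h, w : float
        Height and width of the figure-of-eight, m.
    tether_length : float
        Straight-line tether length from foundation to kite, m.
    """

    T: float = 8.0
    D: float = 7.0
    H: float = 20.0
    h: float = 3.0
    w: float = 10.0
    tether_length: float = 25.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ConfigurationError("kite period T must be positive")
        if not 0 < self.D < self.H:
            raise ConfigurationError("mean depth D must satisfy 0 < D < H")
        # w = h = 0 (a static tether) is admitted as a degenerate path,
        # useful for validation against closed-form static geometry
        if self.w < 0 or self.h < 0:
            raise ConfigurationError("figure-of-eight dimensions must be non-negative")
        if self.tether_length <= 0:
            raise ConfigurationError("tether length must be positive")
        z_hi = self.H - self.D + self.h / 2.0
        z_lo = self.H - self.D - self.h / 2.0
        if z_hi > self.tether_length:
            raise ConfigurationError(
                "top of the flight path exceeds the tether length "
                f"(H-D+h/2 = {z_hi} > {self.tether_length})"
            )
        if z_lo < 0:
            raise ConfigurationError(
                "bottom of the flight path is below the seabed (h/2 > H-D)"
            )
        if self.h / 2.0 > self.D:
            raise ConfigurationError("top of the flight path breaks the surface")
        # the lateral excursion must stay on the tether sphere: the arcsin
        # argument of gamma peaks where sin(beta) is smallest
        if self.w > 0:
            sin_beta_min = np.sqrt(
                1.0 - (max(z_hi, abs(z_lo)) / self.tether_length) ** 2
            )
            if self.w / 2.0 > self.tether_length * sin_beta_min + 1e-12:
                raise ConfigurationError(
                    "figure-of-eight width w is unreachable for this tether length"
                )

    @classmethod
    def baseline(cls) -> "FlightPathParams":
        """Quarter-scale tidal-kite demonstration configuration."""
        return cls()

    @property
    def mean_height(self) -> float:
        """Mean height of the kite centre above the seabed, m."""
        return self.H - self.D


@dataclass(frozen=True)
class AnimalParams:
    """Transiting animal: length sets the ellipsoid, speed the transit."""

    L: float = 1.410
    v: float = 1.8
    y0: float = 0.0
    z0: float = 0.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ConfigurationError("animal length must be positive")
        if self.v <= 0:
            raise ConfigurationError("animal speed must be positive")

    @property
    def semi_axis_major(self) -> float:
        return self.L / 2.0

    @property
    def semi_axis_minor(self) -> float:
        return self.L / 3.0


@dataclass(frozen=True)
class PhaseLag:
    """Time offset between animal transit start and kite phase."""

    delta: float
    T: float

    def __post_init__(self) -> None:
        if not 0 <= self.delta < self.T:
            raise ConfigurationError("phase lag must satisfy 0 <= delta < T")


def phase_lags(T: float, n_delays: int) -> np.ndarray:
    """``n_delays`` phase lags distributed evenly over the kite period."""
    if n_delays < 1:
        raise ConfigurationError("n_delays must be at least 1")
    return np.arange(n_delays) * (T / n_delays)


@dataclass(frozen=True)
class KiteState:
    """Kite pose at one instant: the three joint angles and the rigid pose."""

    t: float
    alpha: float
    beta: float
    gamma: float
    pose: RigidTransform
    attachment_point: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.attachment_point is None:
            object.__setattr__(self, "attachment_point", self.pose.translation)


def beta_angle(t, delta, p: FlightPathParams):
    """Polar tether angle; the kite centre height has period ``T/2``."""
    arg = (
        p.H - p.D + 0.5 * p.h * np.sin(4.0 * np.pi / p.T * (np.asarray(t) - delta))
    ) / p.tether_length
    if np.any(np.abs(arg) > 1.0):
        raise ConfigurationError("flight path leaves the tether sphere (|cos beta| > 1)")
    return np.arccos(arg)


def gamma_angle(t, delta, beta, p: FlightPathParams):
    """Azimuthal tether angle; the lateral position has period ``T``."""
    if p.w == 0.0:
        return np.zeros_like(np.asarray(beta, dtype=float))
    sin_beta = np.sin(np.asarray(beta))
    if np.any(sin_beta == 0.0):
        raise ConfigurationError("gamma is undefined for a vertical tether (beta = 0)")
    arg = 0.5 * p.w * np.sin(2.0 * np.pi / p.T * (np.asarray(t) - delta)) / (
        p.tether_length * sin_beta
    )
    if np.any(np.abs(arg) > 1.0):
        raise ConfigurationError("figure-of-eight width unreachable (|sin gamma| > 1)")
    return np.arcsin(arg)


def attachment_point(t, delta, p: FlightPathParams) -> np.ndarray:
    """Tether attachment point(s) on the sphere of radius ``tether_length``.

    Height above seabed is ``L cos(beta)``; lateral position ``L sin(beta)
    sin(gamma)`` oscillates in ``[-w/2, w/2]``; the remainder points
    downstream (+x).
    """
    beta = beta_angle(t, delta, p)
    gamma = gamma_angle(t, delta, beta, p)
    L = p.tether_length
    sb = np.sin(beta)
    return np.stack(
        [L * sb * np.cos(gamma), L * sb * np.sin(gamma), L * np.cos(beta)], axis=-1
    )


def _heading_frames(attachments: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Rotation matrices (N, 3, 3) with columns (chord, span, radial).

    ``directions`` are finite-difference motion vectors of the attachment
    point; they are projected onto the local tangent plane of the tether
    sphere to give the chord axis.  Near-stationary samples inherit the
    previous heading (or a downstream default at start-up).
    """
    att = np.atleast_2d(attachments)
    dirs = np.atleast_2d(directions).astype(float).copy()
    e_r = att / np.linalg.norm(att, axis=1, keepdims=True)
    frames = np.empty((len(att), 3, 3))
    prev_chord = None
    for i in range(len(att)):
        d = dirs[i]
        d_tan = d - (d @ e_r[i]) * e_r[i]
        norm = np.linalg.norm(d_tan)
        if norm < 1e-12:
            if prev_chord is not None:
                d_tan = prev_chord - (prev_chord @ e_r[i]) * e_r[i]
            else:  # static path: default chord points downstream
                x_hat = np.array([1.0, 0.0, 0.0])
                d_tan = x_hat - (x_hat @ e_r[i]) * e_r[i]
            norm = np.linalg.norm(d_tan)
        chord = d_tan / norm
        span = np.cross(e_r[i], chord)
        frames[i] = np.column_stack([chord, span, e_r[i]])
        prev_chord = chord
    return frames


def _alpha_from_frame(frame: np.ndarray, attachment: np.ndarray) -> float:
    """Heading angle about the tether axis, measured from the local
    "south" tangent direction (the direction of increasing beta)."""
    e_r = attachment / np.linalg.norm(attachment)
    # tangent basis: t1 = d(e_r)/d(beta) direction, t2 = e_r x t1
    z_hat = np.array([0.0, 0.0, 1.0])
    t1 = z_hat - (z_hat @ e_r) * e_r
    n = np.linalg.norm(t1)
    if n < 1e-12:  # vertical tether: use downstream reference
        t1 = np.array([1.0, 0.0, 0.0])
    else:
        t1 = -t1 / n  # increasing beta moves away from the vertical
    t2 = np.cross(e_r, t1)
    chord = frame[:, 0]
    return float(np.arctan2(chord @ t2, chord @ t1))


def alpha_heading(state_prev2: KiteState, state_prev1: KiteState) -> float:
    """Heading angle from the previous two kite positions.

    Aligns the chord axis with the finite-difference direction of
    attachment-point motion; coincident positions reuse the previous
    heading.
    """
    d = state_prev1.attachment_point - state_prev2.attachment_point
    if np.linalg.norm(d) < 1e-12:
        return state_prev1.alpha
    frame = _heading_frames(state_prev1.attachment_point[None, :], d[None, :])[0]
    return _alpha_from_frame(frame, state_prev1.attachment_point)


def kite_frames(
    times: np.ndarray, delta: float, p: FlightPathParams, bootstrap_dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised poses over a time grid.

    Returns ``(attachments (N, 3), rotations (N, 3, 3))``.  The heading at
    each step uses the current and previous attachment positions; the first
    step is bootstrapped from the parametric path at ``times[0] -
    bootstrap_dt``.
    """
    t = np.asarray(times, dtype=float)
    att = attachment_point(t, delta, p)
    att_prev = attachment_point(t - bootstrap_dt, delta, p)
    dirs = np.empty_like(att)
    dirs[0] = att[0] - att_prev[0]
    dirs[1:] = att[1:] - att[:-1]
    return att, _heading_frames(att, dirs)


def kite_pose(
    t: float,
    delta: float,
    p: FlightPathParams,
    history: tuple[KiteState, KiteState] | None = None,
    bootstrap_dt: float = 1e-3,
) -> KiteState:
    """Kite state at time ``t``: three rotations about the bottom joint.

    ``history`` supplies the two previous states for the heading rule; when
    absent (start of a trajectory) the heading is bootstrapped from the
    parametric path at ``t - bootstrap_dt`` and ``t``.
    """
    beta = float(beta_angle(t, delta, p))
    gamma = float(gamma_angle(t, delta, beta, p))
    att = attachment_point(t, delta, p)
    if history is not None:
        prev2, prev1 = history
        d = att - prev1.attachment_point
        if np.linalg.norm(d) < 1e-12:
            d = prev1.attachment_point - prev2.attachment_point
    else:
        d = att - attachment_point(t - bootstrap_dt, delta, p)
    frame = _heading_frames(att[None, :], d[None, :])[0]
    alpha = _alpha_from_frame(frame, att)
    return KiteState(
        t=float(t),
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        pose=RigidTransform(frame, att),
    )


def animal_position(t, a: AnimalParams) -> np.ndarray:
    """Ellipsoid centre at time ``t``: linear translation along +x."""
    t = np.asarray(t, dtype=float)
    x = a.v * t
    out = np.stack(
        [x, np.full_like(x, a.y0), np.full_like(x, a.z0)], axis=-1
    )
    return out
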