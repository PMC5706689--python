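"""Independent brute-force distance oracles.

These routines bound or estimate shape-to-ellipsoid distances by dense
surface sampling (optionally polished with a general-purpose local
minimiser over the surface parametrisations).  They share no code path with
the production kernels in :mod:`tidalkite.geometry` and exist to
cross-check them; they are far too slow for use inside the simulator.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .geometry import CapsuleShape, EllipsoidShape, KiteSurface

__all__ = [
    "sample_ellipsoid_surface",
    "sample_capsule_surface",
    "sample_mesh_surface",
    "brute_force_distance_oracle",
    "refined_segment_ellipsoid_distance",
    "refined_mesh_ellipsoid_distance",
]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere sampling (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _ellipsoid_point(theta, phi, e: EllipsoidShape) -> np.ndarray:
    a, b = e.semi_axis_major, e.semi_axis_minor
    body = np.stack(
        [
            a * np.sin(phi) * np.cos(theta),
            b * np.sin(phi) * np.sin(theta),
            b * np.cos(phi),
        ],
        axis=-1,
    )
    return e.pose.apply(body)


def sample_ellipsoid_surface(e: EllipsoidShape, n: int) -> np.ndarray:
    body = _fibonacci_sphere(n) * e.semi_axes
    return e.pose.apply(body)


def sample_capsule_surface(c: CapsuleShape, n: int) -> np.ndarray:
    """Points on the capsule surface (cylindrical wall plus end caps)."""
    axis = c.endpoint_b - c.endpoint_a
    length = np.linalg.norm(axis)
    axis = axis / length
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    if c.radius == 0.0:
        s = np.linspace(0.0, 1.0, n)
        return c.endpoint_a + s[:, None] * (c.endpoint_b - c.endpoint_a)
    n_wall = max(n // 2, 1)
    n_side = max(int(np.sqrt(n_wall)), 2)
    s, ang = np.meshgrid(
        np.linspace(0.0, 1.0, n_side), np.linspace(0.0, 2 * np.pi, n_side, endpoint=False)
    )
    wall = (
        c.endpoint_a
        + s.ravel()[:, None] * (c.endpoint_b - c.endpoint_a)
        + c.radius * (np.cos(ang.ravel())[:, None] * u + np.sin(ang.ravel())[:, None] * v)
    )
    n_cap = max((n - len(wall)) // 2, 8)
    sphere = _fibonacci_sphere(n_cap) * c.radius
    caps = np.vstack([c.endpoint_a + sphere, c.endpoint_b + sphere])
    return np.vstack([wall, caps])


def sample_mesh_surface(k: KiteSurface, n: int) -> np.ndarray:
    """Area-weighted stratified sampling of the posed triangulated surface."""
    tri = k.world_triangles
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    counts = np.maximum((n * areas / areas.sum()).astype(int), 1)
    rng = np.random.default_rng(0)  # fixed: the oracle is deterministic
    pts = []
    for t, m in zip(tri, counts):
        r1 = np.sqrt(rng.random(m))
        r2 = rng.random(m)
        pts.append(
            (1 - r1)[:, None] * t[0]
            + (r1 * (1 - r2))[:, None] * t[1]
            + (r1 * r2)[:, None] * t[2]
        )
    pts.append(tri.reshape(-1, 3))  # always include the vertices
    return np.vstack(pts)


def _surface_points(shape, n: int) -> np.ndarray:
    if isinstance(shape, EllipsoidShape):
        return sample_ellipsoid_surface(shape, n)
    if isinstance(shape, CapsuleShape):
        return sample_capsule_surface(shape, n)
    if isinstance(shape, KiteSurface):
        return sample_mesh_surface(shape, n)
    raise TypeError(f"unsupported shape {type(shape).__name__}")


def brute_force_distance_oracle(shape_a, shape_b, n_samples: int = 10_000) -> float:
    """Minimum pairwise distance over dense surface samplings of two shapes.

    Upper-bounds the true surface-to-surface distance and converges to it as
    ``n_samples`` grows; reports 0 when samples of one shape fall inside the
    other (overlap).
    """
    pa = _surface_points(shape_a, n_samples)
    pb = _surface_points(shape_b, n_samples)
    for ell, other in ((shape_a, pb), (shape_b, pa)):
        if isinstance(ell, EllipsoidShape) and np.any(ell.contains(other)):
            return 0.0
    # chunked pairwise minimum to bound memory
    best = np.inf
    for chunk in np.array_split(pa, max(len(pa) * len(pb) // 4_000_000, 1)):
        d2 = np.sum((chunk[:, None, :] - pb[None, :, :]) ** 2, axis=2)
        best = min(best, float(np.sqrt(d2.min())))
    return best


def _polish_on_ellipsoid(x0, objective) -> float:
    res = minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return float(res.fun)


def refined_segment_ellipsoid_distance(c: CapsuleShape, e: EllipsoidShape) -> float:
    """Segment/capsule-to-ellipsoid distance by grid search over (segment
    parameter × surface angles) followed by a local simplex polish."""

    def objective(x):
        s, theta, phi = x
        s = np.clip(s, 0.0, 1.0)
        p_seg = c.endpoint_a + s * (c.endpoint_b - c.endpoint_a)
        p_ell = _ellipsoid_point(theta, phi, e)
        return np.linalg.norm(p_seg - p_ell)

    s_grid = np.linspace(0.0, 1.0, 60)
    seg_pts = c.endpoint_a + s_grid[:, None] * (c.endpoint_b - c.endpoint_a)
    if np.any(e.contains(seg_pts)):
        return 0.0
    thetas = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    phis = np.linspace(0, np.pi, 24)
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    ell_pts = _ellipsoid_point(tt.ravel(), pp.ravel(), e)
    d2 = np.sum((seg_pts[:, None, :] - ell_pts[None, :, :]) ** 2, axis=2)
    flat = np.argsort(d2, axis=None)[:6]
    best = np.inf
    for idx in flat:
        i, j = np.unravel_index(idx, d2.shape)
        x0 = [s_grid[i], tt.ravel()[j], pp.ravel()[j]]
        best = min(best, _polish_on_ellipsoid(x0, objective))
    return max(best - c.radius, 0.0)


def refined_mesh_ellipsoid_distance(k: KiteSurface, e: EllipsoidShape) -> float:
    """Mesh-to-ellipsoid distance by dense sampling plus local polish over
    (triangle barycentric coordinates × surface angles)."""
    samples = sample_mesh_surface(k, 4000)
    if np.any(e.contains(samples)):
        return 0.0

    i = np.arange(48) + 0.5
    thetas = np.pi * (1 + 5**0.5) * i
    phis = np.arccos(1 - 2 * i / 48)
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    ell_angles = np.column_stack([tt.ravel(), pp.ravel()])
    ell_pts = _ellipsoid_point(ell_angles[:, 0], ell_angles[:, 1], e)

    uv = np.array(
        [(u, v) for u in np.linspace(0, 1, 9) for v in np.linspace(0, 1, 9) if u + v <= 1]
    )
    best = np.inf
    for t in k.world_triangles:

        def objective(x, t=t):
            u, v, theta, phi = x
            u, v = np.clip(u, 0, 1), np.clip(v, 0, 1)
            if u + v > 1.0:
                u, v = u / (u + v), v / (u + v)
            p_tri = t[0] + u * (t[1] - t[0]) + v * (t[2] - t[0])
            return np.linalg.norm(p_tri - _ellipsoid_point(theta, phi, e))

        tri_pts = t[0] + uv[:, :1] * (t[1] - t[0]) + uv[:, 1:] * (t[2] - t[0])
        d2 = np.sum((tri_pts[:, None, :] - ell_pts[None, :, :]) ** 2, axis=2)
        ii, jj = np.unravel_index(np.argmin(d2), d2.shape)
        x0 = [uv[ii, 0], uv[ii, 1], ell_angles[jj, 0], ell_angles[jj, 1]]
        best = min(best, _polish_on_ellipsoid(x0, objective))
    return best
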