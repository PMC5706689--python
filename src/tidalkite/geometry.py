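"""Geometric primitives and minimum-distance queries against an ellipsoid.

The animal is modelled as a solid ellipsoid of revolution (one major and two
equal minor semi-axes); the device is a capsule (tether) plus a triangulated
plate (kite wing).  Every collision test in the simulator reduces to the
minimum Euclidean distance between the ellipsoid surface and a convex
primitive (point, segment or triangle).

Distances are computed by alternating projection between the two convex
bodies: project the current estimate onto the solid ellipsoid, then back onto
the primitive, and repeat.  For a pair of convex sets this converges to a
globally closest pair of points; for intersecting shapes it converges to a
common point, which reports distance zero.  Projection onto the solid
ellipsoid solves the standard one-parameter Lagrange condition
``x_i = a_i^2 p_i / (t + a_i^2)`` by a safeguarded Newton iteration.  All
kernels are vectorised so a whole batch of primitives (e.g. every triangle of
the kite at every candidate time step of a trial) is resolved in one call.

Distances are unsigned: interior/overlapping configurations report 0 together
with a containment flag, which is all the threshold-based collision test
needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import trimesh

__all__ = [
    "RigidTransform",
    "EllipsoidShape",
    "CapsuleShape",
    "KiteSurface",
    "DistanceQuery",
    "build_kite_surface",
    "point_to_ellipsoid_distance",
    "segment_to_ellipsoid_distance",
    "mesh_to_ellipsoid_distance",
]

_ORTHONORMAL_TOL = 1e-9


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must have finite components, got {arr}")
    return arr


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x_world = rotation @ x_body + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = _as_vec3(self.translation, "translation")
        if rot.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {rot.shape}")
        if not np.all(np.isfinite(rot)):
            raise ValueError("rotation must be finite")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=_ORTHONORMAL_TOL):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation must be proper (determinant +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, translation) -> "RigidTransform":
        return cls(np.eye(3), translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map body-frame point(s), shape (3,) or (N, 3), to the world frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class EllipsoidShape:
    """Solid ellipsoid of revolution; major axis along the body x-axis."""

    semi_axis_major: float
    semi_axis_minor: float
    pose: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if not (self.semi_axis_major > 0 and self.semi_axis_minor > 0):
            raise ValueError("ellipsoid semi-axes must be positive")

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array(
            [self.semi_axis_major, self.semi_axis_minor, self.semi_axis_minor]
        )

    @classmethod
    def from_animal(cls, length: float, center=(0.0, 0.0, 0.0)) -> "EllipsoidShape":
        """Ellipsoid for an animal of body length ``length``: major radius
        ``length/2``, minor radii ``length/3``, major axis along +x."""
        return cls(length / 2.0, length / 3.0, RigidTransform.from_translation(center))

    def contains(self, points: np.ndarray) -> np.ndarray:
        body = self.pose.inverse().apply(np.atleast_2d(points))
        return np.sum((body / self.semi_axes) ** 2, axis=1) <= 1.0


@dataclass(frozen=True)
class CapsuleShape:
    """Line segment inflated by ``radius``; models the straight tether."""

    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        a = _as_vec3(self.endpoint_a, "endpoint_a")
        b = _as_vec3(self.endpoint_b, "endpoint_b")
        if self.radius < 0:
            raise ValueError("capsule radius must be non-negative")
        if np.allclose(a, b):
            raise ValueError("capsule endpoints must be distinct")
        object.__setattr__(self, "endpoint_a", a)
        object.__setattr__(self, "endpoint_b", b)


class KiteSurface:
    """Watertight triangulated plate standing in for the kite wing.

    Body frame: chord along x, span along y, thickness along z, centred on
    the tether attachment point.  The true hydrofoil geometry of a tidal kite
    is proprietary; a rectangular-planform plate with the published 3 m span
    reproduces the swept-volume character of the device without inventing
    aerofoil detail.
    """

    def __init__(
        self,
        span: float,
        chord: float,
        thickness: float,
        pose: RigidTransform | None = None,
    ) -> None:
        if not (span > 0 and chord > 0 and thickness > 0):
            raise ValueError("kite dimensions must all be positive")
        self.span = float(span)
        self.chord = float(chord)
        self.thickness = float(thickness)
        self.pose = pose if pose is not None else RigidTransform.identity()
        self._mesh = trimesh.creation.box(extents=(self.chord, self.span, self.thickness))

    @property
    def mesh(self) -> trimesh.Trimesh:
        """Body-frame triangulated surface."""
        return self._mesh

    @property
    def body_triangles(self) -> np.ndarray:
        """(F, 3, 3) triangle vertices in the body frame."""
        return self._mesh.triangles.copy()

    @property
    def world_triangles(self) -> np.ndarray:
        tri = self._mesh.triangles
        return self.pose.apply(tri.reshape(-1, 3)).reshape(tri.shape)

    @property
    def half_diagonal(self) -> float:
        """Radius of the bounding sphere about the attachment point."""
        return 0.5 * float(np.sqrt(self.span**2 + self.chord**2 + self.thickness**2))

    @property
    def surface_area(self) -> float:
        return float(self._mesh.area)

    @property
    def is_watertight(self) -> bool:
        return bool(self._mesh.is_watertight)

    def posed(self, pose: RigidTransform) -> "KiteSurface":
        new = KiteSurface.__new__(KiteSurface)
        new.span, new.chord, new.thickness = self.span, self.chord, self.thickness
        new.pose = pose
        new._mesh = self._mesh
        return new


def build_kite_surface(span: float, chord: float, thickness: float) -> KiteSurface:
    """Construct the parametric kite plate in its body frame."""
    return KiteSurface(span, chord, thickness)


class DistanceQuery(NamedTuple):
    """Result of a shape-to-ellipsoid minimum-distance query."""

    distance: float
    contained: bool
    point_on_shape: np.ndarray
    point_on_ellipsoid: np.ndarray


# ---------------------------------------------------------------------------
# vectorised kernels (ellipsoid body frame, axis-aligned, centred at origin)
# ---------------------------------------------------------------------------


def project_points_to_ellipsoid(
    points: np.ndarray, semi_axes: np.ndarray, iterations: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto the *solid* axis-aligned ellipsoid at the origin.

    Interior points project to themselves.  Returns ``(projected, inside)``.
    The exterior branch solves sum((a_i p_i)^2 / (t + a_i^2)^2) = 1 for the
    positive root by Newton from t = 0; the function is convex and
    decreasing, so the iteration increases monotonically to the root.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    a0, a1, a2_ = (float(a) ** 2 for a in np.asarray(semi_axes, dtype=float))
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    inside = x * x / a0 + y * y / a1 + z * z / a2_ <= 1.0
    out = ~inside
    proj = p.copy()
    if np.any(out):
        xo, yo, zo = x[out], y[out], z[out]
        q0, q1, q2 = xo * xo * a0, yo * yo * a1, zo * zo * a2_  # (a_i p_i)^2
        t = np.zeros(len(xo))
        for _ in range(iterations):
            d0, d1, d2 = t + a0, t + a1, t + a2_
            r0, r1, r2 = q0 / (d0 * d0), q1 / (d1 * d1), q2 / (d2 * d2)
            f = r0 + r1 + r2
            fp = 2.0 * (r0 / d0 + r1 / d1 + r2 / d2)
            step = (f - 1.0) / fp
            t += step
            if step.max() < 1e-14 * (1.0 + t.max()):
                break
        proj[out] = np.column_stack(
            (a0 * xo / (t + a0), a1 * yo / (t + a1), a2_ * zo / (t + a2_))
        )
    return proj, inside


def closest_point_on_segments(
    points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray
) -> np.ndarray:
    """Closest point on segment [a, b] to each point (all (N, 3))."""
    ab = seg_b - seg_a
    s = _safe_div(_rowdot(points - seg_a, ab), _rowdot(ab, ab))
    s = np.clip(s, 0.0, 1.0)
    return seg_a + s[:, None] * ab


def _rowdot(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1] + u[:, 2] * v[:, 2]


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return num / np.where(den == 0.0, 1.0, den)


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle (tri: (N, 3, 3)) to each point (N, 3).

    Vectorised form of the standard Voronoi-region case analysis.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = points - a
    d1 = _rowdot(ab, ap)
    d2 = _rowdot(ac, ap)
    bp = points - b
    d3 = _rowdot(ab, bp)
    d4 = _rowdot(ac, bp)
    cp = points - c
    d5 = _rowdot(ab, cp)
    d6 = _rowdot(ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    v_ab = _safe_div(d1, d1 - d3)
    w_ac = _safe_div(d2, d2 - d6)
    w_bc = _safe_div(d4 - d3, (d4 - d3) + (d5 - d6))
    denom = va + vb + vc
    v_in = _safe_div(vb, denom)
    w_in = _safe_div(vc, denom)

    result = a + v_in[:, None] * ab + w_in[:, None] * ac
    undecided = np.ones(len(points), dtype=bool)

    def assign(mask, value):
        nonlocal undecided
        m = mask & undecided
        if np.any(m):
            result[m] = value[m]
        undecided &= ~m

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    assign(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
        b + w_bc[:, None] * (c - b),
    )
    return result


def alternating_projection_distance(
    project_onto_primitive,
    start_points: np.ndarray,
    semi_axes: np.ndarray,
    max_iterations: int = 400,
    tolerance: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Minimum distance between each convex primitive and the solid ellipsoid.

    ``project_onto_primitive(points, idx) -> points`` maps arbitrary points
    to the closest point on the primitive with batch index ``idx``;
    ``start_points`` is the initial iterate on each primitive (a good start
    is the primitive point closest to the ellipsoid centre).  Returns
    ``(distance, contained, on_primitive, on_ellipsoid)`` with distance 0
    wherever the primitive touches or enters the ellipsoid.  Converged
    problems are dropped from the working set as the iteration proceeds.
    """
    x = np.atleast_2d(np.asarray(start_points, dtype=float)).copy()
    n = len(x)
    y = np.empty_like(x)
    contained = np.zeros(n, dtype=bool)

    idx = np.arange(n)
    xa = x[idx]
    ya, inside = project_points_to_ellipsoid(xa, semi_axes)
    y[idx] = ya
    contained[idx[inside]] = True
    y[idx[inside]] = x[idx[inside]]
    idx = idx[~inside]
    not_converged = 0
    for _ in range(max_iterations):
        if len(idx) == 0:
            break
        xa_new = project_onto_primitive(y[idx], idx)
        steps = np.linalg.norm(xa_new - x[idx], axis=1)
        x[idx] = xa_new
        ya, inside = project_points_to_ellipsoid(xa_new, semi_axes)
        y[idx] = ya
        newly_in = idx[inside]
        contained[newly_in] = True
        y[newly_in] = x[newly_in]
        idx = idx[(steps >= tolerance) & ~inside]
    else:
        not_converged = len(idx)
    if not_converged:
        # the distance value converges roughly quadratically faster than the
        # iterate itself, so a small point residual is still a tight value
        residual = float(
            np.max(np.linalg.norm(x[idx] - project_onto_primitive(y[idx], idx), axis=1))
        )
        if residual > 1e-4:
            warnings.warn(
                f"ellipsoid distance iteration did not fully converge "
                f"(residual {residual:.2e} m)",
                RuntimeWarning,
                stacklevel=2,
            )
    dist = np.linalg.norm(x - y, axis=1)
    dist[contained] = 0.0
    return dist, contained, x, y


def segments_to_ellipsoid_distances(
    seg_a: np.ndarray, seg_b: np.ndarray, semi_axes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batch segment-to-ellipsoid distances in the ellipsoid body frame."""
    seg_a = np.atleast_2d(np.asarray(seg_a, dtype=float))
    seg_b = np.atleast_2d(np.asarray(seg_b, dtype=float))

    def project(points, idx):
        return closest_point_on_segments(points, seg_a[idx], seg_b[idx])

    start = project(np.zeros_like(seg_a), np.arange(len(seg_a)))
    return alternating_projection_distance(project, start, semi_axes)


def triangles_to_ellipsoid_distances(
    triangles: np.ndarray, semi_axes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batch triangle-to-ellipsoid distances in the ellipsoid body frame."""
    tri = np.asarray(triangles, dtype=float)

    def project(points, idx):
        return closest_point_on_triangles(points, tri[idx])

    start = project(np.zeros((len(tri), 3)), np.arange(len(tri)))
    return alternating_projection_distance(project, start, semi_axes)


def point_in_closed_mesh(point: np.ndarray, triangles: np.ndarray) -> bool:
    """Ray-crossing parity test for a point against a closed triangle mesh.

    Casts a single ray in a fixed oblique direction (chosen to avoid edge
    and vertex grazing for meshes in general position) and counts
    Moller-Trumbore intersections; an odd count means inside.
    """
    p = np.asarray(point, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    direction = np.array([0.579845246987, 0.664723867352, 0.470912377103])
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(direction, e2)
    det = _rowdot(e1, h)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, det, 1.0)
    s = p - tri[:, 0]
    u = _rowdot(s, h) / inv
    q = np.cross(s, e1)
    v = (q @ direction) / inv
    t = _rowdot(e2, q) / inv
    hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
    return bool(np.sum(hits) % 2 == 1)


def _drop_degenerate_triangles(triangles: np.ndarray) -> tuple[np.ndarray, int]:
    e1 = triangles[:, 1] - triangles[:, 0]
    e2 = triangles[:, 2] - triangles[:, 0]
    area2 = np.linalg.norm(np.cross(e1, e2), axis=1)
    good = area2 > 1e-14
    return triangles[good], int(np.sum(~good))


# ---------------------------------------------------------------------------
# public scalar queries (arbitrary poses)
# ---------------------------------------------------------------------------


def _to_ellipsoid_frame(points: np.ndarray, e: EllipsoidShape) -> np.ndarray:
    return e.pose.inverse().apply(points)


def point_to_ellipsoid_distance(point, e: EllipsoidShape) -> DistanceQuery:
    """Distance from a point to the ellipsoid surface (0 inside, flagged)."""
    p_body = _to_ellipsoid_frame(_as_vec3(point, "point"), e)
    proj, inside = project_points_to_ellipsoid(p_body[None, :], e.semi_axes)
    on_surface = e.pose.apply(proj[0])
    dist = 0.0 if inside[0] else float(np.linalg.norm(proj[0] - p_body))
    return DistanceQuery(dist, bool(inside[0]), np.asarray(point, float), on_surface)


def segment_to_ellipsoid_distance(c: CapsuleShape, e: EllipsoidShape) -> DistanceQuery:
    """Minimum distance between a capsule and the ellipsoid surface.

    The capsule radius is subtracted from the segment-to-ellipsoid distance
    and the result clamped at zero, so overlap reports 0.
    """
    inv = e.pose.inverse()
    a = inv.apply(c.endpoint_a)[None, :]
    b = inv.apply(c.endpoint_b)[None, :]
    dist, contained, on_seg, on_ell = segments_to_ellipsoid_distances(
        a, b, e.semi_axes
    )
    d = max(float(dist[0]) - c.radius, 0.0)
    touching = bool(contained[0]) or d == 0.0
    p_seg_world = e.pose.apply(on_seg[0])
    p_ell_world = e.pose.apply(on_ell[0])
    if not touching and dist[0] > 0:
        # move the segment point outward to the capsule surface
        direction = (p_ell_world - p_seg_world) / dist[0]
        p_seg_world = p_seg_world + c.radius * direction
    return DistanceQuery(d, bool(contained[0]), p_seg_world, p_ell_world)


def mesh_to_ellipsoid_distance(k: KiteSurface, e: EllipsoidShape) -> DistanceQuery:
    """Minimum distance between a posed triangulated surface and the ellipsoid."""
    inv = e.pose.inverse()
    tri_world = k.world_triangles
    tri_body = inv.apply(tri_world.reshape(-1, 3)).reshape(tri_world.shape)
    tri_body, n_degenerate = _drop_degenerate_triangles(tri_body)
    if n_degenerate:
        warnings.warn(
            f"skipped {n_degenerate} degenerate triangle(s)", RuntimeWarning
        )
    if len(tri_body) == 0:
        raise ValueError("mesh has no non-degenerate triangles")
    dist, contained, on_tri, on_ell = triangles_to_ellipsoid_distances(
        tri_body, e.semi_axes
    )
    i = int(np.argmin(dist))
    d = float(dist[i])
    is_contained = bool(contained[i]) or d == 0.0
    if d > 0.0:
        # ellipsoid could still sit entirely inside a closed mesh
        centre_in_mesh_frame = k.pose.inverse().apply(e.pose.translation)
        if k.mesh.is_watertight and point_in_closed_mesh(
            centre_in_mesh_frame, k.body_triangles
        ):
            d = 0.0
            is_contained = True
    return DistanceQuery(
        d, is_contained, e.pose.apply(on_tri[i]), e.pose.apply(on_ell[i])
    )
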