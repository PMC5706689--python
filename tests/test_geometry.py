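"""Distance-query correctness: closed forms, frozen oracle values, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tidalkite.geometry import (
    CapsuleShape,
    EllipsoidShape,
    KiteSurface,
    RigidTransform,
    build_kite_surface,
    mesh_to_ellipsoid_distance,
    point_to_ellipsoid_distance,
    segment_to_ellipsoid_distance,
    _drop_degenerate_triangles,
)


def random_pose(rng) -> RigidTransform:
    rot = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
    return RigidTransform(rot, rng.uniform(-2, 2, 3))


class TestPointDistance:
    def test_sphere_reduces_to_radius_arithmetic(self):
        sphere = EllipsoidShape(2.0, 2.0)
        q = point_to_ellipsoid_distance([5.0, 0.0, 0.0], sphere)
        assert q.distance == pytest.approx(3.0, abs=1e-12)
        assert not q.contained

    def test_center_is_contained_with_zero_distance(self):
        e = EllipsoidShape(2.0, 1.0)
        q = point_to_ellipsoid_distance([0.0, 0.0, 0.0], e)
        assert q.distance == 0.0
        assert q.contained

    def test_generic_point_matches_surface_minimisation_oracle(self):
        # frozen value from dense sampling + simplex polish over the
        # parametrised surface of the (2, 1, 1) ellipsoid
        q = point_to_ellipsoid_distance([3.0, 1.0, 0.5], EllipsoidShape(2.0, 1.0))
        assert q.distance == pytest.approx(1.3629378479, abs=1e-4)

    def test_rejects_non_finite_input(self):
        with pytest.raises(ValueError):
            point_to_ellipsoid_distance([np.nan, 0, 0], EllipsoidShape(1, 1))


class TestSegmentDistance:
    def test_far_collinear_segment(self):
        # closest endpoint 4 m from the centre of a unit sphere, radius 0
        c = CapsuleShape([4.0, 0.0, 0.0], [9.0, 0.0, 0.0], 0.0)
        q = segment_to_ellipsoid_distance(c, EllipsoidShape(1.0, 1.0))
        assert q.distance == pytest.approx(3.0, abs=1e-10)

    def test_segment_through_center_overlaps(self):
        c = CapsuleShape([-5.0, 0.0, 0.0], [5.0, 0.0, 0.0], 0.0)
        q = segment_to_ellipsoid_distance(c, EllipsoidShape(2.0, 0.94))
        assert q.distance == 0.0

    def test_generic_oblique_segment_matches_grid_search_oracle(self):
        # frozen value from the (segment parameter x surface) search oracle
        c = CapsuleShape([3.0, -2.0, 1.0], [1.0, 3.0, 2.0], 0.0)
        q = segment_to_ellipsoid_distance(c, EllipsoidShape(2.0, 0.94))
        assert q.distance == pytest.approx(1.0256342138, abs=1e-4)

    def test_capsule_radius_is_subtracted_and_clamped(self):
        e = EllipsoidShape(1.0, 1.0)
        near = CapsuleShape([3.0, 0.0, 0.0], [3.0, 5.0, 0.0], 0.5)
        assert segment_to_ellipsoid_distance(near, e).distance == pytest.approx(1.5, abs=1e-10)
        overlapping = CapsuleShape([1.5, 0.0, 0.0], [1.5, 5.0, 0.0], 1.0)
        assert segment_to_ellipsoid_distance(overlapping, e).distance == 0.0

    def test_sphere_specialization_matches_closed_form(self, rng):
        # equal semi-axes: distance must equal point-segment distance minus
        # both radii, clamped at zero
        for _ in range(50):
            radius = rng.uniform(0.2, 2.0)
            center = rng.uniform(-3, 3, 3)
            sphere = EllipsoidShape(radius, radius, RigidTransform.from_translation(center))
            a, b = rng.uniform(-5, 5, 3), rng.uniform(-5, 5, 3)
            cap_r = rng.uniform(0.0, 0.5)
            cap = CapsuleShape(a, b, cap_r)
            ab = b - a
            s = np.clip((center - a) @ ab / (ab @ ab), 0.0, 1.0)
            expected = max(np.linalg.norm(center - (a + s * ab)) - radius - cap_r, 0.0)
            got = segment_to_ellipsoid_distance(cap, sphere).distance
            assert got == pytest.approx(expected, abs=1e-9)


class TestMeshDistance:
    def test_sphere_to_flat_plate_gap(self):
        plate = KiteSurface(2.0, 0.5, 0.5, RigidTransform.from_translation([5.25, 0, 0]))
        # chord extent 0.5 puts the nearest face at x = 5; unit sphere -> gap 4
        q = mesh_to_ellipsoid_distance(plate, EllipsoidShape(1.0, 1.0))
        assert q.distance == pytest.approx(4.0, abs=1e-10)

    def test_intersecting_surface_reports_zero(self):
        plate = KiteSurface(3.0, 0.75, 0.15, RigidTransform.from_translation([0.5, 0, 0]))
        q = mesh_to_ellipsoid_distance(plate, EllipsoidShape(1.0, 0.8))
        assert q.distance == 0.0
        assert q.contained

    def test_ellipsoid_inside_closed_mesh_reports_containment(self):
        box = KiteSurface(4.0, 4.0, 4.0)
        q = mesh_to_ellipsoid_distance(box, EllipsoidShape(0.5, 0.3))
        assert q.distance == 0.0
        assert q.contained

    def test_degenerate_triangles_are_dropped(self):
        tri = np.array(
            [
                [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                [[0, 0, 0], [1, 0, 0], [2, 0, 0]],  # collinear
            ],
            dtype=float,
        )
        kept, n_dropped = _drop_degenerate_triangles(tri)
        assert len(kept) == 1
        assert n_dropped == 1


class TestKiteSurfaceConstruction:
    def test_bounding_box_matches_dimensions(self):
        k = build_kite_surface(3.0, 0.75, 0.15)
        extents = k.mesh.bounds[1] - k.mesh.bounds[0]
        assert extents == pytest.approx([0.75, 3.0, 0.15])  # chord, span, thickness

    def test_unit_cube_is_closed(self):
        k = build_kite_surface(1.0, 1.0, 1.0)
        assert len(k.body_triangles) >= 12
        assert k.is_watertight

    def test_surface_area_bounded_below_by_two_faces(self):
        k = build_kite_surface(3.0, 0.75, 0.15)
        assert k.surface_area >= 2 * 3.0 * 0.75

    @pytest.mark.parametrize("dims", [(0, 1, 1), (1, -2, 1), (1, 1, 0)])
    def test_non_positive_dimension_rejected(self, dims):
        with pytest.raises(ValueError):
            build_kite_surface(*dims)


class TestInvariances:
    def test_rigid_invariance_of_all_distances(self, rng):
        """Moving both shapes by the same rigid motion leaves distances fixed."""
        e = EllipsoidShape(1.4, 0.6, random_pose(rng))
        cap = CapsuleShape(rng.uniform(-4, 4, 3), rng.uniform(-4, 4, 3), 0.1)
        kite = KiteSurface(2.0, 0.6, 0.2, random_pose(rng))
        p = rng.uniform(-4, 4, 3)
        for _ in range(10):
            g = random_pose(rng)
            e2 = EllipsoidShape(1.4, 0.6, g.compose(e.pose))
            cap2 = CapsuleShape(g.apply(cap.endpoint_a), g.apply(cap.endpoint_b), 0.1)
            kite2 = kite.posed(g.compose(kite.pose))
            p2 = g.apply(p)
            assert point_to_ellipsoid_distance(p2, e2).distance == pytest.approx(
                point_to_ellipsoid_distance(p, e).distance, abs=1e-9
            )
            assert segment_to_ellipsoid_distance(cap2, e2).distance == pytest.approx(
                segment_to_ellipsoid_distance(cap, e).distance, abs=1e-9
            )
            assert mesh_to_ellipsoid_distance(kite2, e2).distance == pytest.approx(
                mesh_to_ellipsoid_distance(kite, e).distance, abs=1e-9
            )

    def test_distances_non_negative_and_zero_iff_touching(self, rng):
        e = EllipsoidShape(1.0, 0.5)
        for _ in range(50):
            cap = CapsuleShape(rng.uniform(-2, 2, 3), rng.uniform(-2, 2, 3), rng.uniform(0, 0.3))
            q = segment_to_ellipsoid_distance(cap, e)
            assert q.distance >= 0.0
            # when strictly positive the reported pair realises the distance
            if q.distance > 0:
                gap = np.linalg.norm(q.point_on_shape - q.point_on_ellipsoid)
                assert gap == pytest.approx(q.distance, rel=1e-6)

    finite = st.floats(-10.0, 10.0, allow_nan=False)
    axis = st.floats(0.1, 5.0, allow_nan=False)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(px=finite, py=finite, pz=finite, a=axis, b=axis)
    def test_point_projection_lands_on_surface(self, px, py, pz, a, b):
        """The projected point of any exterior query lies on the ellipsoid
        and realises the reported distance."""
        e = EllipsoidShape(a, b)
        q = point_to_ellipsoid_distance([px, py, pz], e)
        assert q.distance >= 0.0
        if not q.contained:
            on = q.point_on_ellipsoid
            level = (on[0] / a) ** 2 + (on[1] / b) ** 2 + (on[2] / b) ** 2
            assert level == pytest.approx(1.0, abs=1e-9)
            assert np.linalg.norm(on - np.array([px, py, pz])) == pytest.approx(
                q.distance, abs=1e-9
            )

    def test_rotation_validation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        reflection = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            RigidTransform(reflection, np.zeros(3))
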