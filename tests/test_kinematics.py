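"""Flight-path angles, pose composition and animal translation."""

import numpy as np
import pytest

from tidalkite import (
    AnimalParams,
    ConfigurationError,
    FlightPathParams,
    PhaseLag,
    alpha_heading,
    animal_position,
    attachment_point,
    beta_angle,
    gamma_angle,
    kite_pose,
    phase_lags,
)
from tidalkite.kinematics import KiteState
from tidalkite.geometry import RigidTransform


@pytest.fixture(scope="module")
def flight():
    return FlightPathParams.baseline()


DENSE_T = np.linspace(0.0, 8.0, 4001)


class TestBeta:
    def test_value_at_zero_phase(self, flight):
        # sin term vanishes at t = delta: beta = arccos((H-D)/L)
        assert beta_angle(0.0, 0.0, flight) == pytest.approx(np.arccos(13 / 25), abs=1e-12)

    def test_constant_when_no_vertical_oscillation(self):
        p = FlightPathParams(h=0.0)
        betas = beta_angle(DENSE_T, 0.3, p)
        assert np.ptp(betas) == 0.0

    def test_period_is_half_kite_period(self, flight):
        t = np.linspace(0, 16, 257)
        assert beta_angle(t, 0.1, flight) == pytest.approx(
            beta_angle(t + flight.T / 2, 0.1, flight), abs=1e-12
        )

    def test_unreachable_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            FlightPathParams(D=1.0, H=30.0, tether_length=25.0)  # H-D+h/2 > L


class TestGamma:
    def test_zero_on_center_plane(self, flight):
        beta = beta_angle(0.0, 0.0, flight)
        assert gamma_angle(0.0, 0.0, beta, flight) == 0.0

    def test_period_is_kite_period(self, flight):
        t = np.linspace(0, 8, 97)
        beta = beta_angle(t, 0.0, flight)
        beta_shift = beta_angle(t + flight.T, 0.0, flight)
        assert gamma_angle(t, 0.0, beta, flight) == pytest.approx(
            gamma_angle(t + flight.T, 0.0, beta_shift, flight), abs=1e-12
        )

    def test_max_lateral_excursion_is_half_width(self, flight):
        att = attachment_point(DENSE_T, 0.0, flight)
        assert np.max(att[:, 1]) == pytest.approx(flight.w / 2, abs=1e-3)
        assert np.min(att[:, 1]) == pytest.approx(-flight.w / 2, abs=1e-3)


class TestAttachmentPath:
    def test_attachment_stays_on_tether_sphere(self, flight):
        att = attachment_point(DENSE_T, 1.7, flight)
        assert np.linalg.norm(att, axis=1) == pytest.approx(25.0, abs=1e-9)

    def test_height_extremes(self, flight):
        att = attachment_point(DENSE_T, 0.0, flight)
        assert np.max(att[:, 2]) == pytest.approx(flight.mean_height + flight.h / 2, abs=1e-4)
        assert np.min(att[:, 2]) == pytest.approx(flight.mean_height - flight.h / 2, abs=1e-4)

    def test_figure_of_eight_crossings(self, flight):
        """Two centre-line crossings per period, both at the node height."""
        att = attachment_point(DENSE_T[:-1], 0.0, flight)
        sign_changes = np.flatnonzero(np.diff(np.signbit(att[:, 1])))
        # dense grid starts exactly on a crossing (y(0) = 0)
        n_crossings = len(sign_changes) + 1
        assert n_crossings == 2
        crossing_heights = att[sign_changes, 2]
        assert crossing_heights == pytest.approx(flight.mean_height, abs=1e-2)

    def test_mirror_symmetry_under_half_period_shift(self, flight):
        att = attachment_point(DENSE_T, 0.0, flight)
        att_shift = attachment_point(DENSE_T + flight.T / 2, 0.0, flight)
        assert att_shift[:, 0] == pytest.approx(att[:, 0], abs=1e-9)
        assert att_shift[:, 1] == pytest.approx(-att[:, 1], abs=1e-9)
        assert att_shift[:, 2] == pytest.approx(att[:, 2], abs=1e-9)


def _state(t, att, alpha=0.0):
    return KiteState(
        t=t, alpha=alpha, beta=0.0, gamma=0.0,
        pose=RigidTransform.from_translation(att),
    )


class TestAlphaHeading:
    def test_chord_follows_pure_lateral_motion(self, flight):
        """Attachment moving purely in +y gives a chord along +y."""
        att = np.array([0.0, 0.0, 25.0])
        prev = _state(0.0, att - np.array([0.0, 0.1, 0.0]))
        cur = _state(0.1, att)
        alpha = alpha_heading(prev, cur)
        # on the vertical axis the heading reference is +x, so +y is +pi/2
        assert alpha == pytest.approx(np.pi / 2, abs=1e-9)

    def test_stationary_path_keeps_previous_heading(self):
        att = np.array([3.0, 0.0, 24.0])
        prev = _state(0.0, att, alpha=0.7)
        cur = _state(0.1, att, alpha=0.7)
        assert alpha_heading(prev, cur) == 0.7

    def test_uniform_circular_motion_gives_uniform_heading_steps(self):
        """Attachment on a horizontal circle at constant polar angle: the
        heading relative to the local frame is the same at every step."""
        beta = 0.6
        r, z = 25 * np.sin(beta), 25 * np.cos(beta)
        phis = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        att = np.column_stack([r * np.cos(phis), r * np.sin(phis), np.full_like(phis, z)])
        alphas = [
            alpha_heading(_state(i - 1, att[i - 1]), _state(i, att[i]))
            for i in range(1, len(att))
        ]
        increments = np.diff(alphas)
        assert increments == pytest.approx(np.zeros_like(increments), abs=1e-9)


class TestKitePose:
    def test_zero_phase_pose_is_centered_at_mean_height(self, flight):
        state = kite_pose(0.0, 0.0, flight)
        assert state.gamma == 0.0
        att = state.attachment_point
        assert att[1] == pytest.approx(0.0, abs=1e-12)
        assert att[2] == pytest.approx(13.0, abs=1e-12)  # H - D above seabed

    def test_pose_is_periodic(self, flight):
        for t in (0.7, 2.3, 5.1):
            s1 = kite_pose(t, 0.4, flight)
            s2 = kite_pose(t + flight.T, 0.4, flight)
            assert s2.attachment_point == pytest.approx(s1.attachment_point, abs=1e-6)
            assert s2.pose.rotation == pytest.approx(s1.pose.rotation, abs=1e-6)

    def test_attachment_norm_equals_tether_length(self, flight):
        for t in np.linspace(0, 8, 33):
            state = kite_pose(float(t), 1.1, flight)
            assert np.linalg.norm(state.attachment_point) == pytest.approx(25.0, abs=1e-9)

    def test_rotation_is_proper_orthonormal(self, flight):
        state = kite_pose(1.9, 0.25, flight)
        rot = state.pose.rotation
        assert rot @ rot.T == pytest.approx(np.eye(3), abs=1e-12)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-12)


class TestAnimal:
    def test_starts_at_initial_cross_section_position(self):
        a = AnimalParams(y0=-2.0, z0=5.0)
        assert animal_position(0.0, a) == pytest.approx([0.0, -2.0, 5.0])

    def test_linear_translation(self):
        a = AnimalParams(L=1.41, v=1.8)
        assert animal_position(10.0, a)[0] == pytest.approx(18.0)
        xs = animal_position(np.arange(5) * 0.5, a)[:, 0]
        assert np.diff(xs) == pytest.approx(np.full(4, 0.9))

    def test_ellipsoid_radii_derived_from_length(self):
        a = AnimalParams(L=1.410)
        assert a.semi_axis_major == pytest.approx(0.705)
        assert a.semi_axis_minor == pytest.approx(0.470)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            AnimalParams(L=-1.0)
        with pytest.raises(ConfigurationError):
            AnimalParams(v=0.0)


class TestPhaseLags:
    def test_even_spacing_over_period(self):
        lags = phase_lags(8.0, 50)
        assert len(lags) == 50
        assert np.diff(lags) == pytest.approx(np.full(49, 8.0 / 50))
        assert lags[0] == 0.0
        assert lags[-1] < 8.0

    def test_phase_lag_bounds(self):
        PhaseLag(0.0, 8.0)
        with pytest.raises(ConfigurationError):
            PhaseLag(8.0, 8.0)
        with pytest.raises(ConfigurationError):
            PhaseLag(-0.1, 8.0)
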