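import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memscaffold.geometry import (
    ModelParameters,
    OverlapError,
    PairConfiguration,
    ScaffoldShape,
    contact_angle,
    place_pair,
    preset,
    rim_samples,
    surface_height,
)
from memscaffold.geometry import surface_normal, _rim_at


class TestScaffoldShape:
    def test_validation_rejects_bad_radii(self):
        with pytest.raises(ValueError):
            ScaffoldShape(rho_a=5, rho_b=5, r_a=-1, r_b=1)
        with pytest.raises(ValueError):
            ScaffoldShape(rho_a=1, rho_b=5, r_a=1, r_b=1)   # r_a == rho_a
        with pytest.raises(ValueError):
            ScaffoldShape(rho_a=5, rho_b=0.5, r_a=1, r_b=1)  # r_b > |rho_b|

    def test_derived_curvatures_and_angles(self):
        s = ScaffoldShape.shallow_circular(0.75)
        assert s.c_a == pytest.approx(0.2)
        assert s.c_b == pytest.approx(0.15)
        assert s.phi_a == pytest.approx(np.degrees(np.arcsin(0.2)))
        # cylinder limit: c_b = 0, contact angle 0 on the short axis
        cyl = ScaffoldShape.shallow_circular(0.0)
        assert cyl.c_b == 0.0
        assert cyl.phi_b == 0.0

    def test_bar_preset(self):
        s = preset("endophilin_nbar")
        assert s.units == "nm"
        assert (s.r_a, s.r_b, s.rho_a) == (6.5, 1.5, 8.5)
        assert s.phi_a == pytest.approx(np.degrees(np.arcsin(6.5 / 8.5)), abs=1e-9)

    def test_spherical_cap_area_matches_closed_form(self):
        # A = 2 pi rho^2 (1 - cos phi_a) for a spherical cap
        s = ScaffoldShape.shallow_circular(1.0)
        phi = np.arcsin(s.r_a / s.rho_a)
        exact = 2 * np.pi * s.rho_a ** 2 * (1 - np.cos(phi))
        assert s.A == pytest.approx(exact, rel=1e-4)


class TestSurfaceHeight:
    def test_apex_is_reference(self, shallow_iso):
        assert surface_height(shallow_iso, 0.0, 0.0) == pytest.approx(0.0)

    def test_spherical_drop_matches_closed_form(self):
        s = ScaffoldShape(rho_a=5.0, rho_b=5.0, r_a=1.0, r_b=1.0)
        # sphere: z = sqrt(rho^2 - x^2 - y^2) - rho; drop below apex 5 - sqrt(24)
        assert surface_height(s, 1.0, 0.0) == pytest.approx(-(5.0 - np.sqrt(24.0)))

    def test_saddle_signs(self, shallow_saddle):
        # principal curvature +1/rho along x (falls), -1/rho along y (rises)
        assert surface_height(shallow_saddle, 0.5, 0.0) < 0
        assert surface_height(shallow_saddle, 0.0, 0.5) > 0

    def test_outside_footprint_rejected(self, shallow_iso):
        with pytest.raises(ValueError):
            surface_height(shallow_iso, 1.5, 0.0)

    def test_cylinder_flat_along_y(self):
        cyl = ScaffoldShape.shallow_circular(0.0)
        assert surface_height(cyl, 0.0, 0.9) == pytest.approx(0.0)


class TestContactAngle:
    def test_isotropic_cap_constant_and_exact(self, shallow_iso):
        az = np.linspace(0, 360, 13)
        ang = contact_angle(shallow_iso, az)
        expect = np.degrees(np.arcsin(0.2))
        assert np.allclose(ang, expect, atol=1e-10)

    def test_bar_long_axis_value(self):
        s = preset("endophilin_nbar")
        assert contact_angle(s, 0.0) == pytest.approx(
            np.degrees(np.arcsin(6.5 / 8.5)), abs=1e-9)

    def test_extremes_on_axes(self):
        s = preset("endophilin_nbar")
        az = np.linspace(0, 90, 31)
        ang = contact_angle(s, az)
        assert ang[0] == max(ang)
        assert ang[-1] == min(ang)

    @given(ratio=st.floats(min_value=0.02, max_value=0.9))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_r_over_rho_for_caps(self, ratio):
        s = ScaffoldShape(rho_a=1.0 / ratio, rho_b=1.0 / ratio, r_a=1.0, r_b=1.0)
        assert contact_angle(s, 17.0) == pytest.approx(
            np.degrees(np.arcsin(ratio)), rel=1e-9)


class TestRimSamples:
    def test_loop_on_both_surfaces(self, shallow_saddle):
        pts, nrm, t = rim_samples(shallow_saddle, 48)
        s = shallow_saddle
        # footprint residual
        res_fp = (pts[:, 0] / s.r_a) ** 2 + (pts[:, 1] / s.r_b) ** 2 - 1.0
        assert np.abs(res_fp).max() < 1e-10
        # quadric residual
        res_q = ((pts[:, 0] / s.rho_a) ** 2
                 - (pts[:, 1] / s.rho_b) ** 2
                 + ((pts[:, 2] + s.rho_a) / s.rho_a) ** 2 - 1.0)
        assert np.abs(res_q).max() < 1e-10

    def test_minimum_count_enforced(self, shallow_iso):
        with pytest.raises(ValueError):
            rim_samples(shallow_iso, 8)

    def test_axis_points_present(self):
        s = preset("endophilin_nbar")
        pts, _, t = rim_samples(s, 12)
        assert np.allclose(pts[0, :2], [s.r_a, 0.0], atol=1e-12)
        i90 = int(np.argmin(np.abs(t - np.pi / 2)))
        assert np.allclose(pts[i90, :2], [0.0, s.r_b], atol=1e-12)

    def test_normals_match_finite_differences(self, shallow_saddle):
        s = shallow_saddle
        t = np.linspace(0.1, 2 * np.pi, 17)
        x, y = 0.9 * s.r_a * np.cos(t), 0.9 * s.r_b * np.sin(t)
        n = surface_normal(s, x, y)
        eps = 1e-6
        gx = (surface_height(s, x + eps, y) - surface_height(s, x - eps, y)) / (2 * eps)
        gy = (surface_height(s, x, y + eps) - surface_height(s, x, y - eps)) / (2 * eps)
        n_fd = np.c_[-gx, -gy, np.ones_like(gx)]
        n_fd /= np.linalg.norm(n_fd, axis=1, keepdims=True)
        assert np.abs(n - n_fd).max() < 1e-6


class TestPlacement:
    def test_pure_translation_at_zero_angles(self, shallow_iso):
        T1, T2 = place_pair(shallow_iso, PairConfiguration(d=4.0))
        assert np.allclose(T1.R, np.eye(3))
        assert np.allclose(T2.R, np.eye(3))
        assert np.allclose(T1.t, [-2, 0, 0])
        assert np.allclose(T2.t, [2, 0, 0])

    @given(phi=st.floats(0, 90), theta=st.floats(-30, 60),
           d=st.floats(3.0, 12.0))
    @settings(max_examples=25, deadline=None)
    def test_rigid_body_distances_preserved(self, phi, theta, d):
        s = ScaffoldShape.shallow_circular(0.75)
        cfg = PairConfiguration(d=d, phi=phi, theta=theta)
        T1, T2 = place_pair(s, cfg)
        pts, _, _ = rim_samples(s, 16)
        for T in (T1, T2):
            q = T.apply(pts)
            orig = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            new = np.linalg.norm(q[:, None] - q[None, :], axis=-1)
            assert np.abs(orig - new).max() < 1e-9
            assert np.linalg.det(T.R) == pytest.approx(1.0)

    def test_mirror_symmetry(self, shallow_saddle):
        cfg = PairConfiguration(d=5.0, phi=30.0, theta=10.0)
        T1, T2 = place_pair(shallow_saddle, cfg)
        pts, _, t = rim_samples(shallow_saddle, 32)
        q1 = T1.apply(pts)
        q2 = T2.apply(pts)
        q1_mirrored = q1 * np.array([-1.0, 1.0, 1.0])
        # the mirrored rim of scaffold 1 is the rim of scaffold 2 as a set
        d2 = np.linalg.norm(q1_mirrored[:, None] - q2[None, :], axis=-1)
        assert d2.min(axis=1).max() < 1e-9

    def test_phi90_aligns_long_axes_perpendicular_to_line(self):
        s = preset("endophilin_nbar")
        T1, _ = place_pair(s, PairConfiguration(d=30.0, phi=90.0))
        long_axis = T1.apply_vectors(np.array([1.0, 0.0, 0.0]))
        assert abs(long_axis[0]) < 1e-12      # perpendicular to connecting line
        assert abs(long_axis[1]) == pytest.approx(1.0)

    def test_overlap_rejected_with_min_distance(self, shallow_iso):
        with pytest.raises(OverlapError) as err:
            place_pair(shallow_iso, PairConfiguration(d=1.5))
        assert err.value.min_distance > 1.5

    def test_away_tilt_tips_normal_off_partner(self, shallow_iso):
        T1, T2 = place_pair(shallow_iso, PairConfiguration(d=4.0, theta=10.0))
        n1 = T1.apply_vectors(np.array([0.0, 0.0, 1.0]))
        # scaffold 1 sits at -d/2; away tilt has negative x component
        assert n1[0] < 0
        n2 = T2.apply_vectors(np.array([0.0, 0.0, 1.0]))
        assert n2[0] == pytest.approx(-n1[0])


class TestModelParameters:
    def test_defaults(self):
        p = ModelParameters()
        assert p.kappa == 20.0
        assert p.gamma == 0.0
        assert np.isinf(p.xi)

    def test_xi(self):
        p = ModelParameters(gamma=0.002)
        assert p.xi == pytest.approx(np.sqrt(20.0 / 0.002))

    def test_invalid(self):
        with pytest.raises(ValueError):
            ModelParameters(kappa=-1)
        with pytest.raises(ValueError):
            ModelParameters(gamma=-0.1)
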