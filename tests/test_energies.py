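"""Interaction-energy assembly, tested against closed-form orientation
landscapes (fast, no mesh solves) plus synthetic curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memscaffold.energies import (
    EnergyLandscape,
    InteractionCurve,
    _boltzmann_theta_integral,
    _theta_line_min,
    _theta_window_samples,
    fit_power_law,
    free_energy,
    optimal_orientation,
)
from memscaffold.geometry import ModelParameters, ScaffoldShape


def quadratic_landscape(shape, d, k_phi=0.002, k_th=0.5, phi0=60.0, th0=1.5,
                        F0=2.0):
    """Analytic F_m(phi, theta) with a unique interior minimum."""
    def evaluator(phi, theta, _d):
        return F0 + k_phi * (phi - phi0) ** 2 + k_th * (theta - th0) ** 2
    return EnergyLandscape(shape, d, ModelParameters(), evaluator=evaluator)


@pytest.fixture(scope="module")
def aniso_shape():
    return ScaffoldShape.shallow_circular(0.75)


class TestOptimalOrientation:
    def test_recovers_analytic_minimum(self, aniso_shape):
        ls = quadratic_landscape(aniso_shape, 5.0)
        phi, th, F, _ = optimal_orientation(
            aniso_shape, 5.0, ModelParameters(), landscape=ls,
            phi_grid=[0.0, 30.0, 60.0, 90.0], theta_grid=[-2.0, 0.0, 2.0, 6.0])
        assert phi == pytest.approx(60.0, abs=8.0)
        assert th == pytest.approx(1.5, abs=0.15)
        assert F == pytest.approx(2.0, abs=0.05)

    def test_tie_breaks_toward_smaller_angles(self, aniso_shape):
        flat = EnergyLandscape(aniso_shape, 5.0, ModelParameters(),
                               evaluator=lambda p, t, d: 1.0)
        phi, th, F, _ = optimal_orientation(
            aniso_shape, 5.0, ModelParameters(), landscape=flat,
            phi_grid=[0.0, 45.0, 90.0], theta_grid=[0.0, 5.0])
        assert phi == 0.0
        assert th == 0.0

    def test_theta_line_min_subdegree(self, aniso_shape):
        ls = quadratic_landscape(aniso_shape, 5.0, th0=0.73)
        t, F = _theta_line_min(ls, 60.0, 0.0, 1.0)
        assert t == pytest.approx(0.73, abs=0.08)


class TestThetaWindow:
    def test_window_spans_4kbt(self, aniso_shape):
        ls = quadratic_landscape(aniso_shape, 5.0, k_th=1.0, th0=0.0, F0=0.0)
        ts, Fs = _theta_window_samples(ls, 60.0, 0.0, 4.0)
        # window should reach past F = 4 on both sides: theta ~ +-2 deg
        assert Fs.max() >= 4.0
        assert ts.min() <= -1.8 and ts.max() >= 1.8

    def test_gaussian_integral_recovered(self, aniso_shape):
        # exp(-k t^2) integral in radians: sqrt(pi/k) with t in degrees
        k = 0.8
        ls = quadratic_landscape(aniso_shape, 5.0, k_phi=0.0, k_th=k, th0=20.0,
                                 F0=0.0)
        ts, Fs = _theta_window_samples(ls, 45.0, 20.0, 4.0)
        integral, Fmin = _boltzmann_theta_integral(ts, Fs, 4.0)
        exact = np.sqrt(np.pi / k) * np.pi / 180.0   # degrees -> radians
        assert Fmin == pytest.approx(0.0, abs=1e-9)
        assert integral == pytest.approx(exact, rel=0.02)


class TestFreeEnergy:
    def test_logZ_gaussian_product(self, aniso_shape):
        # separable quadratic landscape: Z = Z_phi * Z_theta in radians
        k_phi, k_th = 0.004, 0.9
        ls = quadratic_landscape(aniso_shape, 6.0, k_phi=k_phi, k_th=k_th,
                                 phi0=45.0, th0=0.0, F0=1.25)
        logZ, diag = free_energy(aniso_shape, 6.0, ModelParameters(),
                                 landscape=ls, phi_star=45.0, theta_star=0.0,
                                 n_phi=9)
        deg2rad = np.pi / 180.0
        Z_phi = np.sqrt(np.pi / k_phi) * deg2rad      # wide but covered by (0,90)
        Z_th = np.sqrt(np.pi / k_th) * deg2rad
        assert logZ == pytest.approx(np.log(Z_phi * Z_th) - 1.25, abs=0.08)

    def test_entropy_difference_of_two_widths(self, aniso_shape):
        # narrower angular well at small d => lower entropy => F_ent > 0
        params = ModelParameters()
        # phi wells centered mid-range, wide enough for the quadrature but
        # narrow enough that the (0, 90) truncation is negligible
        wide = quadratic_landscape(aniso_shape, 10.0, k_phi=0.002, k_th=0.3,
                                   phi0=45.0, F0=0.0, th0=0.0)
        narrow = quadratic_landscape(aniso_shape, 3.0, k_phi=0.008, k_th=1.2,
                                     phi0=45.0, F0=0.0, th0=0.0)
        lz_wide, _ = free_energy(aniso_shape, 10.0, params, landscape=wide,
                                 phi_star=45.0, theta_star=0.0, n_phi=15)
        lz_narrow, _ = free_energy(aniso_shape, 3.0, params, landscape=narrow,
                                   phi_star=45.0, theta_star=0.0, n_phi=15)
        F = -(lz_narrow - lz_wide)       # free energy at d=3 relative to d=10
        F_el = 0.0                       # same minimum energy by construction
        F_ent = F - F_el
        # analytic: kT/2 * log(k ratio product) = 0.5*log(4*4)
        assert F_ent == pytest.approx(0.5 * np.log(16.0), abs=0.08)


class TestFitPowerLaw:
    def test_synthetic_cubic(self):
        d = np.geomspace(4, 20, 8)
        curve = InteractionCurve(d=d, F_el=2.7 / d ** 3,
                                 phi_star=np.zeros(8), theta_star=np.zeros(8),
                                 d_ref=40.0, F_min_ref=0.0)
        slope, err = fit_power_law(curve)
        assert slope == pytest.approx(-3.0, abs=0.01)

    @given(p=st.floats(min_value=1.0, max_value=6.0),
           c=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_recovers_exponent_attractive_or_repulsive(self, p, c):
        d = np.geomspace(5, 15, 6)
        for sign in (+1, -1):
            slope, _ = fit_power_law((d, sign * c * d ** (-p)))
            assert slope == pytest.approx(-p, abs=1e-8)

    def test_sign_change_rejected(self):
        d = np.linspace(2, 8, 6)
        F = np.array([1.0, 0.4, 0.05, -0.08, -0.15, -0.1])
        with pytest.raises(ValueError, match="split the window"):
            fit_power_law((d, F))

    def test_window_selection(self):
        d = np.geomspace(2, 32, 10)
        F = 5.0 / d ** 4 - 1e-4         # contaminated tail outside window
        slope, _ = fit_power_law((d, F), d_window=(2, 8))
        assert slope == pytest.approx(-4.0, abs=0.1)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_power_law((np.array([1.0, 2, 3]), np.array([1.0, 0.2, 0.1])))
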