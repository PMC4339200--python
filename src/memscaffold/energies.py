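"""Interaction energies of the scaffold pair.

Three energies are derived from the minimized membrane energy
F_m(phi, theta, d):

* the *elastic* interaction F_el(d) = F_min(d) - F_min(d_ref), where
  F_min(d) is F_m minimized over the mutual orientation angles (phi in
  [0, 90] deg, theta in [0, 180] deg) and d_ref is a large reference
  separation standing in for infinity;

* the *free energy* F(d) = -kT log Int exp(-F_m(phi, theta, d)/kT) dtheta
  dphi, integrating over the whole orientation range (angles in radians;
  the constant measure drops out of differences).  F_m is sampled inside
  the theta-window where it exceeds the minimum by at most a configurable
  number of k_B T (default 4) and continued quadratically outside, where
  the Boltzmann weight is below e^-4;

* the *orientational-entropy* part F_ent(d) = F(d) - F_el(d), the
  repulsive free-energy component from thermal fluctuations of the
  scaffold orientation (membrane-undulation entropy is out of scope).

Only mirror-symmetric orientations enter the integral, so F_ent is a lower
bound on the total orientational repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import (ModelParameters, OverlapError, PairConfiguration,
                       ScaffoldShape, contact_angle)
from .minimize import MinimizedShape, minimize_configuration

__all__ = [
    "InteractionCurve",
    "FreeEnergyCurve",
    "EnergyLandscape",
    "optimal_orientation",
    "elastic_interaction",
    "free_energy",
    "free_energy_curve",
    "fit_power_law",
]


@dataclass
class InteractionCurve:
    """Orientation-optimized elastic interaction versus distance."""

    d: np.ndarray
    F_el: np.ndarray
    phi_star: np.ndarray
    theta_star: np.ndarray
    d_ref: float
    F_min_ref: float
    fronting_azimuth: np.ndarray = field(default=None)
    diagnostics: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(d=self.d, F_el=self.F_el,
                                 phi_star=self.phi_star,
                                 theta_star=self.theta_star,
                                 fronting_azimuth=self.fronting_azimuth))


@dataclass
class FreeEnergyCurve:
    """Free energy and its entropic part versus distance (both referenced
    to d_ref; F_ent = F - F_el pointwise by construction)."""

    d: np.ndarray
    F: np.ndarray
    F_ent: np.ndarray
    F_el: np.ndarray
    d_ref: float
    diagnostics: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(d=self.d, F=self.F, F_ent=self.F_ent,
                                 F_el=self.F_el))


class EnergyLandscape:
    """Caching evaluator of F_m(phi, theta) at fixed distance.

    Wraps mesh build + relaxation; consecutive evaluations warm-start from
    the nearest previously solved orientation.
    """

    #: tilt bound: beyond max-contact-angle + |tilt| ~ 85 deg the membrane
    #: near the rim overhangs and the height-field discretization is no
    #: longer a valid surface model; such orientations cost far more than
    #: the sampling window anyway and are excluded from the ensemble
    TILT_LIMIT_DEG = 85.0

    def __init__(self, shape: ScaffoldShape, d: float, params: ModelParameters,
                 evaluator: Optional[Callable[[float, float, float], float]] = None):
        self.shape = shape
        self.d = d
        self.params = params
        self._eval = evaluator
        self._cache: dict[tuple[float, float], float] = {}
        self._shapes: dict[tuple[float, float], MinimizedShape] = {}
        az = np.linspace(0.0, 90.0, 19)
        self._max_contact = float(np.max(np.abs(contact_angle(shape, az))))

    def __call__(self, phi: float, theta: float) -> float:
        key = (round(float(phi), 6), round(float(theta), 6))
        if key in self._cache:
            return self._cache[key]
        if self._eval is None and (
                self._max_contact + abs(theta) >= self.TILT_LIMIT_DEG):
            self._cache[key] = np.inf
            return np.inf
        if self._eval is not None:
            F = float(self._eval(phi, theta, self.d))
        else:
            warm = None
            if self._shapes:
                near = min(self._shapes,
                           key=lambda k: (k[0] - phi) ** 2 + (k[1] - theta) ** 2)
                # warm-start only from genuinely neighboring orientations;
                # interpolating a far-away orientation's shape can trap the
                # descent in a spurious minimum
                if abs(near[0] - phi) <= 30.0 and abs(near[1] - theta) <= 20.0:
                    warm = self._shapes[near]
            cfg = PairConfiguration(d=self.d, phi=float(phi), theta=float(theta))
            try:
                ms = minimize_configuration(self.shape, cfg, self.params,
                                            warm_start=warm)
                self._shapes[key] = ms
                F = ms.F_m
            except OverlapError:
                # orientations whose rims would overlap are excluded from
                # the accessible ensemble
                F = np.inf
        self._cache[key] = F
        return F

    @property
    def n_evaluations(self) -> int:
        return len(self._cache)


def _grid_minimum(landscape, phi_grid, theta_grid):
    """Grid scan; ties broken toward smaller phi, then smaller theta."""
    best = (np.inf, np.inf, np.inf)  # (F, phi, theta)
    for phi in phi_grid:
        for theta in theta_grid:
            F = landscape(phi, theta)
            if (F < best[0] - 1e-12 or
                    (abs(F - best[0]) <= 1e-12 and (phi, theta) < (best[1], best[2]))):
                best = (F, phi, theta)
    return best


def _theta_line_min(landscape, phi, theta0, step, lo=-90.0, hi=180.0,
                    max_evals=8, tol=0.05):
    """Sequential parabolic minimization of F_m along theta at fixed phi.

    Sub-degree accuracy in theta matters: the optimal tilt is of order a
    fraction of a degree at large separations, and the energy is steeply
    quadratic around it.
    """
    pts = {}

    def f(t):
        t = float(np.clip(t, lo, hi))
        if t not in pts:
            pts[t] = landscape(phi, t)
        return t, pts[t]

    a, Fa = f(theta0)
    b, Fb = f(theta0 + step)
    c, Fc = f(theta0 - step)
    for _ in range(max_evals):
        ts = sorted(pts)
        i = int(np.argmin([pts[t] for t in ts]))
        if i == 0:
            t_new = ts[0] - (ts[1] - ts[0]) * 2
        elif i == len(ts) - 1:
            t_new = ts[-1] + (ts[-1] - ts[-2]) * 2
        else:
            x0, x1, x2 = ts[i - 1], ts[i], ts[i + 1]
            y0, y1, y2 = pts[x0], pts[x1], pts[x2]
            denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
            if abs(denom) < 1e-30:
                break
            t_new = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2)
                                - (x1 - x2) ** 2 * (y1 - y0)) / denom
        t_new = float(np.clip(t_new, lo, hi))
        if any(abs(t_new - t) < tol for t in pts):
            break
        f(t_new)
    tbest = min(pts, key=lambda t: (pts[t], abs(t)))
    return tbest, pts[tbest]


def _phi_refine(landscape, phi, theta, dphi, steps=2):
    F0 = landscape(phi, theta)
    for _ in range(steps):
        if dphi < 1.0:
            break
        for p in (max(0.0, phi - dphi), min(90.0, phi + dphi)):
            F = landscape(p, theta)
            if F < F0 - 1e-12:
                phi, F0 = p, F
        dphi *= 0.5
    return phi, F0


def _is_axisymmetric(shape: ScaffoldShape) -> bool:
    return shape.is_circular and np.isclose(shape.rho_a, shape.rho_b)


def optimal_orientation(shape: ScaffoldShape, d: float, params: ModelParameters,
                        phi_grid: Optional[Sequence[float]] = None,
                        theta_grid: Optional[Sequence[float]] = None,
                        landscape: Optional[EnergyLandscape] = None,
                        refine_steps: int = 2):
    """Minimize F_m over the orientation angles at fixed distance.

    Coarse grid scan followed by coordinate-wise parabolic refinement.
    Returns ``(phi_star, theta_star, F_min, landscape)``; the landscape
    carries all evaluated configurations for reuse.  For axially symmetric
    scaffolds F_m does not depend on phi and phi* = 0 is reported by the
    tie-break convention.
    """
    if landscape is None:
        landscape = EnergyLandscape(shape, d, params)
    axisym = _is_axisymmetric(shape)
    if phi_grid is None:
        phi_grid = [0.0] if axisym else [0.0, 45.0, 90.0]
    if theta_grid is None:
        theta_grid = [-2.0, 0.0, 2.0, 6.0]
    F, phi, theta = _grid_minimum(landscape, phi_grid, theta_grid)
    dtheta0 = max(0.5, np.diff(sorted(theta_grid)).min() / 2
                  if len(theta_grid) > 1 else 1.0)
    theta, F = _theta_line_min(landscape, phi, theta, dtheta0)
    if not axisym and len(phi_grid) > 1:
        dphi = np.diff(sorted(phi_grid)).max() / 2
        phi_new, F_new = _phi_refine(landscape, phi, theta, dphi,
                                     steps=refine_steps)
        if F_new < F - 1e-12:
            phi = phi_new
            theta, F = _theta_line_min(landscape, phi, theta, dtheta0)
    return phi, theta, F, landscape


def fronting_azimuth(shape: ScaffoldShape, phi_star: float) -> float:
    """Rim azimuth (degrees, in the scaffold frame) crossed by the line
    connecting the centers: the faces the scaffolds front each other with.
    0 is the long-axis face, 90 the short-axis face."""
    # connecting line along x; scaffold rotated in-plane by phi
    return abs(((phi_star + 90.0) % 180.0) - 90.0)


def elastic_interaction(shape: ScaffoldShape, d_values: Sequence[float],
                        params: ModelParameters,
                        d_ref: Optional[float] = None,
                        phi_grid: Optional[Sequence[float]] = None,
                        theta_grid: Optional[Sequence[float]] = None,
                        refine_steps: int = 2,
                        keep_landscapes: bool = False):
    """Orientation-optimized elastic interaction curve F_el(d).

    All distances (including d_ref, default 20 r_a) are solved with a
    common domain radius so the residual mesh error cancels in the
    subtraction; the sweep runs from d_ref inward with warm starts.
    """
    d_values = np.asarray(sorted(d_values, reverse=True), dtype=float)
    if d_ref is None:
        d_ref = 20.0 * shape.r_a
    if np.max(d_values) > d_ref:
        raise ValueError("d_ref must exceed every requested distance")
    if params.L is None:
        # one common domain for the whole sweep: residual mesh error is then
        # nearly constant in d and cancels in the F_min(d) - F_min(d_ref)
        # subtraction; L-independence is checked in the test suite
        params = params.with_(L=max(5.0 * d_ref, 25.0 * shape.r_a))

    rows = []
    landscapes = {}
    results = {}
    for d in np.concatenate([[d_ref], d_values]):
        phi, theta, F, ls = optimal_orientation(
            shape, float(d), params, phi_grid=phi_grid, theta_grid=theta_grid,
            refine_steps=refine_steps)
        results[float(d)] = (phi, theta, F)
        if keep_landscapes:
            landscapes[float(d)] = ls
        rows.append(dict(d=float(d), phi_star=phi, theta_star=theta, F_min=F,
                         n_evals=ls.n_evaluations))
    F_ref = results[float(d_ref)][2]
    order = np.argsort(d_values)
    d_sorted = d_values[order]
    curve = InteractionCurve(
        d=d_sorted,
        F_el=np.array([results[float(d)][2] - F_ref for d in d_sorted]),
        phi_star=np.array([results[float(d)][0] for d in d_sorted]),
        theta_star=np.array([results[float(d)][1] for d in d_sorted]),
        fronting_azimuth=np.array([fronting_azimuth(shape, results[float(d)][0])
                                   for d in d_sorted]),
        d_ref=float(d_ref), F_min_ref=F_ref,
        diagnostics=pd.DataFrame(rows))
    return (curve, landscapes) if keep_landscapes else curve


# --------------------------------------------------------------------------
# orientation-entropy integration


def _theta_window_samples(landscape, phi: float, theta0: float,
                          window_kbt: float, step0: float = 3.0,
                          grow: float = 1.6, theta_lo: float = -90.0,
                          theta_hi: float = 180.0, n_nodes: int = 7):
    """Sample F_m(theta) at phi, expanding from theta0 until the energy
    exceeds the local minimum by the window, in both directions (tilt is
    signed: positive away from the partner)."""
    samples = {theta0: landscape(phi, theta0)}
    Fmin = min(samples.values())
    for direction in (+1, -1):
        step = step0
        theta = theta0
        while True:
            theta = theta + direction * step
            if theta < theta_lo or theta > theta_hi:
                break
            samples[theta] = landscape(phi, theta)
            Fmin = min(Fmin, samples[theta])
            if samples[theta] - Fmin > window_kbt:
                break
            step *= grow
    # drop infeasible (overlapping) orientations, then place n_nodes
    # evaluation nodes across the detected window so narrow wells are
    # resolved, not just bracketed
    samples = {t: F for t, F in samples.items() if np.isfinite(F)}
    if not samples:      # entire line infeasible at this phi
        return np.array([]), np.array([])
    Fmin = min(samples.values())
    ts = np.array(sorted(samples))
    Fs = np.array([samples[t] for t in ts])
    inside = Fs <= Fmin + window_kbt
    lo_w = ts[inside].min()
    hi_w = ts[inside].max()
    i_lo = max(0, int(np.flatnonzero(inside)[0]) - 1)
    i_hi = min(len(ts) - 1, int(np.flatnonzero(inside)[-1]) + 1)
    lo_w, hi_w = ts[i_lo], ts[i_hi]
    for t in np.linspace(lo_w, hi_w, n_nodes):
        t = float(t)
        if all(abs(t - u) > 0.02 * max(1.0, hi_w - lo_w) for u in samples):
            samples[t] = landscape(phi, t)
    ts = np.array(sorted(samples))
    return ts, np.array([samples[t] for t in ts])


def _boltzmann_theta_integral(ts_deg, Fs, window_kbt: float,
                              theta_lo: float = -90.0,
                              theta_max: float = 180.0, n_quad: int = 500):
    """Int exp(-F(theta)) dtheta (radians), with F interpolated inside the
    sampled window and continued quadratically outside it."""
    from scipy.interpolate import PchipInterpolator

    imin = int(np.argmin(Fs))
    Fmin = Fs[imin]
    tmin = ts_deg[imin]
    # local quadratic curvature around the minimum (per degree^2)
    if len(ts_deg) >= 3:
        sel = np.argsort(np.abs(ts_deg - tmin))[:5]
        coef = np.polyfit(ts_deg[sel] - tmin, Fs[sel] - Fmin, 2)
        curv = max(coef[0], 1e-6)
    else:
        curv = 1e-2
    lo, hi = ts_deg[0], ts_deg[-1]
    interp = PchipInterpolator(ts_deg, Fs) if len(ts_deg) >= 2 else (lambda t: Fs[0] + 0 * t)

    curv = max(curv, 1e-4)

    def F_of(t):
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        inside = (t >= lo) & (t <= hi)
        out[inside] = interp(t[inside])
        # quadratic continuation, forced to rise away from the window (the
        # excluded wings carry weight < e^-window by construction)
        for edge, mask in ((lo, t < lo), (hi, t > hi)):
            if np.any(mask):
                Fe = float(interp(edge))
                ge = abs(float(interp.derivative()(edge))) if len(ts_deg) >= 2 else 0.0
                dt = np.abs(t[mask] - edge)
                out[mask] = Fe + ge * dt + 0.5 * curv * dt ** 2
        return out

    tq = np.linspace(theta_lo, theta_max, n_quad)
    Fq = F_of(tq)
    w = np.exp(-np.clip(Fq - Fmin, -5.0, 700.0))
    integral = np.trapezoid(w, np.radians(tq))
    return integral, Fmin  # Int exp(-F) = integral * exp(-Fmin)


def free_energy(shape: ScaffoldShape, d: float, params: ModelParameters,
                landscape: Optional[EnergyLandscape] = None,
                phi_star: float = 0.0,
                theta_star: float = 0.0,
                n_phi: Optional[int] = None,
                window_kbt: Optional[float] = None):
    """log-partition free energy of the orientation ensemble at distance d.

    Returns ``(logZ, diagnostics)`` with logZ = log Int exp(-F_m/kT) dtheta
    dphi (angles in radians).  F(d) differences between distances are the
    physical free-energy curve; absolute values contain the arbitrary
    measure constant.

    Both angles are integrated adaptively: the tilt within its
    sampled-energy window around the minimum, and the in-plane angle via
    the effective potential G(phi) = -log Int exp(-F_m(phi, theta)) dtheta,
    sampled with the same window logic (strongly anisotropic scaffolds can
    confine phi to a degree-wide well at the range boundary, which fixed
    quadrature nodes would miss entirely).
    """
    if landscape is None:
        landscape = EnergyLandscape(shape, d, params)
    n_phi = n_phi if n_phi is not None else params.n_phi_nodes
    window = window_kbt if window_kbt is not None else params.theta_window_kbt

    diags = []
    t_start = {0: float(theta_star)}

    def G(_ignored, phi):
        """Effective phi potential -log Ztheta(phi) (radians measure)."""
        phi = float(phi)
        starts = min(t_start, key=lambda p: abs(p - phi))
        ts, Fs = _theta_window_samples(landscape, phi, t_start[starts],
                                       window, n_nodes=params.n_theta_nodes)
        if len(ts) == 0:
            diags.append(dict(phi=phi, theta_min=np.nan, F_min=np.inf,
                              n_theta=0, G=np.inf))
            return np.inf
        integral, Fmin = _boltzmann_theta_integral(ts, Fs, window)
        t_start[phi] = float(ts[np.argmin(Fs)])
        val = Fmin - float(np.log(integral))
        diags.append(dict(phi=phi, theta_min=t_start[phi], F_min=Fmin,
                          n_theta=len(ts), G=val))
        return val

    if _is_axisymmetric(shape):
        G0 = G(0.0, 45.0)
        logZ = np.log(np.pi / 2) - G0
        return float(logZ), pd.DataFrame(diags)

    phis, Gs = _theta_window_samples(
        G, 0.0, float(np.clip(phi_star, 0.0, 90.0)), window,
        step0=4.0, theta_lo=0.0, theta_hi=90.0, n_nodes=n_phi)
    if len(phis) == 0:
        raise ValueError("no feasible orientation at this distance")
    integral_phi, Gmin = _boltzmann_theta_integral(
        phis, Gs, window, theta_lo=0.0, theta_max=90.0)
    logZ = float(np.log(integral_phi) - Gmin)
    return logZ, pd.DataFrame(diags)


def free_energy_curve(shape: ScaffoldShape, d_values: Sequence[float],
                      params: ModelParameters,
                      d_ref: Optional[float] = None,
                      phi_grid: Optional[Sequence[float]] = None,
                      theta_grid: Optional[Sequence[float]] = None) -> FreeEnergyCurve:
    """F(d) and F_ent(d) = F(d) - F_el(d), both referenced to d_ref."""
    if d_ref is None:
        d_ref = 20.0 * shape.r_a
    if params.L is None:
        params = params.with_(L=params.L_factor * max(d_ref, shape.r_a))
    curve, landscapes = elastic_interaction(
        shape, d_values, params, d_ref=d_ref, phi_grid=phi_grid,
        theta_grid=theta_grid, keep_landscapes=True)
    optima = curve.diagnostics.set_index("d")
    logZ = {}
    diag_rows = []
    for d in np.concatenate([[d_ref], curve.d]):
        ls = landscapes[float(d)]
        row = optima.loc[float(d)]
        lz, dg = free_energy(shape, float(d), params, landscape=ls,
                             phi_star=float(row.phi_star),
                             theta_star=float(row.theta_star))
        logZ[float(d)] = lz
        diag_rows.append(dict(d=float(d), logZ=lz, n_evals=ls.n_evaluations))
    F = np.array([-(logZ[float(d)] - logZ[float(d_ref)]) for d in curve.d])
    return FreeEnergyCurve(d=curve.d, F=F, F_ent=F - curve.F_el,
                           F_el=curve.F_el, d_ref=float(d_ref),
                           diagnostics=pd.DataFrame(diag_rows))


# --------------------------------------------------------------------------
# far-field power law


def fit_power_law(curve: InteractionCurve | tuple, d_window=None):
    """Least-squares slope of log|F_el| versus log d.

    ``curve`` may be an InteractionCurve or a (d, F_el) pair.  All points
    inside the window must have one sign (else the fit is meaningless and a
    ValueError instructs to split the window).  Returns (slope, stderr).
    """
    if isinstance(curve, InteractionCurve):
        d, F = curve.d, curve.F_el
    else:
        d, F = map(np.asarray, curve)
    if d_window is not None:
        sel = (d >= d_window[0]) & (d <= d_window[1])
        d, F = d[sel], F[sel]
    if len(d) < 4:
        raise ValueError("need at least 4 points in the fit window")
    signs = np.sign(F)
    if len(set(signs[signs != 0])) > 1:
        raise ValueError("F_el changes sign inside the window; "
                         "split the window at the zero crossing")
    x, y = np.log(d), np.log(np.abs(F))
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    n = len(x)
    if n > 2 and np.size(res):
        s2 = float(np.ravel(res)[0]) / (n - 2)
        stderr = float(np.sqrt(s2 / np.sum((x - x.mean()) ** 2)))
    else:
        stderr = float("nan")
    return float(coef[0]), stderr
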