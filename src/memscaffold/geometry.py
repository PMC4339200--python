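"""Rigid scaffold geometry.

A membrane-shaping protein (or protein oligomer) is modeled as an infinitely
rigid surface patch cut from a quadric: an ellipsoid-of-revolution-like
surface

    (x/rho_a)^2 + sign(rho_b) (y/rho_b)^2 + (z/rho_a)^2 = 1,

intersected with an elliptic cylinder (x/r_a)^2 + (y/r_b)^2 = 1.  Positive
``rho_b`` gives a convex (ellipsoidal) patch, negative ``rho_b`` a saddle-like
(hyperboloidal) patch, and ``|rho_b| = inf`` a cylindrical patch curved along
one axis only.  The patch is apex-referenced: its central point touches z = 0
and the surface extends downward (for convex patches) toward the membrane
plane.

The scaffold imposes a normal-continuity boundary condition on the membrane
along its rim: the membrane surface normal must coincide with the scaffold
surface normal at every rim point.  The angle between the rim normal and the
center normal is the *contact angle*; for the quadric above it varies along
the rim between roughly arcsin(r_a/rho_a) (long axis) and arcsin(r_b/rho_b)
(short axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ScaffoldShape",
    "PairConfiguration",
    "ModelParameters",
    "RigidTransform",
    "OverlapError",
    "surface_height",
    "contact_angle",
    "rim_samples",
    "place_pair",
    "preset",
    "PRESETS",
]


class OverlapError(ValueError):
    """Raised when a pair configuration would overlap the scaffold rims.

    Carries ``min_distance``, the smallest center-to-center distance allowed
    for the requested orientations.
    """

    def __init__(self, d: float, min_distance: float):
        self.min_distance = min_distance
        super().__init__(
            f"scaffold rims overlap at d={d:g}; minimum allowed distance for "
            f"this orientation is {min_distance:g}"
        )


# --------------------------------------------------------------------------
# shapes


@dataclass(frozen=True)
class ScaffoldShape:
    """Rigid scaffold patch geometry.

    Parameters
    ----------
    rho_a : float
        Curvature radius along the long (x) axis, > 0.
    rho_b : float
        Signed curvature radius along the short (y) axis.  Positive for
        convex (ellipsoidal) patches, negative for saddles; ``±inf`` for a
        cylindrical patch (zero curvature along y).
    r_a, r_b : float
        Semi-axes of the elliptical footprint in the reference plane.
    units : str
        Length unit tag, ``"a"`` (scaffold radii) or ``"nm"``.
    """

    rho_a: float
    rho_b: float
    r_a: float
    r_b: float
    units: str = "a"

    def __post_init__(self):
        if not (self.rho_a > 0):
            raise ValueError("rho_a must be positive")
        if self.r_a <= 0 or self.r_b <= 0:
            raise ValueError("footprint semi-axes must be positive")
        if not (self.r_a < self.rho_a):
            raise ValueError("need r_a < rho_a for a real rim height")
        if self.rho_b == 0:
            raise ValueError("rho_b must be nonzero (use inf for flat axis)")
        if not (self.r_b < abs(self.rho_b)):
            raise ValueError("need r_b < |rho_b| for a real rim height")
        if self.units not in ("a", "nm"):
            raise ValueError("units must be 'a' or 'nm'")

    # -- derived quantities -------------------------------------------------

    @property
    def c_a(self) -> float:
        """Nominal principal curvature along the long axis, 1/rho_a."""
        return 1.0 / self.rho_a

    @property
    def c_b(self) -> float:
        """Nominal (signed) principal curvature along the short axis, 1/rho_b."""
        if np.isinf(self.rho_b):
            return 0.0
        return 1.0 / self.rho_b

    @property
    def phi_a(self) -> float:
        """Contact angle at the long-axis rim point, degrees (exact)."""
        return float(np.degrees(np.arcsin(self.r_a / self.rho_a)))

    @property
    def phi_b(self) -> float:
        """Nominal contact angle arcsin(r_b/rho_b) at the short-axis rim
        point, degrees; signed like ``rho_b``.  Exact for rho_a = rho_b."""
        if np.isinf(self.rho_b):
            return 0.0
        return float(np.degrees(np.arcsin(self.r_b / self.rho_b)))

    @property
    def is_circular(self) -> bool:
        return np.isclose(self.r_a, self.r_b)

    @property
    def a_scale(self) -> float:
        """Footprint length scale: r_a for circular footprints, else the
        geometric-mean radius sqrt(r_a r_b)."""
        if self.is_circular:
            return float(self.r_a)
        return float(np.sqrt(self.r_a * self.r_b))

    @property
    def A(self) -> float:
        """Scaffold patch area (numerical surface integral over the footprint)."""
        # Gauss-Legendre on the unit disc mapped to the elliptical footprint.
        n = 48
        gl_r, gl_wr = np.polynomial.legendre.leggauss(n)
        u = 0.5 * (gl_r + 1.0)          # radial in (0, 1)
        wu = 0.5 * gl_wr
        t = np.linspace(0.0, 2 * np.pi, 2 * n, endpoint=False)
        dt = 2 * np.pi / (2 * n)
        uu, tt = np.meshgrid(u, t, indexing="ij")
        x = self.r_a * uu * np.cos(tt)
        y = self.r_b * uu * np.sin(tt)
        gx, gy = _height_gradient(self, x, y)
        integrand = np.sqrt(1.0 + gx**2 + gy**2) * uu
        return float(self.r_a * self.r_b * dt * np.sum(integrand.T * wu))

    # -- constructors ---------------------------------------------------------

    @staticmethod
    def shallow_circular(cb_over_ca: float = 1.0, a_over_rho: float = 0.2) -> "ScaffoldShape":
        """Circular-footprint shallow scaffold: r_a = r_b = 1 (a-units),
        rho_a = 1/a_over_rho, rho_b chosen so c_b/c_a equals `cb_over_ca`."""
        rho_a = 1.0 / a_over_rho
        rho_b = np.inf if cb_over_ca == 0 else rho_a / cb_over_ca
        return ScaffoldShape(rho_a=rho_a, rho_b=rho_b, r_a=1.0, r_b=1.0, units="a")

    @staticmethod
    def elongated_isotropic(aspect: float, r_over_rho: float = 0.2) -> "ScaffoldShape":
        """Elliptical-footprint scaffold with isotropic curvature
        rho_a = rho_b = rho, geometric-mean radius r = sqrt(r_a r_b) = 1 and
        aspect ratio r_a/r_b = `aspect`; r/rho = `r_over_rho`."""
        r_a = float(np.sqrt(aspect))
        r_b = 1.0 / r_a
        rho = 1.0 / r_over_rho
        return ScaffoldShape(rho_a=rho, rho_b=rho, r_a=r_a, r_b=r_b, units="a")


def preset(name: str, **overrides) -> ScaffoldShape:
    """Return a named scaffold preset.

    ``shallow_circular``: circular footprint, a/rho_a = 0.2 (a-units).
    ``endophilin_nbar``: BAR-domain geometry r_a = 6.5 nm, r_b = 1.5 nm,
    rho_a = 8.5 nm; ``c_b`` (nm^-1) selects rho_b (default 0.2 nm^-1).
    """
    if name == "shallow_circular":
        return ScaffoldShape.shallow_circular(**overrides)
    if name == "endophilin_nbar":
        c_b = overrides.pop("c_b", 0.2)
        rho_b = np.inf if c_b == 0 else 1.0 / c_b
        return ScaffoldShape(rho_a=8.5, rho_b=rho_b, r_a=6.5, r_b=1.5, units="nm", **overrides)
    raise KeyError(f"unknown preset {name!r}")


PRESETS = ("shallow_circular", "endophilin_nbar")


# --------------------------------------------------------------------------
# surface evaluation


def _inside_footprint(shape: ScaffoldShape, x, y, tol: float = 1e-9):
    return (np.asarray(x) / shape.r_a) ** 2 + (np.asarray(y) / shape.r_b) ** 2 <= 1.0 + tol


def _radicand(shape: ScaffoldShape, x, y):
    s = np.sign(shape.rho_b)
    yterm = 0.0 if np.isinf(shape.rho_b) else s * (np.asarray(y) / shape.rho_b) ** 2
    return 1.0 - (np.asarray(x) / shape.rho_a) ** 2 - yterm


def surface_height(shape: ScaffoldShape, x, y):
    """Apex-referenced height z(x, y) of the scaffold surface.

    Solves the quadric for the upper sheet and shifts so z(0, 0) = 0.  For a
    convex patch the height is <= 0 away from the apex (the patch is a dome
    whose rim sits below its center); a saddle patch falls along x and rises
    along y.

    Raises ``ValueError`` for points outside the elliptical footprint or
    where the quadric has no real upper-sheet root.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(_inside_footprint(shape, x, y)):
        raise ValueError("point outside the scaffold footprint")
    rad = _radicand(shape, x, y)
    if np.any(rad < -1e-12):
        raise ValueError("no real surface point here (quadric out of range)")
    z = shape.rho_a * np.sqrt(np.clip(rad, 0.0, None))
    out = z - shape.rho_a
    return float(out) if out.ndim == 0 else out


def _height_gradient(shape: ScaffoldShape, x, y):
    """(dz/dx, dz/dy) of the apex-referenced surface."""
    # z^2 = rho_a^2 (1 - x^2/rho_a^2 - s y^2/rho_b^2)
    # => z dz/dx = -x,   z dz/dy = -s y rho_a^2 / rho_b^2
    rad = np.clip(_radicand(shape, x, y), 1e-15, None)
    z = shape.rho_a * np.sqrt(rad)
    gx = -np.asarray(x) / z
    if np.isinf(shape.rho_b):
        gy = np.zeros_like(np.asarray(y, dtype=float))
    else:
        s = np.sign(shape.rho_b)
        gy = -s * np.asarray(y) * shape.rho_a**2 / (shape.rho_b**2 * z)
    return gx, gy


def surface_normal(shape: ScaffoldShape, x, y):
    """Upward unit normal(s) of the scaffold surface at footprint point(s)."""
    gx, gy = _height_gradient(shape, x, y)
    n = np.stack(np.broadcast_arrays(-gx, -gy, np.ones_like(gx)), axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def contact_angle(shape: ScaffoldShape, azimuth) -> float | np.ndarray:
    """Contact angle (degrees) at rim azimuth(s).

    The rim point is parametrized as (r_a cos t, r_b sin t) with t the
    azimuth in degrees; the returned value is the true angle between the
    surface normal there and the center normal (z axis).  For a spherical
    cap it is arcsin(r/rho) at every azimuth.
    """
    t = np.radians(azimuth)
    x = shape.r_a * np.cos(t)
    y = shape.r_b * np.sin(t)
    n = surface_normal(shape, x, y)
    ang = np.degrees(np.arccos(np.clip(n[..., 2], -1.0, 1.0)))
    return float(ang) if np.ndim(azimuth) == 0 else ang


def rim_samples(shape: ScaffoldShape, n: int):
    """Sample the rim curve.

    Returns ``(points, normals, t)``: `n` points on the intersection of the
    quadric with the footprint cylinder (closing the loop), the analytic unit
    surface normals there, and the footprint parameter angles t (radians).
    """
    if n < 12:
        raise ValueError("need at least 12 rim samples")
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return _rim_at(shape, t) + (t,)


def _rim_at(shape: ScaffoldShape, t):
    x = shape.r_a * np.cos(t)
    y = shape.r_b * np.sin(t)
    z = surface_height(shape, x, y)
    pts = np.stack([x, y, np.atleast_1d(z)], axis=-1)
    nrm = surface_normal(shape, x, y)
    return pts, nrm


# --------------------------------------------------------------------------
# pair configuration and placement


@dataclass(frozen=True)
class PairConfiguration:
    """Relative placement of two scaffolds on the membrane.

    ``d`` is the center-to-center distance.  ``phi`` is the in-plane angle
    (degrees, [0, 90]) between each scaffold's long axis and the line
    connecting the centers; ``theta`` (degrees) tilts the scaffold center
    normal within the plane containing the connecting line, positive away
    from the partner (a convex scaffold riding the partner's membrane
    depression tilts away; this is where the energy minima lie).  The
    nominal range [0, 180] spans vertical to fully inverted; negative
    values down to -90 (tilt toward the partner) are accepted for controls
    and for sampling the orientation ensemble across the minimum.  In
    symmetric mode the two scaffolds are mirror images across the plane
    bisecting the connecting line.  Asymmetric orientations (phi1 != phi2
    or theta1 != theta2) are supported as a control.
    """

    d: float
    phi: float = 0.0
    theta: float = 0.0
    symmetric: bool = True
    phi1: Optional[float] = None
    phi2: Optional[float] = None
    theta1: Optional[float] = None
    theta2: Optional[float] = None

    def __post_init__(self):
        if not self.d > 0:
            raise ValueError("d must be positive")
        if self.symmetric:
            if any(v is not None for v in (self.phi1, self.phi2, self.theta1, self.theta2)):
                raise ValueError("symmetric mode takes only phi and theta")
            object.__setattr__(self, "phi1", self.phi)
            object.__setattr__(self, "phi2", self.phi)
            object.__setattr__(self, "theta1", self.theta)
            object.__setattr__(self, "theta2", self.theta)
        else:
            for name in ("phi1", "phi2", "theta1", "theta2"):
                if getattr(self, name) is None:
                    raise ValueError(f"asymmetric mode requires {name}")
        if not (0.0 <= self.phi <= 90.0):
            raise ValueError("phi must lie in [0, 90] degrees")
        for th in (self.theta, self.theta1, self.theta2):
            if not (-90.0 <= th <= 180.0):
                raise ValueError("theta must lie in [-90, 180] degrees")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform p -> R p + t."""

    R: np.ndarray
    t: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.R.T + self.t

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.R.T


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def place_pair(shape: ScaffoldShape, config: PairConfiguration,
               clearance: float = 0.0) -> tuple[RigidTransform, RigidTransform]:
    """Rigid placements of the two scaffolds.

    Scaffold 1 is centered at (-d/2, 0, 0): rotated in-plane by phi1 about
    its vertical axis, then tilted by theta1 about the in-plane axis
    perpendicular to the connecting line (so its center normal tips within
    the connecting-line plane, positive theta away from the partner).
    Scaffold 2 is the mirror image across the bisecting plane x = 0 (with
    an internal x-flip so the transform stays a proper rotation; the
    quadric patch is symmetric under local x -> -x).

    Raises ``OverlapError`` if the rim projections would come closer than
    ``clearance`` along the connecting line.
    """
    R1 = _rot_y(-config.theta1) @ _rot_z(config.phi1)
    R2 = _MIRROR_X @ (_rot_y(-config.theta2) @ _rot_z(config.phi2)) @ _MIRROR_X
    T1 = RigidTransform(R1, np.array([-config.d / 2.0, 0.0, 0.0]))
    T2 = RigidTransform(R2, np.array([+config.d / 2.0, 0.0, 0.0]))

    min_d = _support_x(shape, R1) + _support_x(shape, R2) + clearance
    if config.d < min_d:
        raise OverlapError(config.d, min_d)
    if clearance > 0 and _surface_clearance(shape, T1, T2) < 0.5 * clearance:
        # tilted scaffolds can approach (or interpenetrate) in 3D even when
        # their rim projections stay apart
        raise OverlapError(config.d, min_d)
    return T1, T2


def _surface_points(shape: ScaffoldShape, n_r: int = 6, n_t: int = 28) -> np.ndarray:
    """Sample points covering the scaffold surface (cached per shape)."""
    cache = getattr(shape, "_surf_cache", None)
    if cache is not None:
        return cache
    fr = np.linspace(0.15, 1.0, n_r)
    t = np.linspace(0.0, 2 * np.pi, n_t, endpoint=False)
    ff, tt = np.meshgrid(fr, t, indexing="ij")
    x = shape.r_a * ff * np.cos(tt)
    y = shape.r_b * ff * np.sin(tt)
    z = surface_height(shape, x, y)
    pts = np.c_[x.ravel(), y.ravel(), np.asarray(z).ravel()]
    object.__setattr__(shape, "_surf_cache", pts)
    return pts


def _surface_clearance(shape: ScaffoldShape, T1: RigidTransform,
                       T2: RigidTransform) -> float:
    """Minimum 3D distance between the two placed scaffold surfaces."""
    from scipy.spatial import cKDTree
    pts = _surface_points(shape)
    p1 = T1.apply(pts)
    p2 = T2.apply(pts)
    dmin, _ = cKDTree(p1).query(p2, k=1)
    return float(dmin.min())


def _support_x(shape: ScaffoldShape, R: np.ndarray, n: int = 720) -> float:
    """Support radius of the transformed rim projected on the connecting line."""
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts, _ = _rim_at(shape, t)
    return float(np.max(np.abs(pts @ R.T[:, 0])))


# --------------------------------------------------------------------------
# model parameters


@dataclass(frozen=True)
class ModelParameters:
    """Membrane model and numerical parameters.

    Energies are in units of k_B T throughout; lengths follow the scaffold's
    unit tag.  ``kappa`` is the bending modulus (default 20 k_B T), ``gamma``
    an optional lateral tension (k_B T / length^2; the tension decay length
    is xi = sqrt(kappa/gamma)).  ``L`` is the membrane patch radius; if None
    it is sized automatically as ``L_factor * max(d, r_a)``.  ``h`` is the
    target mesh edge length near the scaffolds.
    """

    kappa: float = 20.0
    gamma: float = 0.0
    L: Optional[float] = None
    L_factor: float = 30.0
    h: Optional[float] = None
    # minimizer contract
    gtol: float = 1e-6
    ftol: float = 1e-10
    max_iter: int = 5000
    n_cycles: int = 3          # descent stages per level
    xyz_stages: int = 0        # optional full-3D (tangential) interludes
    n_levels: int = 1
    energy_tol: float = 0.05   # k_B T, refinement stopping error estimate
    # orientation-entropy integration
    n_phi_nodes: int = 9
    n_theta_nodes: int = 7
    theta_window_kbt: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    def domain_radius(self, d: float, shape: ScaffoldShape) -> float:
        if self.L is not None:
            return self.L
        return self.L_factor * max(d, shape.r_a)

    def edge_length(self, shape: ScaffoldShape) -> float:
        if self.h is not None:
            return self.h
        return 0.35 * shape.a_scale

    @property
    def xi(self) -> float:
        """Tension decay length sqrt(kappa/gamma); inf for gamma = 0."""
        return np.inf if self.gamma == 0 else float(np.sqrt(self.kappa / self.gamma))

    def with_(self, **kw) -> "ModelParameters":
        return replace(self, **kw)
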