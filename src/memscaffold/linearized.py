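"""Linearized (small-gradient) membrane height solvers.

Two distinct linear solvers live here:

* :func:`mesh_biharmonic_solve` — the small-gradient limit of the discrete
  Helfrich energy on the *same* triangulation the nonlinear minimizer uses.
  It provides the initial height field for cold starts (one sparse solve).
  The quadratic form is exactly degenerate along discrete harmonic
  functions (the catenoid log-mode costs no bending energy), so a weak
  tension-like regularizer ~ kappa/L^2 selects the smallest-gradient
  minimizer; the nonlinear relaxation then refines the shape.

* :class:`MongeGrid` — an independent finite-difference solver of the
  Monge-gauge linearized problem, (kappa/2) (laplacian u)^2 on a regular
  grid with the scaffold footprints imposed as Dirichlet patches.  It is
  used as a cross-check of the mesh engine in the shallow regime and never
  feeds the mesh pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl

from .geometry import (
    ModelParameters,
    PairConfiguration,
    RigidTransform,
    ScaffoldShape,
    place_pair,
    surface_height,
)
from .mesh import TriangulatedMembrane, _barycentric_areas, _cotangents

__all__ = ["mesh_biharmonic_solve", "flat_bending_operator", "MongeGrid",
           "monge_elastic_energy"]


def flat_bending_operator(mesh: TriangulatedMembrane, kappa: float,
                          gamma: float = 0.0):
    """Sparse quadratic form K of the linearized bending (+tension) energy
    about the flat projected configuration: F ~ (1/2) z^T K z."""
    X = np.c_[mesh.vertices[:, 0], mesh.vertices[:, 1],
              np.zeros(mesh.n_vertices)]
    ci, cj, ck, A2 = _cotangents(X, mesh.triangles)[:4]
    T = mesh.triangles
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for (a, b, cot) in ((1, 2, ci), (0, 2, cj), (0, 1, ck)):
        w = 0.5 * cot
        ia, ib = T[:, a], T[:, b]
        rows += [ia, ib, ia, ib]
        cols += [ib, ia, ia, ib]
        vals += [-w, -w, w, w]
    L = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    M = _barycentric_areas(T, A2, n)
    emask = mesh.interior_mask()
    D = sp.diags(np.where(emask, 1.0 / np.maximum(M, 1e-300), 0.0))
    Ldom = mesh.meta.get("L", float(np.sqrt(M.sum() / np.pi)))
    # weak tension-like term: the pure biharmonic form is degenerate along
    # discrete harmonic modes (log / r^m cos(m phi) tails); a decay length
    # of L/4 pins them without disturbing the near field
    greg = max(gamma, 16.0 * kappa / Ldom ** 2)
    return kappa * (L.T @ D @ L) + greg * L


def mesh_biharmonic_solve(mesh: TriangulatedMembrane,
                          params: ModelParameters) -> np.ndarray:
    """Height field minimizing the linearized energy with the fixed ring
    heights as Dirichlet data.  Returns the full per-vertex z array.

    The outer boundary ring carries a single shared height unknown (rigid
    ring), matching the nonlinear solver's boundary treatment.
    """
    K = flat_bending_operator(mesh, params.kappa, params.gamma)
    fixed = mesh.fixed_mask
    outer = np.asarray(mesh.outer_ids, dtype=int)
    outer = outer[~fixed[outer]] if outer.size else outer
    fr = np.setdiff1d(np.flatnonzero(~fixed), outer)
    fx = np.flatnonzero(fixed)
    z = np.zeros(mesh.n_vertices)
    z[fx] = mesh.vertices[fx, 2]
    if outer.size:
        ones = np.ones(outer.size)
        Kii = K[fr][:, fr]
        Kio = sp.csr_matrix(K[fr][:, outer] @ ones).T
        koo = float(ones @ (K[outer][:, outer] @ ones))
        A = sp.bmat([[Kii, Kio], [Kio.T, sp.csr_matrix([[koo]])]]).tocsc()
        b = np.concatenate([-(K[fr][:, fx] @ z[fx]),
                            [-(ones @ (K[outer][:, fx] @ z[fx]))]])
        sol = spl.spsolve(A, b)
        z[fr] = sol[:-1]
        z[outer] = sol[-1]
    else:
        z[fr] = spl.spsolve(K[fr][:, fr].tocsc(), -(K[fr][:, fx] @ z[fx]))
    return z


# --------------------------------------------------------------------------
# independent Monge-gauge finite-difference oracle


@dataclass
class MongeGrid:
    """Regular-grid Monge-gauge solver.

    The membrane is a height function u(x, y) over [-W, W]^2 with spacing
    delta; bending energy (kappa/2) sum (lap u)^2 dA with the 5-point
    Laplacian, u clamped to 0 on the outer frame.  Scaffold footprints are
    Dirichlet patches carrying the (rigidly placed) scaffold surface height;
    constraining the full patch interior enforces slope continuity across
    the rim at grid resolution.
    """

    W: float
    n: int
    kappa: float = 20.0
    gamma: float = 0.0

    def __post_init__(self):
        x = np.linspace(-self.W, self.W, self.n)
        self.delta = x[1] - x[0]
        self.x, self.y = np.meshgrid(x, x, indexing="ij")
        n2 = self.n * self.n
        e = np.ones(self.n)
        L1 = sp.diags([e[:-1], -2 * e, e[:-1]], [-1, 0, 1], (self.n, self.n))
        I = sp.identity(self.n)
        self.lap = (sp.kron(L1, I) + sp.kron(I, L1)).tocsr() / self.delta ** 2
        self._frame = np.zeros((self.n, self.n), dtype=bool)
        self._frame[[0, -1], :] = True
        self._frame[:, [0, -1]] = True

    def scaffold_mask_height(self, shape: ScaffoldShape, T: RigidTransform):
        """Grid mask of a placed footprint and the scaffold height there."""
        rel = np.c_[self.x.ravel(), self.y.ravel(), np.zeros(self.x.size)]
        loc = (rel - T.t) @ T.R
        inside = (loc[:, 0] / shape.r_a) ** 2 + (loc[:, 1] / shape.r_b) ** 2 <= 1.0
        zloc = np.zeros(self.x.size)
        idx = np.flatnonzero(inside)
        zloc[idx] = surface_height(shape, loc[idx, 0], loc[idx, 1])
        world = np.c_[loc[:, 0], loc[:, 1], zloc] @ T.R.T + T.t
        return inside.reshape(self.n, self.n), world[:, 2].reshape(self.n, self.n)

    def solve(self, shape: ScaffoldShape, config: PairConfiguration | None):
        """Relaxed height field and its bending energy (k_B T)."""
        if config is None:
            placements = [RigidTransform(np.eye(3), np.zeros(3))]
        else:
            placements = list(place_pair(shape, config))
        u = np.zeros((self.n, self.n))
        fixed = self._frame.copy()
        patch = np.zeros_like(fixed)
        for T in placements:
            mask, hz = self.scaffold_mask_height(shape, T)
            u[mask] = hz[mask]
            fixed |= mask
            patch |= mask
        nfl = self.n * self.n
        fixedf = fixed.ravel()
        # energy rows: grid nodes whose 5-point stencil stays off the patch
        # interiors' complement is fine -- use all non-frame nodes
        interior = ~self._frame.ravel()
        D = sp.diags(np.where(interior, self.delta ** 2, 0.0))
        K = self.kappa * (self.lap.T @ D @ self.lap)
        if self.gamma:
            K = K + self.gamma * self.delta ** 2 * (-self.lap)
        fr = np.flatnonzero(~fixedf)
        fx = np.flatnonzero(fixedf)
        uf = u.ravel()
        rhs = -(K[fr][:, fx] @ uf[fx])
        uf[fr] = spl.spsolve(K[fr][:, fr].tocsc(), rhs)
        u = uf.reshape(self.n, self.n)
        # bending energy off the scaffold patches
        lap_u = (self.lap @ uf).reshape(self.n, self.n)
        dens = 0.5 * self.kappa * lap_u ** 2 * self.delta ** 2
        dens[patch] = 0.0
        dens[self._frame] = 0.0
        F = float(dens.sum())
        if self.gamma:
            gx, gy = np.gradient(u, self.delta)
            td = 0.5 * self.gamma * (gx ** 2 + gy ** 2) * self.delta ** 2
            td[patch] = 0.0
            F += float(td.sum())
        return u, F


def monge_elastic_energy(shape: ScaffoldShape, d_values, params: ModelParameters,
                         d_ref: float, phi: float = 0.0, theta: float = 0.0,
                         W: float | None = None, n: int = 321) -> np.ndarray:
    """F_el(d) from the finite-difference Monge solver (shallow regime)."""
    W = W if W is not None else max(6.0 * max(d_values), 40.0 * shape.a_scale)
    grid = MongeGrid(W=W, n=n, kappa=params.kappa, gamma=params.gamma)
    def F_at(d):
        _, F = grid.solve(shape, PairConfiguration(d=d, phi=phi, theta=theta))
        return F
    Fref = F_at(d_ref)
    return np.array([F_at(d) - Fref for d in np.atleast_1d(d_values)])
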