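"""Triangulated membrane: discrete curvature and Helfrich energy.

The membrane is a triangle mesh with three boundary loops (two scaffold
collars, one outer rim) or one loop in single-scaffold mode.  The bending
energy is the discrete Helfrich functional

    F = sum_v (kappa/2) J_v^2 A_v,        J_v = |(L x)_v| / A_v,

where L is the cotangent Laplacian (area-gradient form, so (L x)_v is the
integrated mean-curvature vector, J the total curvature = twice the mean
curvature) and A_v a vertex area.  The energy uses barycentric vertex areas,
which are smooth functions of the vertex positions; the exact analytic
gradient of F with respect to all free vertices is assembled alongside the
energy and drives the quasi-Newton minimizer.  The curvature *measurement*
operator offers the mixed-Voronoi (obtuse-safe) area as its default.

An optional lateral tension gamma adds gamma * (area - reference area),
with the reference the flat projected area of the patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import trimesh

__all__ = [
    "TriangulatedMembrane",
    "CurvatureField",
    "vertex_total_curvature",
    "bending_energy",
    "tension_energy",
    "total_energy",
    "energy_and_gradient",
    "regularize",
    "max_dihedral_angle",
    "error_estimate",
    "min_triangle_angle",
    "save_mesh",
    "load_mesh",
]


class DegenerateTriangleError(RuntimeError):
    def __init__(self, tri_id: int):
        self.tri_id = tri_id
        super().__init__(f"degenerate triangle {tri_id}")


@dataclass
class TriangulatedMembrane:
    """Vertex/triangle mesh with fixed scaffold rings.

    ``fixed_mask`` marks vertices pinned during minimization (scaffold rim
    and collar rings).  ``rim_rings`` / ``collar_rings`` hold the ordered
    vertex ids of each scaffold's rings; ``outer_ids`` the outer boundary.
    ``area_ref`` is the flat projected reference area used by the tension
    term.  ``meta`` carries construction data (shape, placements, ring
    parameters) needed for refinement.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    fixed_mask: np.ndarray
    rim_rings: list = field(default_factory=list)
    collar_rings: list = field(default_factory=list)
    outer_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    area_ref: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        if self.area_ref is None:
            self.area_ref = float(_triangle_areas(self.vertices, self.triangles).sum())

    # -- basic queries ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "TriangulatedMembrane":
        return TriangulatedMembrane(
            self.vertices.copy(), self.triangles.copy(), self.fixed_mask.copy(),
            [np.array(r) for r in self.rim_rings],
            [np.array(c) for c in self.collar_rings],
            np.array(self.outer_ids), self.area_ref, dict(self.meta),
        )

    def boundary_vertices(self) -> np.ndarray:
        """Vertices on boundary edges (edges used by exactly one triangle).

        Cached per object; edge flips never touch boundary edges so the
        cache stays valid across regularization.
        """
        cache = self.__dict__.setdefault("_cache", {})
        if "boundary" not in cache:
            e = np.vstack([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                           self.triangles[:, [2, 0]]])
            e.sort(axis=1)
            uniq, counts = np.unique(e, axis=0, return_counts=True)
            cache["boundary"] = np.unique(uniq[counts == 1])
        return cache["boundary"]

    def boundary_loops(self) -> list:
        """Ordered boundary loops (lists of vertex ids)."""
        e = np.vstack([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        es = np.sort(e, axis=1)
        uniq, counts = np.unique(es, axis=0, return_counts=True)
        bedges = uniq[counts == 1]
        # walk loops
        from collections import defaultdict
        adj = defaultdict(list)
        for a, b in bedges:
            adj[a].append(b)
            adj[b].append(a)
        seen = set()
        loops = []
        for start in adj:
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nxts = [v for v in adj[cur] if v != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                if cur == start:
                    break
                loop.append(cur)
                seen.add(cur)
            loops.append(loop)
        return loops

    def interior_mask(self) -> np.ndarray:
        cache = self.__dict__.setdefault("_cache", {})
        if "interior" not in cache:
            m = np.ones(self.n_vertices, dtype=bool)
            m[self.boundary_vertices()] = False
            cache["interior"] = m
        return cache["interior"]

    def free_mask(self) -> np.ndarray:
        return ~self.fixed_mask

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles,
                               process=False)

    @staticmethod
    def from_trimesh(tm: trimesh.Trimesh, fixed=None) -> "TriangulatedMembrane":
        v = np.asarray(tm.vertices, dtype=float)
        f = np.asarray(tm.faces, dtype=np.int64)
        mask = np.zeros(len(v), dtype=bool) if fixed is None else np.asarray(fixed, bool)
        return TriangulatedMembrane(v, f, mask)


# --------------------------------------------------------------------------
# geometric helpers


def _triangle_areas(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    n = np.cross(X[T[:, 1]] - X[T[:, 0]], X[T[:, 2]] - X[T[:, 0]])
    return 0.5 * np.linalg.norm(n, axis=1)


def min_triangle_angle(mesh: TriangulatedMembrane) -> float:
    """Smallest triangle corner angle in the mesh, degrees."""
    X, T = mesh.vertices, mesh.triangles
    angs = []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        u = X[T[:, b]] - X[T[:, a]]
        v = X[T[:, c]] - X[T[:, a]]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        angs.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return float(np.min(angs))


def _cotangents(X: np.ndarray, T: np.ndarray):
    """Per-triangle corner cotangents and twice-areas.

    Returns (cot_i, cot_j, cot_k, A2, u, v, w, nhat) with u = x_j - x_i,
    v = x_k - x_i, w = x_k - x_j and A2 = 2 * triangle area.
    """
    xi, xj, xk = X[T[:, 0]], X[T[:, 1]], X[T[:, 2]]
    u = xj - xi
    v = xk - xi
    w = xk - xj
    n = np.cross(u, v)
    A2 = np.linalg.norm(n, axis=1)
    bad = np.flatnonzero(A2 < 1e-300)
    if bad.size:
        raise DegenerateTriangleError(int(bad[0]))
    nhat = n / A2[:, None]
    cot_i = np.einsum("ij,ij->i", u, v) / A2
    cot_j = -np.einsum("ij,ij->i", u, w) / A2
    cot_k = np.einsum("ij,ij->i", v, w) / A2
    return cot_i, cot_j, cot_k, A2, u, v, w, nhat


def _scatter_add(indices: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Column-wise scatter-add via bincount (much faster than np.add.at)."""
    out = np.empty((n, values.shape[1]))
    for c in range(values.shape[1]):
        out[:, c] = np.bincount(indices, weights=values[:, c], minlength=n)
    return out


def _scatter_laplacian(T, cots, Y, n_vertices):
    """Apply the cotangent Laplacian built from per-triangle cots to Y."""
    cot_i, cot_j, cot_k = cots
    i, j, k = T[:, 0], T[:, 1], T[:, 2]
    # edge (j,k) carries cot_i/2, etc.
    cjk = 0.5 * cot_i[:, None] * (Y[j] - Y[k])
    cik = 0.5 * cot_j[:, None] * (Y[i] - Y[k])
    cij = 0.5 * cot_k[:, None] * (Y[i] - Y[j])
    idx = np.concatenate([j, k, i, k, i, j])
    val = np.concatenate([cjk, -cjk, cik, -cik, cij, -cij])
    return _scatter_add(idx, val, n_vertices)


def _barycentric_areas(T, A2, n_vertices):
    third = np.repeat(A2 / 6.0, 3)
    return np.bincount(T.ravel(), weights=third, minlength=n_vertices)


# --------------------------------------------------------------------------
# curvature field


@dataclass(frozen=True)
class CurvatureField:
    """Per-vertex total curvature J (signed, = 2H) and vertex areas.

    ``interior`` marks vertices where J is defined (non-boundary).  The
    vertex areas partition the surface: their sum equals the total mesh
    area for either area scheme.
    """

    J: np.ndarray
    area: np.ndarray
    interior: np.ndarray


def _mixed_voronoi_areas(X, T, n_vertices):
    """Meyer et al. obtuse-safe mixed areas."""
    cot_i, cot_j, cot_k, A2, u, v, w, _ = _cotangents(X, T)
    A = 0.5 * A2
    lu = np.einsum("ij,ij->i", u, u)   # |x_j - x_i|^2
    lv = np.einsum("ij,ij->i", v, v)   # |x_k - x_i|^2
    lw = np.einsum("ij,ij->i", w, w)   # |x_k - x_j|^2
    # Voronoi areas per corner (valid when triangle non-obtuse)
    vor_i = (lu * cot_k + lv * cot_j) / 8.0
    vor_j = (lu * cot_k + lw * cot_i) / 8.0
    vor_k = (lv * cot_j + lw * cot_i) / 8.0
    obtuse_i = cot_i < 0
    obtuse_j = cot_j < 0
    obtuse_k = cot_k < 0
    any_obtuse = obtuse_i | obtuse_j | obtuse_k
    area_i = np.where(any_obtuse, np.where(obtuse_i, A / 2.0, A / 4.0), vor_i)
    area_j = np.where(any_obtuse, np.where(obtuse_j, A / 2.0, A / 4.0), vor_j)
    area_k = np.where(any_obtuse, np.where(obtuse_k, A / 2.0, A / 4.0), vor_k)
    Av = np.zeros(n_vertices)
    np.add.at(Av, T[:, 0], area_i)
    np.add.at(Av, T[:, 1], area_j)
    np.add.at(Av, T[:, 2], area_k)
    return Av


def vertex_normals(X, T, n_vertices):
    fn = np.cross(X[T[:, 1]] - X[T[:, 0]], X[T[:, 2]] - X[T[:, 0]])
    vn = np.zeros((n_vertices, 3))
    for c in range(3):
        np.add.at(vn, T[:, c], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    return vn / norms[:, None]


def vertex_total_curvature(mesh: TriangulatedMembrane,
                           area: str = "mixed") -> CurvatureField:
    """Discrete total curvature J = 2H per vertex.

    Cotangent (area-gradient) formulation: the integrated mean-curvature
    vector is (L x)_v; J is its magnitude over the vertex area, signed by
    the projection onto the outward vertex normal.  Boundary vertices are
    excluded (J = 0, interior mask False).
    """
    X, T = mesh.vertices, mesh.triangles
    cot_i, cot_j, cot_k, A2, *_ = _cotangents(X, T)
    m = _scatter_laplacian(T, (cot_i, cot_j, cot_k), X, mesh.n_vertices)
    if area == "mixed":
        Av = _mixed_voronoi_areas(X, T, mesh.n_vertices)
    elif area == "barycentric":
        Av = _barycentric_areas(T, A2, mesh.n_vertices)
    else:
        raise ValueError("area must be 'mixed' or 'barycentric'")
    interior = mesh.interior_mask()
    vn = vertex_normals(X, T, mesh.n_vertices)
    sign = np.sign(np.einsum("ij,ij->i", m, vn))
    sign[sign == 0] = 1.0
    J = np.zeros(mesh.n_vertices)
    J[interior] = sign[interior] * np.linalg.norm(m[interior], axis=1) / Av[interior]
    return CurvatureField(J=J, area=Av, interior=interior)


# --------------------------------------------------------------------------
# energies


def energy_and_gradient(X: np.ndarray, mesh: TriangulatedMembrane,
                        kappa: float, gamma: float = 0.0,
                        energy_mask: Optional[np.ndarray] = None,
                        with_gradient: bool = True):
    """Discrete Helfrich + tension energy and its exact gradient.

    ``X`` are candidate vertex positions (same connectivity as ``mesh``).
    The bending sum runs over ``energy_mask`` vertices (default: all
    non-boundary vertices, which includes the fixed rim ring — the hinge
    term across the rim is what transmits the normal-continuity boundary
    condition to the free membrane).  The gradient is zeroed on fixed
    vertices.  Energies are in k_B T.
    """
    T = mesh.triangles
    nv = len(X)
    if energy_mask is None:
        energy_mask = mesh.interior_mask()
    cot_i, cot_j, cot_k, A2, u, v, w, nhat = _cotangents(X, T)
    A = 0.5 * A2
    m = _scatter_laplacian(T, (cot_i, cot_j, cot_k), X, nv)
    Av = _barycentric_areas(T, A2, nv)
    msq = np.einsum("ij,ij->i", m, m)
    E = energy_mask & (Av > 0)
    F_bend = 0.5 * kappa * float(np.sum(msq[E] / Av[E]))
    area_total = float(A.sum())
    F_tens = gamma * (area_total - mesh.area_ref) if gamma else 0.0
    F = F_bend + F_tens
    if not with_gradient:
        return F, None

    y = np.zeros((nv, 3))
    y[E] = m[E] / Av[E, None]
    p = np.zeros(nv)
    p[E] = msq[E] / Av[E] ** 2

    grad = kappa * _scatter_laplacian(T, (cot_i, cot_j, cot_k), y, nv)

    i, j, k = T[:, 0], T[:, 1], T[:, 2]
    xi, xj, xk = X[i], X[j], X[k]
    # dF/dw for the edge opposite each corner
    s_i = 0.5 * kappa * np.einsum("ij,ij->i", y[j] - y[k], xj - xk)  # * dcot_i
    s_j = 0.5 * kappa * np.einsum("ij,ij->i", y[i] - y[k], xi - xk)
    s_k = 0.5 * kappa * np.einsum("ij,ij->i", y[i] - y[j], xi - xj)

    # area gradients
    GAi = 0.5 * np.cross(nhat, w)
    GAj = -0.5 * np.cross(nhat, v)
    GAk = 0.5 * np.cross(nhat, u)

    inv = (1.0 / A2)[:, None]
    # cotangent-variation terms (the -cot * dA parts folded into qA below)
    gi = inv * (s_i[:, None] * (-(u + v)) + s_j[:, None] * w + s_k[:, None] * (-w))
    gj = inv * (s_i[:, None] * v + s_j[:, None] * (u - w) + s_k[:, None] * (-v))
    gk = inv * (s_i[:, None] * u + s_j[:, None] * (-u) + s_k[:, None] * (v + w))

    # combined coefficient on dA: tension + vertex-area variation + cot normalization
    qA = (gamma
          - (kappa / 6.0) * (p[i] + p[j] + p[k])
          - (2.0 / A2) * (s_i * cot_i + s_j * cot_j + s_k * cot_k))
    gi += qA[:, None] * GAi
    gj += qA[:, None] * GAj
    gk += qA[:, None] * GAk

    grad += _scatter_add(np.concatenate([i, j, k]),
                         np.concatenate([gi, gj, gk]), nv)
    grad[mesh.fixed_mask] = 0.0
    return F, grad


def bending_energy(mesh: TriangulatedMembrane, params=None, kappa: Optional[float] = None) -> float:
    """Helfrich bending energy of the mesh, k_B T (tension excluded)."""
    if kappa is None:
        kappa = params.kappa if params is not None else 20.0
    F, _ = energy_and_gradient(mesh.vertices, mesh, kappa, 0.0, with_gradient=False)
    return F


def tension_energy(mesh: TriangulatedMembrane, params) -> float:
    """gamma * (membrane area - flat reference area), k_B T."""
    if params.gamma == 0:
        return 0.0
    area = float(_triangle_areas(mesh.vertices, mesh.triangles).sum())
    return params.gamma * (area - mesh.area_ref)


def total_energy(mesh: TriangulatedMembrane, params) -> float:
    return bending_energy(mesh, params) + tension_energy(mesh, params)


# --------------------------------------------------------------------------
# regularization


def _edge_map(T: np.ndarray):
    """dict: sorted edge -> list of (triangle index, opposite corner slot)."""
    emap = {}
    for ti, (a, b, c) in enumerate(T):
        for (p, q, opp) in ((a, b, 2), (b, c, 0), (c, a, 1)):
            key = (p, q) if p < q else (q, p)
            emap.setdefault(key, []).append((ti, opp))
    return emap


def regularize(mesh: TriangulatedMembrane, passes: int = 2,
               smooth_weight: float = 0.5) -> TriangulatedMembrane:
    """Tangential vertex averaging plus edge-flip equiangulation.

    Free vertices are pulled toward their neighbor centroid with the normal
    component of the motion removed (so the shape, and hence the bending
    energy, changes only at discretization order); fixed vertices never
    move.  Edges failing the local Delaunay criterion are flipped when the
    flip does not touch a fixed-fixed edge.
    """
    out = mesh.copy()
    for _ in range(passes):
        _tangential_smooth(out, smooth_weight)
        _flip_pass(out)
    return out


def _tangential_smooth(mesh: TriangulatedMembrane, lam: float):
    X, T = mesh.vertices, mesh.triangles
    nv = mesh.n_vertices
    nbr_sum = np.zeros((nv, 3))
    nbr_cnt = np.zeros(nv)
    e = np.vstack([T[:, [0, 1]], T[:, [1, 2]], T[:, [2, 0]]])
    es = np.sort(e, axis=1)
    es = np.unique(es, axis=0)
    for a, b in ((0, 1), (1, 0)):
        np.add.at(nbr_sum, es[:, a], X[es[:, b]])
        np.add.at(nbr_cnt, es[:, a], 1.0)
    nbr_cnt[nbr_cnt == 0] = 1.0
    centroid = nbr_sum / nbr_cnt[:, None]
    delta = centroid - X
    vn = vertex_normals(X, T, nv)
    delta -= np.einsum("ij,ij->i", delta, vn)[:, None] * vn
    movable = mesh.free_mask().copy()
    movable[mesh.boundary_vertices()] = False   # keep boundary loops in place
    X[movable] += lam * delta[movable]


def _flip_pass(mesh: TriangulatedMembrane, angle_tol: float = 1e-3):
    X, T = mesh.vertices, mesh.triangles
    fixed = mesh.fixed_mask
    emap = _edge_map(T)
    used = np.zeros(len(T), dtype=bool)
    existing = set(map(tuple, np.sort(np.array(list(emap.keys())), axis=1))) if emap else set()
    for (a, b), tris in emap.items():
        if len(tris) != 2:
            continue
        (t1, o1), (t2, o2) = tris
        if used[t1] or used[t2]:
            continue
        if fixed[a] and fixed[b]:
            continue
        c = T[t1, o1]
        d = T[t2, o2]
        if c == d:
            continue
        # Delaunay criterion: sum of angles opposite the edge > pi
        def opp_angle(p, q, r):
            u_, v_ = X[p] - X[r], X[q] - X[r]
            cosang = np.dot(u_, v_) / (np.linalg.norm(u_) * np.linalg.norm(v_) + 1e-300)
            return np.arccos(np.clip(cosang, -1, 1))
        if opp_angle(a, b, c) + opp_angle(a, b, d) <= np.pi + angle_tol:
            continue
        key_new = (c, d) if c < d else (d, c)
        if key_new in existing:
            continue
        # orientation-preserving flip, keeping the winding of t1
        w1 = list(T[t1])
        # rotate so w1 = [a, b, c] or [b, a, c]
        while w1[2] != c:
            w1 = [w1[2], w1[0], w1[1]]
        if w1[0] == a:      # (a, b, c)
            T[t1] = [a, d, c]
            T[t2] = [d, b, c]
        else:               # (b, a, c)
            T[t1] = [b, d, c]
            T[t2] = [d, a, c]
        used[t1] = used[t2] = True
        existing.add(key_new)


def max_dihedral_angle(mesh: TriangulatedMembrane) -> float:
    """Maximum dihedral angle between adjacent triangles, degrees
    (0 for a flat mesh)."""
    tm = mesh.as_trimesh()
    if len(tm.face_adjacency_angles) == 0:
        return 0.0
    return float(np.degrees(tm.face_adjacency_angles.max()))


def error_estimate(mesh: TriangulatedMembrane,
                   level_energies: Optional[Sequence[float]] = None):
    """(max dihedral angle in degrees, energy error estimate in k_B T).

    The energy error is the difference between the two finest refinement
    levels' converged energies; with a single level it is undefined (nan).
    """
    dih = max_dihedral_angle(mesh)
    if level_energies is None or len(level_energies) < 2:
        return dih, float("nan")
    return dih, abs(float(level_energies[-1]) - float(level_energies[-2]))


# --------------------------------------------------------------------------
# IO: ASCII OFF / PLY with the fixed mask as a vertex scalar


def save_mesh(mesh: TriangulatedMembrane, path) -> None:
    path = str(path)
    if path.endswith(".off"):
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
            for p in mesh.vertices:
                fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    elif path.endswith(".ply"):
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("property uchar fixed\n")
            fh.write(f"element face {mesh.n_triangles}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for p, fx in zip(mesh.vertices, mesh.fixed_mask):
                fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g} {int(fx)}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    else:
        raise ValueError("mesh format must be .off or .ply")


def load_mesh(path) -> TriangulatedMembrane:
    path = str(path)
    if path.endswith(".off"):
        tm = trimesh.load(path, file_type="off", process=False)
        return TriangulatedMembrane.from_trimesh(tm)
    if path.endswith(".ply"):
        verts, faces, fixed = [], [], []
        with open(path) as fh:
            assert fh.readline().strip() == "ply"
            nv = nf = 0
            has_fixed = False
            for line in fh:
                line = line.strip()
                if line.startswith("element vertex"):
                    nv = int(line.split()[-1])
                elif line.startswith("element face"):
                    nf = int(line.split()[-1])
                elif line == "property uchar fixed":
                    has_fixed = True
                elif line == "end_header":
                    break
            for _ in range(nv):
                parts = fh.readline().split()
                verts.append([float(x) for x in parts[:3]])
                fixed.append(bool(int(parts[3])) if has_fixed else False)
            for _ in range(nf):
                parts = fh.readline().split()
                faces.append([int(x) for x in parts[1:4]])
        return TriangulatedMembrane(np.array(verts), np.array(faces),
                                    np.array(fixed, dtype=bool))
    raise ValueError("mesh format must be .off or .ply")
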