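"""Initial mesh construction and refinement.

The membrane patch is a large disc of radius L around the scaffold pair,
replacing a closed vesicle whose radius would exceed the scaffold size by
orders of magnitude: with tensionless bending the far field carries
negligible energy and the outer boundary is left free (natural, zero-moment
condition), which is verified by L-independence checks.

Around each scaffold the mesh carries two fixed rings embedded on the
analytic scaffold surface: the rim (the scaffold perimeter) and a collar at
offset ~h inside it.  The one-ring strip between them is rigid scaffold
surface; the bending penalty across the rim hinge enforces the
normal-continuity boundary condition to O(h).  Free membrane vertices start
in the plane z = 0 and are relaxed by the minimizer.  Vertex spacing grades
geometrically from h at the rims to ~0.2 r at radius r far away.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import (
    ModelParameters,
    PairConfiguration,
    RigidTransform,
    ScaffoldShape,
    place_pair,
    surface_height,
)
from .mesh import TriangulatedMembrane, regularize

__all__ = ["build_initial_mesh", "subdivide"]

_GROW = 1.3          # geometric growth of near-field ring offsets
_FAR_GROW = 0.22     # relative radial growth of far-field rings


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation
    return np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))


def _ensure_ccw(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return poly if area2 > 0 else poly[::-1]


def _points_in_convex_polygon(poly: np.ndarray, pts: np.ndarray,
                              shrink: float = 0.0) -> np.ndarray:
    """Vectorized containment test for a convex CCW polygon."""
    poly = _ensure_ccw(np.asarray(poly))
    c = poly.mean(axis=0)
    if shrink:
        poly = c + (poly - c) * (1.0 - shrink)
    e = np.roll(poly, -1, axis=0) - poly
    rel = pts[:, None, :] - poly[None, :, :]
    cross = e[None, :, 0] * rel[:, :, 1] - e[None, :, 1] * rel[:, :, 0]
    return np.all(cross > 0, axis=1)


def _resample_closed(poly: np.ndarray, n: int, stagger: float = 0.0) -> np.ndarray:
    seg = np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = (np.arange(n) + stagger) / n * total
    closed = np.vstack([poly, poly[:1]])
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def _offset_polygon(poly: np.ndarray, dist: float) -> np.ndarray:
    poly = _ensure_ccw(poly)
    tang = np.roll(poly, -1, axis=0) - np.roll(poly, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.c_[tang[:, 1], -tang[:, 0]]   # outward for CCW
    return poly + dist * normal


def _polygon_perimeter(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1).sum())


def _scaffold_rings(shape: ScaffoldShape, T: RigidTransform, h: float,
                    center_dist: float = 0.0):
    """Fixed collar+rim point sets (3D) and free offset rings (2D) for one
    scaffold placement.

    The free rings grade geometrically outward until their spacing matches
    the far-field (origin-centered) ring spacing at that location, so the
    triangulation has no abrupt resolution seam around off-center
    scaffolds.
    """
    per = _ellipse_perimeter(shape.r_a, shape.r_b)
    if per / h < 12:
        raise ValueError(
            f"mesh edge length h={h:g} too coarse to resolve the scaffold rim")
    n_rim = max(24, int(np.ceil(per / h)))
    t = np.linspace(0.0, 2 * np.pi, n_rim, endpoint=False)
    delta = min(0.5 * h, 0.4 * shape.r_b)

    def ring3d(dl):
        x = (shape.r_a - dl) * np.cos(t)
        y = (shape.r_b - dl) * np.sin(t)
        z = surface_height(shape, x, y)
        return T.apply(np.c_[x, y, z])

    collar3d = ring3d(delta)
    rim3d = ring3d(0.0)

    # free membrane rings offset outward from the projected rim
    rim_proj = rim3d[:, :2]
    extent_min = max(2.0 * shape.a_scale, 6 * h)
    rings2d = []
    poly = _resample_closed(rim_proj, n_rim)
    off, m, total = h, 0, 0.0
    while True:
        spacing = h * _GROW ** m
        if total >= extent_min:
            # stop once we match the global ring spacing at this location
            r_here = max(center_dist - shape.r_a - total, 2 * h)
            if spacing >= max(h, _FAR_GROW * r_here) or total > 2 * center_dist + extent_min:
                break
        poly = _offset_polygon(poly, off)
        n_m = max(16, int(round(_polygon_perimeter(poly) / spacing)))
        rings2d.append((_resample_closed(poly, n_m, stagger=0.5 * (m % 2)), spacing))
        total += off
        m += 1
        off = h * _GROW ** m
    return t, delta, collar3d, rim3d, rings2d, poly


def build_initial_mesh(shape: ScaffoldShape,
                       config: PairConfiguration | None,
                       params: ModelParameters,
                       single: bool = False) -> TriangulatedMembrane:
    """Planar annular mesh around the fixed scaffold patch(es).

    ``config=None`` (or ``single=True``) builds the single-scaffold mesh
    with the scaffold at the origin.  Rim and collar rings are embedded on
    the analytic scaffold surface and fixed; everything else starts flat at
    z = 0.
    """
    h = params.edge_length(shape)
    if config is None or single:
        placements = [RigidTransform(np.eye(3), np.zeros(3))]
        d = 0.0
    else:
        placements = list(place_pair(shape, config, clearance=2 * h))
        d = config.d
    L = params.domain_radius(d, shape)

    pts2d = []          # accepted 2D points
    tol_r = []          # dedupe radius per accepted point
    ids = {}            # role -> index arrays
    v_scaffold, v_delta, v_t = [], [], []

    def _accept(pts, spacing, scaffold=-1, dl=np.nan, tvals=None, dedupe=True):
        nonlocal pts2d, tol_r
        pts = np.atleast_2d(pts)
        keep = np.ones(len(pts), dtype=bool)
        if dedupe and pts2d:
            tree = cKDTree(np.vstack(pts2d))
            dmin, _ = tree.query(pts, k=1)
            keep = dmin > 0.45 * spacing
        idx0 = sum(len(p) for p in pts2d)
        kept = pts[keep]
        pts2d.append(kept)
        tol_r.extend([spacing] * len(kept))
        v_scaffold.extend([scaffold] * len(kept))
        v_delta.extend([dl] * len(kept))
        if tvals is None:
            v_t.extend([np.nan] * len(kept))
        else:
            v_t.extend(list(np.asarray(tvals)[keep]))
        return np.arange(idx0, idx0 + len(kept)), keep

    collar_polys, outer_polys, fixed3d = [], [], {}
    rim_ids, collar_ids = [], []
    for si, T in enumerate(placements):
        t, delta, collar3d, rim3d, rings2d, last_poly = _scaffold_rings(
            shape, T, h, center_dist=float(np.linalg.norm(T.t[:2])))
        cid, _ = _accept(collar3d[:, :2], h, scaffold=si, dl=delta, tvals=t, dedupe=False)
        rid, _ = _accept(rim3d[:, :2], h, scaffold=si, dl=0.0, tvals=t, dedupe=False)
        collar_ids.append(cid)
        rim_ids.append(rid)
        fixed3d[si] = (cid, collar3d, rid, rim3d)
        collar_polys.append(collar3d[:, :2])
        outer_polys.append(last_poly)
        for ring, spacing in rings2d:
            # clip ring points that stray into the partner scaffold's rim
            keepable = np.ones(len(ring), dtype=bool)
            for sj, Tj in enumerate(placements):
                if sj == si:
                    continue
                _, _, _, rimj, _, _ = _scaffold_rings(shape, Tj, h, center_dist=0.0)
                keepable &= ~_points_in_convex_polygon(rimj[:, :2], ring)
            _accept(ring[keepable], spacing)

    # far-field polar rings about the origin
    r = 2 * h
    m = 0
    radii = []
    while r < L:
        radii.append(r)
        r += max(h, _FAR_GROW * r)
    radii.append(L)
    outer_ring_ids = None
    for m, rk in enumerate(radii):
        spacing = max(h, _FAR_GROW * rk)
        n_k = max(12, int(round(2 * np.pi * rk / spacing)))
        ang = (np.arange(n_k) + 0.5 * (m % 2)) / n_k * 2 * np.pi
        ring = rk * np.c_[np.cos(ang), np.sin(ang)]
        inside_near = np.zeros(len(ring), dtype=bool)
        for poly in outer_polys:
            inside_near |= _points_in_convex_polygon(poly, ring)
        if rk == radii[-1]:
            idx, _ = _accept(ring, spacing, dedupe=False)
            outer_ring_ids = idx
        else:
            _accept(ring[~inside_near], spacing)

    P = np.vstack(pts2d)
    tri = Delaunay(P)
    T2 = tri.simplices
    cent = P[T2].mean(axis=1)
    keep = np.ones(len(T2), dtype=bool)
    for poly in collar_polys:
        keep &= ~_points_in_convex_polygon(poly, cent, shrink=1e-3)
    T2 = T2[keep]

    # drop orphaned vertices and remap
    used = np.unique(T2)
    remap = -np.ones(len(P), dtype=np.int64)
    remap[used] = np.arange(len(used))
    T2 = remap[T2]
    P = P[used]
    v_scaffold = np.asarray(v_scaffold)[used]
    v_delta = np.asarray(v_delta)[used]
    v_t = np.asarray(v_t)[used]

    V = np.c_[P, np.zeros(len(P))]
    fixed = np.zeros(len(P), dtype=bool)
    rim_rings, collar_rings = [], []
    for si in fixed3d:
        cid, collar3d, rid, rim3d = fixed3d[si]
        cid = remap[cid]
        rid = remap[rid]
        if np.any(cid < 0) or np.any(rid < 0):
            raise RuntimeError("scaffold ring vertex lost during triangulation")
        V[cid] = collar3d
        V[rid] = rim3d
        fixed[cid] = True
        fixed[rid] = True
        collar_rings.append(cid)
        rim_rings.append(rid)
    outer_ids = remap[outer_ring_ids]

    # flat projected reference area for the tension term
    e1 = P[T2[:, 1]] - P[T2[:, 0]]
    e2 = P[T2[:, 2]] - P[T2[:, 0]]
    area_ref = float(0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]).sum())

    mesh = TriangulatedMembrane(
        V, T2, fixed, rim_rings=rim_rings, collar_rings=collar_rings,
        outer_ids=outer_ids, area_ref=area_ref,
        meta=dict(shape=shape, placements=placements, h=h, L=L, level=0,
                  v_scaffold=v_scaffold, v_delta=v_delta, v_t=v_t),
    )
    return regularize(mesh, passes=2)


# --------------------------------------------------------------------------
# refinement


def subdivide(mesh: TriangulatedMembrane) -> TriangulatedMembrane:
    """1-to-4 midpoint subdivision; new rim/collar/strip vertices are
    reprojected onto the analytic scaffold surface and fixed."""
    meta = mesh.meta
    if "shape" not in meta:
        return _subdivide_plain(mesh)
    shape: ScaffoldShape = meta["shape"]
    placements = meta["placements"]
    v_sc = meta["v_scaffold"]
    v_dl = meta["v_delta"]
    v_t = meta["v_t"]

    V, T = mesh.vertices, mesh.triangles
    edges = np.vstack([T[:, [0, 1]], T[:, [1, 2]], T[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    nv = len(V)
    emap = {tuple(e): nv + i for i, e in enumerate(edges)}

    new_pts = np.empty((len(edges), 3))
    new_fixed = np.zeros(len(edges), dtype=bool)
    new_sc = -np.ones(len(edges), dtype=int)
    new_dl = np.full(len(edges), np.nan)
    new_t = np.full(len(edges), np.nan)
    for i, (a, b) in enumerate(edges):
        sa, sb = v_sc[a], v_sc[b]
        if sa >= 0 and sa == sb and mesh.fixed_mask[a] and mesh.fixed_mask[b]:
            ta, tb = v_t[a], v_t[b]
            dt = (tb - ta + np.pi) % (2 * np.pi) - np.pi
            tm = (ta + 0.5 * dt) % (2 * np.pi)
            dl = 0.5 * (v_dl[a] + v_dl[b])
            x = (shape.r_a - dl) * np.cos(tm)
            y = (shape.r_b - dl) * np.sin(tm)
            z = surface_height(shape, x, y)
            new_pts[i] = placements[sa].apply(np.array([x, y, z]))
            new_fixed[i] = True
            new_sc[i], new_dl[i], new_t[i] = sa, dl, tm
        else:
            new_pts[i] = 0.5 * (V[a] + V[b])

    V2 = np.vstack([V, new_pts])
    fixed2 = np.concatenate([mesh.fixed_mask, new_fixed])
    mids = {e: emap[e] for e in emap}

    def mid(a, b):
        return mids[(a, b) if a < b else (b, a)]

    tris = []
    for (a, b, c) in T:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        tris += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    T2 = np.asarray(tris, dtype=np.int64)

    sc2 = np.concatenate([v_sc, new_sc])
    dl2 = np.concatenate([v_dl, new_dl])
    t2 = np.concatenate([v_t, new_t])

    rim_rings, collar_rings = [], []
    for si in range(len(placements)):
        rsel = np.flatnonzero((sc2 == si) & fixed2 & (dl2 == 0.0))
        csel = np.flatnonzero((sc2 == si) & fixed2 & (dl2 > 0.0) &
                              np.isclose(dl2, np.nanmax(dl2[sc2 == si])))
        rim_rings.append(rsel[np.argsort(t2[rsel])])
        collar_rings.append(csel[np.argsort(t2[csel])])

    outer_set = set(int(i) for i in np.asarray(mesh.outer_ids).ravel())
    outer2 = list(outer_set)
    for i, (a, b) in enumerate(edges):
        if int(a) in outer_set and int(b) in outer_set:
            outer2.append(nv + i)
    out = TriangulatedMembrane(
        V2, T2, fixed2, rim_rings=rim_rings, collar_rings=collar_rings,
        outer_ids=np.array(sorted(outer2), dtype=int), area_ref=mesh.area_ref,
        meta=dict(meta, level=meta.get("level", 0) + 1,
                  v_scaffold=sc2, v_delta=dl2, v_t=t2),
    )
    return out


def _subdivide_plain(mesh: TriangulatedMembrane) -> TriangulatedMembrane:
    V, T = mesh.vertices, mesh.triangles
    edges = np.vstack([T[:, [0, 1]], T[:, [1, 2]], T[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    nv = len(V)
    emap = {tuple(e): nv + i for i, e in enumerate(edges)}
    new_pts = 0.5 * (V[edges[:, 0]] + V[edges[:, 1]])
    V2 = np.vstack([V, new_pts])
    fixed2 = np.concatenate([mesh.fixed_mask,
                             mesh.fixed_mask[edges[:, 0]] & mesh.fixed_mask[edges[:, 1]]])

    def mid(a, b):
        return emap[(a, b) if a < b else (b, a)]

    tris = []
    for (a, b, c) in T:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        tris += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    return TriangulatedMembrane(V2, np.asarray(tris, dtype=np.int64), fixed2,
                                area_ref=mesh.area_ref)
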