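import numpy as np
import pytest
import trimesh

from memscaffold.geometry import ModelParameters, ScaffoldShape
from memscaffold.mesh import TriangulatedMembrane


def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangulatedMembrane:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangulatedMembrane.from_trimesh(tm)


def make_flat_disc(radius: float = 5.0, h: float = 0.5) -> TriangulatedMembrane:
    """Flat triangulated disc in the z = 0 plane (polar rings + Delaunay)."""
    from scipy.spatial import Delaunay

    pts = [np.zeros(2)]
    r = h
    k = 0
    while r <= radius + 1e-9:
        n = max(6, int(round(2 * np.pi * r / h)))
        ang = (np.arange(n) + 0.5 * (k % 2)) / n * 2 * np.pi
        pts.append(np.c_[r * np.cos(ang), r * np.sin(ang)])
        r += h
        k += 1
    P = np.vstack(pts)
    tri = Delaunay(P)
    V = np.c_[P, np.zeros(len(P))]
    return TriangulatedMembrane(V, tri.simplices, np.zeros(len(P), dtype=bool))


def make_tube(radius: float = 1.0, length: float = 6.0, n_circ: int = 48,
              n_ax: int = 30) -> TriangulatedMembrane:
    """Open cylinder along z (two boundary loops)."""
    ang = np.arange(n_circ) / n_circ * 2 * np.pi
    zs = np.linspace(0.0, length, n_ax)
    V = []
    for i, z in enumerate(zs):
        off = 0.5 * (i % 2) * (2 * np.pi / n_circ)
        V.append(np.c_[radius * np.cos(ang + off), radius * np.sin(ang + off),
                       np.full(n_circ, z)])
    V = np.vstack(V)
    T = []
    for i in range(n_ax - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            if i % 2 == 0:
                T += [[a, b, c], [b, d, c]]
            else:
                T += [[a, b, d], [a, d, c]]
    return TriangulatedMembrane(V, np.asarray(T), np.zeros(len(V), dtype=bool))


def make_catenoid(c: float = 1.0, z_half: float = 1.0, n_circ: int = 64,
                  n_ax: int = 33) -> TriangulatedMembrane:
    """Catenoid patch r = c cosh(z/c), boundary rings fixed."""
    zs = np.linspace(-z_half, z_half, n_ax)
    ang = np.arange(n_circ) / n_circ * 2 * np.pi
    V = []
    for i, z in enumerate(zs):
        r = c * np.cosh(z / c)
        off = 0.5 * (i % 2) * (2 * np.pi / n_circ)
        V.append(np.c_[r * np.cos(ang + off), r * np.sin(ang + off),
                       np.full(n_circ, z)])
    V = np.vstack(V)
    T = []
    for i in range(n_ax - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            cc = (i + 1) * n_circ + j
            dd = (i + 1) * n_circ + (j + 1) % n_circ
            if i % 2 == 0:
                T += [[a, b, cc], [b, dd, cc]]
            else:
                T += [[a, b, dd], [a, dd, cc]]
    fixed = np.zeros(len(V), dtype=bool)
    fixed[:n_circ] = True
    fixed[-n_circ:] = True
    return TriangulatedMembrane(V, np.asarray(T), fixed)


@pytest.fixture(scope="session")
def icosphere3():
    return make_icosphere(3)


@pytest.fixture(scope="session")
def flat_disc():
    return make_flat_disc()


@pytest.fixture(scope="session")
def shallow_iso():
    return ScaffoldShape.shallow_circular(1.0)


@pytest.fixture(scope="session")
def shallow_saddle():
    return ScaffoldShape.shallow_circular(-1.0)


@pytest.fixture(scope="session")
def coarse_params():
    """Small, fast parameter set for unit tests (not production accuracy)."""
    return ModelParameters(L=60.0, h=0.45, max_iter=1500)
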