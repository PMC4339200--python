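import numpy as np
import pytest

from memscaffold.mesh import (
    TriangulatedMembrane,
    bending_energy,
    energy_and_gradient,
    error_estimate,
    load_mesh,
    max_dihedral_angle,
    min_triangle_angle,
    regularize,
    save_mesh,
    tension_energy,
    vertex_total_curvature,
)
from memscaffold.geometry import ModelParameters

from conftest import make_catenoid, make_flat_disc, make_icosphere, make_tube

EIGHT_PI_KAPPA = 8 * np.pi * 20.0


class TestCurvatureOperator:
    @pytest.mark.parametrize("radius", [1.0, 3.0])
    def test_sphere_total_curvature(self, radius):
        mesh = make_icosphere(3, radius)
        cf = vertex_total_curvature(mesh)
        assert np.allclose(cf.J, 2.0 / radius, rtol=1e-2)
        assert cf.interior.all()

    def test_flat_disc_interior_zero(self, flat_disc):
        cf = vertex_total_curvature(flat_disc)
        assert np.abs(cf.J[cf.interior]).max() < 1e-10

    def test_cylinder(self):
        mesh = make_tube(radius=2.0)
        cf = vertex_total_curvature(mesh)
        J = cf.J[cf.interior]
        assert np.allclose(J, 0.5, rtol=2e-2)

    def test_area_partition(self, icosphere3):
        tm = icosphere3.as_trimesh()
        for scheme in ("mixed", "barycentric"):
            cf = vertex_total_curvature(icosphere3, area=scheme)
            assert cf.area.sum() == pytest.approx(tm.area, rel=1e-10)

    def test_refinement_improves_accuracy(self):
        errs = []
        for sub in (2, 3):
            mesh = make_icosphere(sub, 1.0)
            cf = vertex_total_curvature(mesh)
            errs.append(np.abs(cf.J - 2.0).max())
        assert errs[1] < errs[0]


class TestBendingEnergy:
    @pytest.mark.parametrize("radius", [1.0, 2.5])
    def test_closed_sphere_invariant(self, radius):
        mesh = make_icosphere(4, radius)
        F = bending_energy(mesh, kappa=20.0)
        assert F == pytest.approx(EIGHT_PI_KAPPA, rel=1e-2)

    def test_flat_is_zero(self, flat_disc):
        assert bending_energy(flat_disc, kappa=20.0) == pytest.approx(0.0, abs=1e-18)

    def test_catenoid_vanishes_under_refinement(self):
        from memscaffold.meshing import _subdivide_plain
        coarse = make_catenoid(n_circ=32, n_ax=17)
        F_coarse = bending_energy(coarse, kappa=20.0)
        fine = make_catenoid(n_circ=64, n_ax=33)
        F_fine = bending_energy(fine, kappa=20.0)
        assert F_fine < F_coarse
        assert F_fine < 0.15  # k_B T, already small at modest resolution

    def test_rigid_motion_invariance(self, icosphere3):
        F0 = bending_energy(icosphere3, kappa=20.0)
        mesh = icosphere3.copy()
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        mesh.vertices = mesh.vertices @ R.T + np.array([3.0, -1.0, 2.0])
        assert bending_energy(mesh, kappa=20.0) == pytest.approx(F0, rel=1e-10)

    def test_scale_invariance_of_bending(self, icosphere3):
        F0 = bending_energy(icosphere3, kappa=20.0)
        mesh = icosphere3.copy()
        mesh.vertices = mesh.vertices * 3.7
        assert bending_energy(mesh, kappa=20.0) == pytest.approx(F0, rel=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        mesh = make_flat_disc(radius=2.0, h=0.5)
        mesh.vertices = mesh.vertices + 0.05 * rng.standard_normal(mesh.vertices.shape)
        F0, g = energy_and_gradient(mesh.vertices, mesh, kappa=20.0, gamma=0.3)
        eps = 1e-6
        for _ in range(12):
            i = rng.integers(mesh.n_vertices)
            c = rng.integers(3)
            Xp = mesh.vertices.copy()
            Xm = mesh.vertices.copy()
            Xp[i, c] += eps
            Xm[i, c] -= eps
            Fp, _ = energy_and_gradient(Xp, mesh, 20.0, 0.3, with_gradient=False)
            Fm, _ = energy_and_gradient(Xm, mesh, 20.0, 0.3, with_gradient=False)
            fd = (Fp - Fm) / (2 * eps)
            assert g[i, c] == pytest.approx(fd, rel=2e-4, abs=1e-7)


class TestTensionEnergy:
    def test_zero_gamma(self, flat_disc):
        params = ModelParameters(gamma=0.0)
        assert tension_energy(flat_disc, params) == 0.0

    def test_flat_reference_is_zero(self, flat_disc):
        params = ModelParameters(gamma=0.5)
        assert tension_energy(flat_disc, params) == pytest.approx(0.0, abs=1e-9)

    def test_scales_with_excess_area(self, icosphere3):
        mesh = icosphere3.copy()
        mesh.area_ref = mesh.area_ref / 2.0
        params = ModelParameters(gamma=0.25)
        tm = mesh.as_trimesh()
        assert tension_energy(mesh, params) == pytest.approx(0.25 * tm.area / 2)

    def test_tension_scales_quadratically_with_size(self, icosphere3):
        mesh = icosphere3.copy()
        mesh.area_ref = 0.0
        params = ModelParameters(gamma=1.0)
        F1 = tension_energy(mesh, params)
        mesh.vertices = mesh.vertices * 2.0
        assert tension_energy(mesh, params) == pytest.approx(4 * F1, rel=1e-10)


class TestRegularize:
    def test_uniform_flat_mesh_fixed_point(self, flat_disc):
        out = regularize(flat_disc, passes=1)
        # stays planar, boundary untouched
        assert np.abs(out.vertices[:, 2]).max() < 1e-12
        b = flat_disc.boundary_vertices()
        assert np.allclose(out.vertices[b], flat_disc.vertices[b])

    def test_skewed_mesh_min_angle_improves(self):
        rng = np.random.default_rng(3)
        mesh = make_flat_disc(radius=3.0, h=0.5)
        interior = mesh.interior_mask()
        mesh.vertices[interior, :2] += 0.17 * rng.standard_normal(
            (int(interior.sum()), 2))
        a0 = min_triangle_angle(mesh)
        out = regularize(mesh, passes=3)
        assert min_triangle_angle(out) > a0

    def test_energy_of_flat_shape_unchanged(self, flat_disc):
        out = regularize(flat_disc, passes=2)
        assert bending_energy(out, kappa=20.0) < 1e-12


class TestErrorEstimate:
    def test_flat_mesh(self, flat_disc):
        dih, err = error_estimate(flat_disc, [0.0, 0.0])
        assert dih == pytest.approx(0.0, abs=1e-4)
        assert err == 0.0

    def test_single_level_flagged(self, icosphere3):
        dih, err = error_estimate(icosphere3)
        assert np.isnan(err)
        assert dih > 0

    def test_refinement_shrinks_dihedral_and_error(self):
        dihs, Fs = [], []
        for sub in (2, 3, 4):
            m = make_icosphere(sub)
            dihs.append(max_dihedral_angle(m))
            Fs.append(bending_energy(m, kappa=20.0))
        assert dihs[2] < dihs[1] < dihs[0]
        _, e1 = error_estimate(make_icosphere(3), Fs[:2])
        _, e2 = error_estimate(make_icosphere(4), Fs[1:])
        assert e2 < e1


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["off", "ply"])
    def test_roundtrip(self, tmp_path, ext, flat_disc):
        mesh = flat_disc.copy()
        mesh.fixed_mask[:5] = True
        path = tmp_path / f"m.{ext}"
        save_mesh(mesh, path)
        back = load_mesh(path)
        assert back.n_vertices == mesh.n_vertices
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-9)
        assert np.array_equal(back.triangles, mesh.triangles)
        if ext == "ply":  # fixed mask travels as a vertex scalar in PLY
            assert np.array_equal(back.fixed_mask, mesh.fixed_mask)
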