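import numpy as np
import pytest

from memscaffold.geometry import ModelParameters, PairConfiguration, ScaffoldShape
from memscaffold.meshing import build_initial_mesh
from memscaffold.minimize import (MinimizedShape, minimize_configuration,
                                  minimize_shape, sweep_membrane_energy)

from conftest import make_flat_disc


@pytest.fixture(scope="module")
def fast_params():
    return ModelParameters(L=50.0, h=0.45, max_iter=1500)


class TestMinimizeShape:
    def test_flat_mesh_stays_flat(self):
        mesh = make_flat_disc(radius=4.0, h=0.6)
        # pin the boundary so the problem is well posed without scaffolds
        mesh.fixed_mask[mesh.boundary_vertices()] = True
        ms = minimize_shape(mesh, ModelParameters(max_iter=200))
        assert ms.F_m == pytest.approx(0.0, abs=1e-12)
        assert np.abs(ms.mesh.vertices[:, 2]).max() < 1e-9

    def test_single_isotropic_scaffold_relaxes_to_near_zero(self, shallow_iso,
                                                            fast_params):
        # a zero-mean-curvature (catenoid-matching) shape exists, so the
        # bending energy should be tiny at convergence
        ms = minimize_configuration(shallow_iso, None, fast_params)
        assert ms.F_m < 0.02
        assert ms.grad_norm < 1e-2

    def test_energy_history_monotone_within_stages(self, shallow_iso,
                                                   fast_params):
        ms = minimize_configuration(shallow_iso, PairConfiguration(d=4.0),
                                    fast_params)
        for stage in ms.energy_history:
            if len(stage) > 1:
                assert np.all(np.diff(stage) <= 1e-12)

    def test_deterministic(self, shallow_iso, fast_params):
        m1 = minimize_configuration(shallow_iso, PairConfiguration(d=5.0),
                                    fast_params)
        m2 = minimize_configuration(shallow_iso, PairConfiguration(d=5.0),
                                    fast_params)
        assert m1.F_m == m2.F_m
        assert np.array_equal(m1.mesh.vertices, m2.mesh.vertices)

    def test_mirror_symmetry_of_converged_shape(self, shallow_iso, fast_params):
        from scipy.interpolate import LinearNDInterpolator
        ms = minimize_configuration(shallow_iso, PairConfiguration(d=4.0),
                                    fast_params)
        V = ms.mesh.vertices
        interp = LinearNDInterpolator(V[:, :2], V[:, 2])
        sel = ms.mesh.free_mask() & (np.abs(V[:, 0]) < 15) & (
            np.linalg.norm(V[:, :2], axis=1) > 3.0)
        z_mirror = interp(-V[sel, 0], V[sel, 1])
        ok = np.isfinite(z_mirror)
        assert np.abs(V[sel, 2][ok] - z_mirror[ok]).max() < 5e-3

    def test_warm_start_agrees_with_cold(self, shallow_iso, fast_params):
        cold5 = minimize_configuration(shallow_iso, PairConfiguration(d=5.0),
                                       fast_params)
        cold6 = minimize_configuration(shallow_iso, PairConfiguration(d=6.0),
                                       fast_params)
        warm6 = minimize_configuration(shallow_iso, PairConfiguration(d=6.0),
                                       fast_params, warm_start=cold5)
        assert warm6.F_m == pytest.approx(cold6.F_m, abs=2e-3)

    def test_pair_repulsion_decreases_with_distance(self, shallow_iso,
                                                    fast_params):
        # isotropic scaffolds at fixed orientation: pure repulsion
        F = {}
        prev = None
        for d in (6.0, 5.0, 4.0):
            prev = minimize_configuration(shallow_iso, PairConfiguration(d=d),
                                          fast_params, warm_start=prev)
            F[d] = prev.F_m
        assert F[4.0] > F[5.0] > F[6.0] > 0


class TestSweep:
    def test_sweep_table_and_failure_recording(self, shallow_iso, fast_params):
        configs = [PairConfiguration(d=6.0), PairConfiguration(d=5.0),
                   PairConfiguration(d=2.05)]   # last one overlaps
        df = sweep_membrane_energy(shallow_iso, configs, fast_params)
        assert len(df) == 3
        assert df.F_m.notna()[:2].all()
        assert not df.converged.iloc[2]
        assert "overlap" in df.error.iloc[2]

    def test_reversed_order_changes_little(self, shallow_iso, fast_params):
        configs = [PairConfiguration(d=d) for d in (6.0, 4.5)]
        df1 = sweep_membrane_energy(shallow_iso, configs, fast_params)
        df2 = sweep_membrane_energy(shallow_iso, configs[::-1], fast_params)
        merged = df1.set_index("d").F_m - df2.set_index("d").F_m
        assert np.abs(merged.values).max() < 5e-3
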