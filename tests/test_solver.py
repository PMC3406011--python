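"""FE solver: kinematics, equilibrium, boundary conditions, isovolumic
constraint and the classical inflation benchmark."""

import numpy as np
import pytest

from lvmech.fibers import FiberField
from lvmech.fixtures import AnalyticMotion, make_motion
from lvmech.geometry import ML_TO_MM3
from lvmech.solver import FEModel, SolverError


@pytest.fixture(scope="module")
def lv_model(small_mesh, ss_field_small):
    return FEModel(small_mesh.cross_section, ss_field_small)


def axial_fiber_field(cs):
    basis = np.tile(np.eye(3), (cs.n_nodes, 1, 1))
    vec = np.tile(np.array([0.0, 0.0, 1.0]), (cs.n_nodes, 1))
    return FiberField(vectors=vec, basis=basis, provenance="parameterized-initial")


from cylinder_util import cylinder_setup as plane_strain_cylinder_model  # noqa: E402
from cylinder_util import pressure_exact as cylinder_pressure_exact  # noqa: E402


class TestKinematics:
    def test_uniform_scaling_patch(self, lv_model, small_mesh):
        """A uniform-scaling displacement field is reproduced exactly by the
        element kinematics: F = c*I at every quadrature point."""
        cs = small_mesh.cross_section
        c = 1.07
        U = np.zeros((cs.n_nodes, 3))
        U[:, 0] = (c - 1.0) * cs.R
        U[:, 2] = (c - 1.0) * cs.Z
        F = lv_model.deformation_gradient(U.ravel())
        assert np.allclose(F, c * np.eye(3), atol=1e-12)

    def test_twist_field_gradient(self, lv_model, small_mesh):
        """psi = c (Z - z0) produces exactly F = I + c r (e_theta x e_Z)."""
        cs = small_mesh.cross_section
        c = 0.01
        U = np.zeros((cs.n_nodes, 3))
        U[:, 1] = c * (cs.Z - cs.Z.min())
        F = lv_model.deformation_gradient(U.ravel())
        expected = np.tile(np.eye(3), (cs.n_elems, cs.nqp, 1, 1))
        expected[..., 1, 2] = c * cs.R_qp
        assert np.allclose(F, expected, atol=1e-12)

    def test_analytic_motion_fixture_agrees_with_element_route(self, small_mesh):
        """Closed-form F of the twist fixture matches the discrete
        shape-function evaluation at quadrature points."""
        from lvmech.fixtures import fd_deformation_gradient

        cs = small_mesh.cross_section
        mo = AnalyticMotion(kind="twist", amplitude=0.01,
                            times=np.linspace(0, 100, 5), z_ref=cs.Z.min())
        fields, F_nodes = make_motion(mo, cs)
        k = 2
        F_qp = fd_deformation_gradient(cs, fields["ur"][k:k + 1],
                                       fields["psi"][k:k + 1],
                                       fields["uz"][k:k + 1])
        c = mo.amplitude * mo.profile(mo.times)[k]
        expected = np.tile(np.eye(3), F_qp.shape[:2] + (1, 1))
        expected[..., 1, 2] = c * cs.R_qp
        assert np.allclose(F_qp, expected, atol=1e-10)


class TestEquilibrium:
    def test_zero_pressure_zero_displacement(self, small_mesh, ss_field_small):
        model = FEModel(small_mesh.cross_section, ss_field_small)
        U = model.solve_equilibrium(0.0)
        assert np.allclose(U, 0.0, atol=1e-10)

    def test_cavity_volume_operator_on_reference(self, small_mesh):
        cs = small_mesh.cross_section
        v = cs.cavity_volume_mm3() / ML_TO_MM3
        assert v == pytest.approx(small_mesh.params.cavity_volume, rel=0.005)

    def test_cavity_volume_gradient_consistent(self, lv_model, rng):
        """Analytic dV/du matches finite differences on random dofs."""
        model = lv_model
        U = np.zeros(model.n_dofs)
        g = model.cavity_volume_gradient(U)
        h = 1e-6
        for dof in rng.choice(np.flatnonzero(g), size=5, replace=False):
            Up, Um = U.copy(), U.copy()
            Up[dof] += h
            Um[dof] -= h
            fd = (model.cavity_volume(Up) - model.cavity_volume(Um)) / (2 * h)
            assert fd == pytest.approx(g[dof], rel=1e-6)

    def test_basal_boundary_conditions_hold(self, small_mesh, ss_field_small):
        """Axial displacement vanishes on the whole base plane; circumferential
        displacement vanishes on the basal endocardial ring."""
        model = FEModel(small_mesh.cross_section, ss_field_small)
        U = model.solve_equilibrium(1.0).reshape(-1, 3)
        cs = small_mesh.cross_section
        assert np.allclose(U[cs.base_nodes, 2], 0.0)
        assert U[cs.basal_endo_node, 1] == 0.0
        # but the basal surface can still move radially
        assert np.abs(U[cs.base_nodes, 0]).max() > 1e-3

    def test_inflation_pressure_volume_monotone(self, small_mesh, ss_field_small):
        """Passive p-V relation is strictly increasing (compliance > 0)."""
        model = FEModel(small_mesh.cross_section, ss_field_small)
        vols = []
        for p in [0.4, 0.8, 1.2]:
            U = model.solve_equilibrium(p)
            vols.append(model.cavity_volume(U))
        assert vols[0] < vols[1] < vols[2]


class TestIsovolumic:
    def test_fixed_point_returns_same_pressure(self, small_mesh, ss_field_small):
        model = FEModel(small_mesh.cross_section, ss_field_small)
        model.solve_equilibrium(0.9)
        V = model.cavity_volume(model.U) / ML_TO_MM3
        p0 = model.p_lv
        _, p = model.solve_isovolumic(V)
        assert p == pytest.approx(p0, abs=1e-3)

    def test_pressure_monotone_in_target_volume(self, small_mesh, ss_field_small):
        model = FEModel(small_mesh.cross_section, ss_field_small)
        model.solve_equilibrium(0.5)
        V0 = model.cavity_volume(model.U) / ML_TO_MM3
        ps = []
        for dv in [0.0, 3.0, 6.0]:
            _, p = model.solve_isovolumic(V0 + dv)
            ps.append(p)
        assert ps[0] < ps[1] < ps[2]

    def test_volume_constraint_tolerance(self, small_mesh, ss_field_small):
        model = FEModel(small_mesh.cross_section, ss_field_small)
        model.solve_equilibrium(0.5)
        V_target = model.cavity_volume(model.U) / ML_TO_MM3 + 4.0
        U, _ = model.solve_isovolumic(V_target)
        assert abs(model.cavity_volume(U) / ML_TO_MM3 - V_target) < 0.01


class TestCylinderBenchmark:
    def test_inflation_matches_closed_form(self):
        """Pressure-stretch of the nearly incompressible thick-walled
        cylinder agrees with the exact incompressible solution within 1% at
        three load levels."""
        cs, model = plane_strain_cylinder_model()
        for p_app in [0.2, 0.5, 1.0]:
            U = model.solve_equilibrium(p_app)
            ri = 10.0 + U.reshape(-1, 3)[cs.endo_nodes, 0].mean()
            p_ex = cylinder_pressure_exact(ri, model.passive)
            assert abs(p_app - p_ex) / p_app < 0.01
            J = np.linalg.det(model.deformation_gradient(U))
            assert np.abs(J - 1.0).max() < 0.005

    def test_incompressible_radius_map(self):
        """The deformed radii follow r^2 = R^2 + k across the wall."""
        cs, model = plane_strain_cylinder_model()
        U = model.solve_equilibrium(0.5).reshape(-1, 3)
        r = cs.R + U[:, 0]
        k = r**2 - cs.R**2
        assert np.ptp(k) < 0.01 * abs(k.mean())


class TestRobustness:
    def test_unattainable_volume_reported(self, small_mesh, ss_field_small):
        model = FEModel(small_mesh.cross_section, ss_field_small)
        with pytest.raises(SolverError):
            model.solve_isovolumic(-50.0)
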