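"""Postprocessing metrics: natural strains, stroke work density, torsion,
region statistics and shear."""

import numpy as np
import pytest

from lvmech.fixtures import AnalyticMotion, make_motion
from lvmech.postprocess import (PostprocessError, natural_fiber_strain,
                                read_torsion_csv, region_stats, section_rotation,
                                stroke_work_density, torsion, write_torsion_csv,
                                TorsionTrace)


class TestNaturalStrain:
    bounds = {"ejection": (2, 5)}

    def test_constant_stretch_gives_zero(self):
        lam = np.ones((6, 4))
        eps = natural_fiber_strain(lam, self.bounds, "ejection")
        assert np.allclose(eps, 0.0)

    def test_log_definition_exact(self):
        lam = np.ones((6, 1))
        lam[5] = np.exp(-1.0)
        eps = natural_fiber_strain(lam, {"ejection": (0, 5)}, "ejection")
        assert eps[0] == pytest.approx(-1.0, abs=1e-14)

    def test_additivity_over_subintervals(self, rng):
        lam = np.exp(rng.normal(0, 0.1, size=(9, 3)))
        full = natural_fiber_strain(lam, {"a": (1, 7)}, "a")
        part = (natural_fiber_strain(lam, {"a": (1, 4)}, "a")
                + natural_fiber_strain(lam, {"a": (4, 7)}, "a"))
        assert np.allclose(full, part, atol=1e-12)

    def test_missing_phase_raises(self):
        with pytest.raises(PostprocessError):
            natural_fiber_strain(np.ones((3, 1)), {}, "ejection")


class TestStrokeWorkDensity:
    def test_constant_stress_closed_loop_is_zero(self, rng):
        eps = np.concatenate([np.linspace(0, -0.1, 20), np.linspace(-0.1, 0, 20)])
        sig = np.full_like(eps, 13.0)
        assert stroke_work_density(sig[:, None], eps[:, None])[0] == pytest.approx(0.0, abs=1e-12)

    def test_rectangle_loop_exact(self):
        """sigma in [10, 20] kPa, eps in [-0.1, 0], work-producing traversal
        (counterclockwise in the strain-stress plane) -> area 1.0 kPa."""
        eps = np.array([0.0, 0.0, -0.1, -0.1, 0.0])
        sig = np.array([10.0, 20.0, 20.0, 10.0, 10.0])
        w = stroke_work_density(sig[:, None], eps[:, None])
        assert w[0] == pytest.approx(1.0, abs=1e-14)

    def test_discretized_ellipse_area(self):
        """1000-point ellipse loop: area within 0.1% of pi*a*b."""
        a, b = 0.08, 15.0
        th = np.linspace(0, 2 * np.pi, 1001)[:-1]
        eps = a * np.cos(th)
        sig = 30.0 + b * np.sin(th)  # counterclockwise in (eps, sig)... check sign
        w = stroke_work_density(sig[:, None], eps[:, None])[0]
        assert abs(abs(w) - np.pi * a * b) < 1e-3 * np.pi * a * b
        # counterclockwise traversal is work-producing (positive)
        assert w == pytest.approx(np.pi * a * b, rel=1e-3)

    def test_open_loop_warns(self):
        eps = np.linspace(0.0, -0.2, 10)
        sig = np.linspace(10.0, 20.0, 10)
        with pytest.warns(UserWarning):
            stroke_work_density(sig[:, None], eps[:, None])


class TestRegionStats:
    def test_uniform_field_zero_sd(self):
        m, sd = region_stats(np.full(7, 3.3), np.random.rand(7) + 0.1)
        assert m == pytest.approx(3.3) and sd == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        m, sd = region_stats(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert m == pytest.approx(1.0) and sd == pytest.approx(1.0)

    def test_volume_weighting_shifts_mean(self):
        """Doubling one point's weight reproduces the direct weighted-moment
        computation."""
        vals = np.array([1.0, 5.0])
        m, _ = region_stats(vals, np.array([2.0, 1.0]))
        assert m == pytest.approx((2 * 1.0 + 5.0) / 3.0)

    def test_empty_mask_raises(self):
        with pytest.raises(PostprocessError):
            region_stats(np.array([1.0]), np.array([1.0]), np.array([False]))


class TestTorsion:
    def test_rigid_rotation_gives_zero_everywhere(self, small_mesh):
        cs = small_mesh.cross_section
        mo = AnalyticMotion(kind="rigid_rotation", amplitude=0.3,
                            times=np.linspace(0, 800, 21))
        fields, _ = make_motion(mo, cs)
        tr = torsion(cs, fields["psi"], mo.times, reference_index=3)
        assert np.max(np.abs(tr.torsion)) < 1e-12

    def test_twist_field_analytic(self, small_mesh):
        """psi = c(t) z: every section's torsion equals -c(t) times its mean
        midwall radius (shear-angle normalization), exactly."""
        cs = small_mesh.cross_section
        mo = AnalyticMotion(kind="twist", amplitude=0.002,
                            times=np.linspace(0, 800, 21), z_ref=0.0)
        fields, _ = make_motion(mo, cs)
        ref = 0
        tr = torsion(cs, fields["psi"], mo.times, reference_index=ref)
        c = mo.amplitude * mo.profile(mo.times)
        # independent mean midwall radius per section from the node grid
        zg = cs.Z.reshape(cs.nj, cs.ni)
        rg = cs.R.reshape(cs.nj, cs.ni)
        mids = 0.5 * (tr.levels[:-1] + tr.levels[1:])
        rbar = np.array([
            np.mean([np.interp(zm, zg[:, i], rg[:, i]) for i in range(cs.ni)
                     if zg[0, i] <= zm <= zg[-1, i]])
            for zm in mids])
        expected = -np.outer(rbar, c - c[ref])
        assert np.allclose(tr.torsion, expected, atol=1e-10)

    def test_reference_time_exactly_zero(self, small_mesh):
        cs = small_mesh.cross_section
        rng = np.random.default_rng(3)
        psi = rng.normal(0, 0.05, size=(11, cs.n_nodes))
        tr = torsion(cs, psi, np.arange(11.0), reference_index=4)
        assert np.allclose(tr.torsion[:, 4], 0.0, atol=1e-15)

    def test_levels_outside_mesh_rejected(self, small_mesh):
        cs = small_mesh.cross_section
        with pytest.raises(PostprocessError):
            torsion(cs, np.zeros((3, cs.n_nodes)), np.arange(3.0), 0,
                    z_levels=np.array([cs.Z.min() - 5.0, 0.0]))

    def test_section_rotation_radial_average(self, small_mesh):
        """A rotation field linear in v averages to its midwall value."""
        cs = small_mesh.cross_section
        psi = (0.1 * cs.v)[None, :]
        z_mid = 0.5 * (cs.Z.min() + cs.Z.max())
        rot = section_rotation(cs, psi, np.array([z_mid]))
        assert abs(rot[0, 0]) < 0.02


class TestShear:
    def test_rigid_motion_zero_strain(self, small_mesh, ss_field_small):
        from lvmech.postprocess import circumferential_radial_shear
        from lvmech.solver import FEModel

        cs = small_mesh.cross_section
        model = FEModel(cs, ss_field_small)
        mo = AnalyticMotion(kind="rigid_rotation", amplitude=0.4,
                            times=np.linspace(0, 100, 4))
        fields, _ = make_motion(mo, cs)

        class C:  # minimal cycle shim
            ur, psi, uz = fields["ur"], fields["psi"], fields["uz"]

        tr = circumferential_radial_shear(model, C)
        assert np.max(np.abs(tr)) < 1e-12

    def test_green_strain_of_simple_shear(self):
        from lvmech.postprocess import green_strain_component

        gamma = 0.31
        F = np.eye(3)
        F[1, 2] = gamma  # shear of the t-plane into the c-direction
        e_c = np.array([0.0, 1.0, 0.0])
        e_t = np.array([0.0, 0.0, 1.0])
        assert green_strain_component(F, e_c, e_t) == pytest.approx(gamma / 2.0)

    def test_agreement_with_fd_gradient_oracle(self, rng):
        """E_ct from element kinematics matches a finite-difference F on a
        random smooth displacement field."""
        from lvmech.fixtures import fd_deformation_gradient
        from lvmech.postprocess import green_strain_component

        from lvmech.fixtures import cylinder_cross_section

        # rectangular cross-section: the parametric map is affine, so
        # quadratic fields in (R, Z) are represented exactly
        cs = cylinder_cross_section(10.0, 20.0, 15.0, n_r=3, n_z=2)
        a = 0.02 * rng.normal(size=3)
        ur = a[0] * (cs.R * cs.Z / 1000.0)[None, :]
        psi = a[1] * (cs.Z / 40.0)[None, :]
        uz = a[2] * (cs.R**2 / 1000.0)[None, :]
        F = fd_deformation_gradient(cs, ur, psi, uz)
        Fa = np.tile(np.eye(3), F.shape[:2] + (1, 1))
        Zq, Rq = cs.Z_qp, cs.R_qp
        rq = Rq + a[0] * Rq * Zq / 1000.0
        Fa[..., 0, 0] = 1.0 + a[0] * Zq / 1000.0
        Fa[..., 0, 2] = a[0] * Rq / 1000.0
        Fa[..., 1, 1] = rq / Rq
        Fa[..., 1, 2] = rq * a[1] / 40.0
        Fa[..., 2, 0] = a[2] * 2.0 * Rq / 1000.0
        assert np.allclose(F, Fa, atol=1e-8)


class TestTorsionCSV:
    def test_roundtrip(self, tmp_path):
        tr = TorsionTrace(t=np.linspace(0, 800, 9),
                          levels=np.linspace(-30, 15, 5),
                          torsion=np.random.default_rng(0).normal(size=(4, 9)),
                          reference_index=0)
        path = tmp_path / "tor.csv"
        write_torsion_csv(tr, path)
        t, tor = read_torsion_csv(path)
        assert np.allclose(t, tr.t)
        assert np.allclose(tor, tr.torsion)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(PostprocessError):
            read_torsion_csv(p)

    def test_comparison_plot_written(self, tmp_path):
        """Model-vs-reference torsion overlay renders to a file."""
        from lvmech.fixtures import TorsionSetParams, make_torsion_set
        from lvmech.postprocess import plot_torsion_comparison

        t, tor = make_torsion_set(TorsionSetParams(template="sit", noise_sd=0.01),
                                  seed=3)
        tr = TorsionTrace(t=t, levels=np.linspace(-30, 10, 5),
                          torsion=0.8 * tor, reference_index=0)
        out = tmp_path / "cmp.png"
        plot_torsion_comparison(tr, t, tor, out)
        assert out.exists() and out.stat().st_size > 1000
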