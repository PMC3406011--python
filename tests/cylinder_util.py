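"""Shared thick-walled cylinder benchmark setup and its closed-form oracle."""

import numpy as np
from scipy.integrate import quad

from lvmech.fibers import FiberField
from lvmech.fixtures import cylinder_cross_section
from lvmech.materials import PassiveParams
from lvmech.solver import FEModel


def cylinder_setup(n_r: int = 8, kappa: float = 2e4):
    """Plane-strain cylinder (psi and u_z constrained everywhere) with a
    numerically incompressible isotropic material."""
    cs = cylinder_cross_section(10.0, 20.0, 10.0, n_r=n_r, n_z=1)
    passive = PassiveParams(a0=0.5, a1=3.0, af=1e-12, bf=1.0, kappa=kappa)
    basis = np.tile(np.eye(3), (cs.n_nodes, 1, 1))
    ff = FiberField(np.tile(np.array([0.0, 0.0, 1.0]), (cs.n_nodes, 1)), basis,
                    "parameterized-initial")
    model = FEModel(cs, ff, passive=passive)
    extra = [d for n in range(cs.n_nodes) for d in (3 * n + 1, 3 * n + 2)]
    fixed = np.union1d(model.fixed_dofs, extra)
    model.fixed_dofs = fixed
    model.free_mask = np.ones(model.n_dofs, bool)
    model.free_mask[fixed] = False
    return cs, model


def pressure_exact(ri_def: float, passive: PassiveParams,
                   Ri: float = 10.0, Ro: float = 20.0) -> float:
    """Exact incompressible plane-strain inflation pressure at a given
    deformed inner radius, by 1D quadrature of the equilibrium integral."""

    def sig_diff(lam):
        def W(l):
            Et, Er = 0.5 * (l * l - 1.0), 0.5 * (l**-2 - 1.0)
            return passive.a0 * (np.exp(passive.a1 * (Et * Et + Er * Er)) - 1.0)

        h = 1e-6
        return lam * (W(lam + h) - W(lam - h)) / (2 * h)

    k = ri_def**2 - Ri**2
    ro = np.sqrt(Ro**2 + k)
    val, _ = quad(lambda r: sig_diff(r / np.sqrt(r * r - k)) / r, ri_def, ro,
                  limit=200)
    return val
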