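"""Quasi-static finite-element mechanics of the rotationally symmetric LV.

Unknowns per node of the wall cross-section are (u_r, psi, u_z): radial
displacement, azimuthal rotation angle and axial displacement.  The deformed
position of a material point (R, Phi, Z) is (R + u_r, Phi + psi, Z + u_z),
which retains circumferential motion (torsion) while keeping all fields
independent of Phi.  The deformation gradient in the two cylindrical
orthonormal frames is

        | 1 + du_r/dR      0        du_r/dZ  |
    F = | r dpsi/dR       r/R      r dpsi/dZ |     with r = R + u_r.
        | du_z/dR          0      1 + du_z/dZ|

Momentum balance (no body or inertial forces) is discretized with a Galerkin
method on biquadratic elements, with the circumferential integral performed
exactly; this is equivalent to one periodic tri-quadratic circumferential
element of 27-node hexahedra.  Boundary conditions: u_z = 0 on the whole
basal surface, psi = 0 on the basal endocardial ring, u_r = psi = 0 on the
long axis, traction-free epicardium, uniform cavity pressure p_lv on the
endocardium applied through the exact cavity-volume potential -p_lv V(u).

During isovolumic phases p_lv is an additional unknown determined by the
constraint V(u) = V_target (a bordered Newton system); during filling and
ejection the same constraint couples V to the circulation flow implicitly.

Note: u_r is constrained to 0 on the axis together with psi; psi there only
parameterizes a vanishing physical displacement but is kept fixed to avoid an
indeterminate interpolation weight.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .circulation import (CirculationParams, CirculationState, PhaseLabel,
                          apply_valve_flows, detect_phase, phase_flow)
from .fibers import FiberField, fibers_at_qps
from .geometry import CrossSection, GAUSS3_X, GAUSS3_W, ML_TO_MM3
from .materials import (ActiveParams, PassiveParams, SarcomereState,
                        first_piola_total)


class SolverError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class SolverConfig:
    newton_tol: float = 1e-7        # relative residual
    newton_maxit: int = 30
    max_substeps: int = 64          # automatic load substepping
    dt: float = 2.0                 # time step, ms
    pressure_tol: float = 1e-3      # kPa, isovolumic pressure root tolerance
    fd_step: float = 1e-6           # tangent finite-difference step on F

    def validate(self) -> None:
        if self.newton_tol <= 0 or self.dt <= 0:
            raise SolverError("tolerance and dt must be positive")


class FEModel:
    """Assembled LV (or generic axisymmetric) mechanics problem."""

    def __init__(self, cs: CrossSection, fiber_field: FiberField,
                 passive: PassiveParams = PassiveParams(),
                 active: ActiveParams = ActiveParams(),
                 config: SolverConfig = SolverConfig()):
        passive.validate()
        active.validate()
        config.validate()
        self.cs = cs
        self.passive = passive
        self.active = active
        self.config = config
        self.fiber_field = fiber_field
        self.set_fiber_field(fiber_field)
        self.n_dofs = 3 * cs.n_nodes

        # element dof indices (nel, 27): node-major, components (ur, psi, uz)
        edof = np.empty((cs.n_elems, 27), dtype=int)
        for a in range(9):
            for c in range(3):
                edof[:, 3 * a + c] = 3 * cs.conn[:, a] + c
        self.edof = edof
        self._rows = np.repeat(edof, 27, axis=1).ravel()
        self._cols = np.tile(edof, (1, 27)).ravel()

        # D operator: element dof -> local kinematic variables
        # q = (ur, ur_R, ur_Z, psi_R, psi_Z, uz_R, uz_Z)
        nel, nqp = cs.n_elems, cs.nqp
        D = np.zeros((nel, nqp, 7, 27))
        for a in range(9):
            D[:, :, 0, 3 * a + 0] = cs.shape_N[None, :, a]
            D[:, :, 1, 3 * a + 0] = cs.dNdR[:, :, a]
            D[:, :, 2, 3 * a + 0] = cs.dNdZ[:, :, a]
            D[:, :, 3, 3 * a + 1] = cs.dNdR[:, :, a]
            D[:, :, 4, 3 * a + 1] = cs.dNdZ[:, :, a]
            D[:, :, 5, 3 * a + 2] = cs.dNdR[:, :, a]
            D[:, :, 6, 3 * a + 2] = cs.dNdZ[:, :, a]
        self.D = D

        # Dirichlet set: base u_z, axis u_r & psi, basal endocardial ring psi
        fixed = set()
        for n in cs.base_nodes:
            fixed.add(3 * n + 2)
        for n in cs.axis_nodes:
            fixed.add(3 * n + 0)
            fixed.add(3 * n + 1)
        fixed.add(3 * cs.basal_endo_node + 1)
        self.fixed_dofs = np.array(sorted(fixed), dtype=int)
        self.free_mask = np.ones(self.n_dofs, dtype=bool)
        self.free_mask[self.fixed_dofs] = False

        # sarcomere state at quadrature points (reference: unit stretch)
        self.sarcomere = SarcomereState.resting(np.ones((nel, nqp)), active)
        self.U = np.zeros(self.n_dofs)
        self.p_lv = 0.0
        self.last_newton_iters = 0

    # -- fiber handling ---------------------------------------------------
    def set_fiber_field(self, field: FiberField) -> None:
        self.fiber_field = field
        self.fib_qp = fibers_at_qps(self.cs, field)  # (nel, nqp, 3)

    # -- kinematics -------------------------------------------------------
    def _gather(self, U: np.ndarray) -> tuple[np.ndarray, ...]:
        cs = self.cs
        Ue = U.reshape(-1, 3)[cs.conn]  # (nel, 9, 3)
        ur = np.einsum("qa,ea->eq", cs.shape_N, Ue[:, :, 0])
        ur_R = np.einsum("eqa,ea->eq", cs.dNdR, Ue[:, :, 0])
        ur_Z = np.einsum("eqa,ea->eq", cs.dNdZ, Ue[:, :, 0])
        ps_R = np.einsum("eqa,ea->eq", cs.dNdR, Ue[:, :, 1])
        ps_Z = np.einsum("eqa,ea->eq", cs.dNdZ, Ue[:, :, 1])
        uz_R = np.einsum("eqa,ea->eq", cs.dNdR, Ue[:, :, 2])
        uz_Z = np.einsum("eqa,ea->eq", cs.dNdZ, Ue[:, :, 2])
        return ur, ur_R, ur_Z, ps_R, ps_Z, uz_R, uz_Z

    def deformation_gradient(self, U: np.ndarray) -> np.ndarray:
        """F at quadrature points, shape (nel, nqp, 3, 3)."""
        cs = self.cs
        ur, ur_R, ur_Z, ps_R, ps_Z, uz_R, uz_Z = self._gather(U)
        r = cs.R_qp + ur
        F = np.zeros((cs.n_elems, cs.nqp, 3, 3))
        F[..., 0, 0] = 1.0 + ur_R
        F[..., 0, 2] = ur_Z
        F[..., 1, 0] = r * ps_R
        F[..., 1, 1] = r / cs.R_qp
        F[..., 1, 2] = r * ps_Z
        F[..., 2, 0] = uz_R
        F[..., 2, 2] = 1.0 + uz_Z
        return F

    def _piola(self, F: np.ndarray, t_a: float) -> np.ndarray:
        return first_piola_total(F, self.fib_qp, self.sarcomere.l_c, t_a,
                                 self.passive, self.active)

    # -- cavity volume and derivatives -----------------------------------
    def cavity_volume(self, U: np.ndarray) -> float:
        """Deformed cavity volume in mm^3 (disc method over the endocardium)."""
        Un = U.reshape(-1, 3)
        return self.cs.cavity_volume_mm3(ur=Un[:, 0], uz=Un[:, 2])

    def cavity_volume_gradient(self, U: np.ndarray) -> np.ndarray:
        cs = self.cs
        Un = U.reshape(-1, 3)
        r = cs.R + Un[:, 0]
        z = cs.Z + Un[:, 2]
        g = np.zeros(self.n_dofs)
        for edge in cs.endo_edges:
            re, ze = r[edge], z[edge]
            for xi, w in zip(GAUSS3_X, GAUSS3_W):
                L = np.array([0.5 * xi * (xi - 1.0), 1.0 - xi * xi, 0.5 * xi * (xi + 1.0)])
                dL = np.array([xi - 0.5, -2.0 * xi, xi + 0.5])
                rq, dzq = L @ re, dL @ ze
                g[3 * edge + 0] += np.pi * w * 2.0 * rq * dzq * L
                g[3 * edge + 2] += np.pi * w * rq * rq * dL
        return g

    def cavity_volume_hessian(self, U: np.ndarray) -> sp.csr_matrix:
        cs = self.cs
        Un = U.reshape(-1, 3)
        r = cs.R + Un[:, 0]
        z = cs.Z + Un[:, 2]
        rows, cols, vals = [], [], []
        for edge in cs.endo_edges:
            re, ze = r[edge], z[edge]
            Hrr = np.zeros((3, 3))
            Hrz = np.zeros((3, 3))
            for xi, w in zip(GAUSS3_X, GAUSS3_W):
                L = np.array([0.5 * xi * (xi - 1.0), 1.0 - xi * xi, 0.5 * xi * (xi + 1.0)])
                dL = np.array([xi - 0.5, -2.0 * xi, xi + 0.5])
                rq, dzq = L @ re, dL @ ze
                Hrr += np.pi * w * 2.0 * dzq * np.outer(L, L)
                Hrz += np.pi * w * 2.0 * rq * np.outer(L, dL)
            dr = 3 * edge + 0
            dz = 3 * edge + 2
            for a in range(3):
                for b in range(3):
                    rows += [dr[a], dr[a], dz[b]]
                    cols += [dr[b], dz[b], dr[a]]
                    vals += [Hrr[a, b], Hrz[a, b], Hrz[a, b]]
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n_dofs, self.n_dofs))

    # -- residual and tangent --------------------------------------------
    def _B_tensor(self, U: np.ndarray) -> np.ndarray:
        """dF/dq at quadrature points, shape (nel, nqp, 7, 3, 3)."""
        cs = self.cs
        ur, ur_R, ur_Z, ps_R, ps_Z, uz_R, uz_Z = self._gather(U)
        r = cs.R_qp + ur
        B = np.zeros((cs.n_elems, cs.nqp, 7, 3, 3))
        B[..., 0, 1, 0] = ps_R
        B[..., 0, 1, 1] = 1.0 / cs.R_qp
        B[..., 0, 1, 2] = ps_Z
        B[..., 1, 0, 0] = 1.0
        B[..., 2, 0, 2] = 1.0
        B[..., 3, 1, 0] = r
        B[..., 4, 1, 2] = r
        B[..., 5, 2, 0] = 1.0
        B[..., 6, 2, 2] = 1.0
        return B

    def internal_force(self, U: np.ndarray, t_a: float) -> np.ndarray:
        cs = self.cs
        F = self.deformation_gradient(U)
        P = self._piola(F, t_a)
        B = self._B_tensor(U)
        G = np.einsum("eqkij,eqij->eqk", B, P)
        fe = np.einsum("eq,eqk,eqkA->eA", cs.w_qp, G, self.D)
        f = np.zeros(self.n_dofs)
        np.add.at(f, self.edof.ravel(), fe.ravel())
        return f

    def residual(self, U: np.ndarray, p_lv: float, t_a: float) -> np.ndarray:
        return self.internal_force(U, t_a) - p_lv * self.cavity_volume_gradient(U)

    def tangent(self, U: np.ndarray, p_lv: float, t_a: float) -> sp.csc_matrix:
        cs = self.cs
        F = self.deformation_gradient(U)
        P = self._piola(F, t_a)
        # material tangent dP/dF by central differences, batched
        h = self.config.fd_step
        A = np.empty(F.shape[:2] + (3, 3, 3, 3))
        for i in range(3):
            for j in range(3):
                dF = np.zeros((3, 3))
                dF[i, j] = h
                Pp = self._piola(F + dF, t_a)
                Pm = self._piola(F - dF, t_a)
                A[..., i, j] = (Pp - Pm) / (2.0 * h)
        # reorder so A[..., i, j, m, n] = dP_ij / dF_mn
        A = np.moveaxis(A, (2, 3), (4, 5))
        B = self._B_tensor(U)
        M = np.einsum("eqkij,eqijmn,eqlmn->eqkl", B, A, B, optimize=True)
        # geometric coupling: d2F/(dur dpsi_R) and d2F/(dur dpsi_Z)
        M[..., 0, 3] += P[..., 1, 0]
        M[..., 3, 0] += P[..., 1, 0]
        M[..., 0, 4] += P[..., 1, 2]
        M[..., 4, 0] += P[..., 1, 2]
        T = np.einsum("eqkl,eqlB->eqkB", M, self.D, optimize=True)
        Ke = np.einsum("eq,eqkA,eqkB->eAB", cs.w_qp, self.D, T, optimize=True)
        K = sp.coo_matrix((Ke.ravel(), (self._rows, self._cols)),
                          shape=(self.n_dofs, self.n_dofs)).tocsc()
        if p_lv != 0.0:
            K = K - p_lv * self.cavity_volume_hessian(U)
        return K

    # -- linear algebra with constraints ---------------------------------
    def _apply_bc_matrix(self, K: sp.csc_matrix) -> sp.csc_matrix:
        mask = self.free_mask.astype(float)
        Dm = sp.diags(mask)
        K = Dm @ K @ Dm + sp.diags(1.0 - mask)
        return K.tocsc()

    def _masked(self, vec: np.ndarray) -> np.ndarray:
        out = vec.copy()
        out[~self.free_mask] = 0.0
        return out

    # -- equilibrium solvers ----------------------------------------------
    def solve_equilibrium(self, p_lv: float, t_a: float = -1.0,
                          U0: np.ndarray | None = None) -> np.ndarray:
        """Newton solve at prescribed cavity pressure, with automatic load
        substepping from the current pressure on non-convergence."""
        U = (self.U if U0 is None else U0).copy()
        p_from = self.p_lv
        n_sub = 1
        while n_sub <= self.config.max_substeps:
            ps = np.linspace(p_from, p_lv, n_sub + 1)[1:]
            Utry = U.copy()
            ok = True
            for p in ps:
                Utry, ok = self._newton(Utry, p, t_a)
                if not ok:
                    break
            if ok:
                self.U, self.p_lv = Utry, p_lv
                return Utry
            n_sub *= 2
        raise SolverError(f"equilibrium solve failed at p_lv={p_lv} kPa "
                          f"after {self.config.max_substeps} substeps")

    def _newton(self, U: np.ndarray, p_lv: float, t_a: float) -> tuple[np.ndarray, bool]:
        """Damped Newton with the affine-invariant (natural) monotonicity
        test: a trial step is accepted when the simplified Newton correction
        computed with the current factorization shrinks.  This is robust to
        the large transient residual spikes of the volumetric penalty."""
        cfg = self.config
        for it in range(cfg.newton_maxit):
            Rv = self._masked(self.residual(U, p_lv, t_a))
            ref = max(float(np.linalg.norm(self._masked(
                p_lv * self.cavity_volume_gradient(U)))), 1e-3 * self.n_dofs)
            rn = float(np.linalg.norm(Rv))
            if rn <= cfg.newton_tol * ref and it > 0:
                return U, True
            try:
                K = self._apply_bc_matrix(self.tangent(U, p_lv, t_a))
                lu = spla.splu(K)
                dU = lu.solve(-Rv)
            except Exception:
                return U, False
            if not np.all(np.isfinite(dU)):
                return U, False
            ndU = float(np.linalg.norm(dU))
            if ndU < 1e-12 * (1.0 + float(np.linalg.norm(U))):
                continue  # converged in the natural norm; top check returns
            accepted = False
            for step in (1.0, 0.5, 0.25, 0.125, 0.0625, 1.0 / 64.0):
                Un = U + step * dU
                try:
                    Rn = self._masked(self.residual(Un, p_lv, t_a))
                    nat = float(np.linalg.norm(lu.solve(-Rn)))
                except Exception:
                    continue
                if np.isfinite(nat) and nat < (1.0 - step / 2.0 + 1e-12) * ndU:
                    U = Un
                    accepted = True
                    break
            if not accepted:
                return U, False
        Rv = self._masked(self.residual(U, p_lv, t_a))
        ok = float(np.linalg.norm(Rv)) <= 10.0 * cfg.newton_tol * max(
            float(np.linalg.norm(self._masked(p_lv * self.cavity_volume_gradient(U)))), 1.0)
        return U, ok

    def solve_constrained(self, V_target_mm3: float, t_a: float,
                          dq_dp_mm3: float = 0.0, p_guess: float | None = None
                          ) -> tuple[np.ndarray, float]:
        """Bordered Newton for (U, p_lv) with V(U) - V_target(p_lv) = 0.

        ``V_target(p) = V_target_mm3 + dq_dp_mm3 * (p - p_guess)`` linearizes
        the circulation coupling (dq_dp_mm3 = dt * dq/dp in mm^3/kPa);
        isovolumic phases use dq_dp_mm3 = 0.
        """
        cfg = self.config
        U = self.U.copy()
        p = self.p_lv if p_guess is None else p_guess
        p_ref = p
        for it in range(cfg.newton_maxit):
            Rv = self._masked(self.residual(U, p, t_a))
            Vu = self._masked(self.cavity_volume_gradient(U))
            g = self.cavity_volume(U) - (V_target_mm3 + dq_dp_mm3 * (p - p_ref))
            ref = max(float(np.linalg.norm(self._masked(p * Vu))), 1.0)
            if (float(np.linalg.norm(Rv)) <= cfg.newton_tol * ref
                    and abs(g) < 1e-3 and it > 0):
                self.U, self.p_lv = U, p
                self.last_newton_iters = it
                return U, p
            K = self._apply_bc_matrix(self.tangent(U, p, t_a))
            lu = spla.splu(K)
            du0 = lu.solve(-Rv)
            du1 = lu.solve(Vu)
            denom = float(Vu @ du1) - dq_dp_mm3
            if abs(denom) < 1e-14:
                raise SolverError("singular bordered system (dV/dp ~ 0)")
            dp = (-g - float(Vu @ du0)) / denom
            dU = du0 + dp * du1
            # damp large pressure updates to keep the exponential law stable
            scale = 1.0
            if abs(dp) > 5.0:
                scale = 5.0 / abs(dp)
            # affine-invariant monotonicity test on the bordered natural
            # correction (pressure scaled to displacement units)
            c_p = 1.0
            nd = np.hypot(float(np.linalg.norm(dU)), c_p * dp)
            if nd < 1e-12 * (1.0 + float(np.linalg.norm(U))):
                continue
            accepted = False
            for frac in (1.0, 0.5, 0.25, 0.125, 0.0625, 1.0 / 64.0):
                step = frac * scale
                Un, pn = U + step * dU, p + step * dp
                try:
                    Rn = self._masked(self.residual(Un, pn, t_a))
                    gn = self.cavity_volume(Un) - (V_target_mm3 + dq_dp_mm3 * (pn - p_ref))
                    du0n = lu.solve(-Rn)
                    dpn = (-gn - float(Vu @ du0n)) / denom
                    nat = np.hypot(float(np.linalg.norm(du0n + dpn * du1)), c_p * dpn)
                except Exception:
                    continue
                if np.isfinite(nat) and nat < (1.0 - step / 2.0 + 1e-12) * nd:
                    U, p = Un, pn
                    accepted = True
                    break
            if not accepted:
                raise SolverError("constrained solve line search failed "
                                  f"(p={p:.3f} kPa, |g|={abs(g):.2e} mm^3)")
        raise SolverError(
            f"constrained solve did not converge (V_target={V_target_mm3 / ML_TO_MM3:.3f} mL, "
            f"last p={p:.4f} kPa, |g|={abs(g):.3e} mm^3)")

    def solve_isovolumic(self, V_target_ml: float, t_a: float = -1.0) -> tuple[np.ndarray, float]:
        """Equilibrium at fixed cavity volume; returns (U, p_lv)."""
        U, p = self.solve_constrained(V_target_ml * ML_TO_MM3, t_a, 0.0)
        if abs(self.cavity_volume(U) / ML_TO_MM3 - V_target_ml) > 0.01:
            raise SolverError("isovolumic volume constraint violated")
        return U, p

    # -- derived fields ---------------------------------------------------
    def fiber_stretch(self, F: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.einsum("eqij,eqj->eqi", F, self.fib_qp), axis=-1)

    def fiber_cauchy_stress(self, F: np.ndarray, t_a: float) -> np.ndarray:
        """Total fiber-direction Cauchy stress sigma_f = f_hat . sigma . f_hat."""
        from .materials import active_stress_magnitude, passive_stress
        sig_p = passive_stress(F, self.fib_qp, self.passive)
        f = np.einsum("eqij,eqj->eqi", F, self.fib_qp)
        lam = np.linalg.norm(f, axis=-1)
        fhat = f / lam[..., None]
        sig_f = np.einsum("eqi,eqij,eqj->eq", fhat, sig_p, fhat)
        sig_f = sig_f + active_stress_magnitude(self.sarcomere.l_c, lam * self.active.ls0,
                                                t_a, self.active)
        return sig_f

    def nodal_deformation_gradient(self, U: np.ndarray) -> np.ndarray:
        """F recovered at mesh nodes (averaged over adjacent elements)."""
        cs = self.cs
        Ue = U.reshape(-1, 3)[cs.conn]
        ur = np.einsum("qa,ea->eq", cs.nodal_N, Ue[:, :, 0])
        ur_R = np.einsum("eqa,ea->eq", cs.nodal_dNdR, Ue[:, :, 0])
        ur_Z = np.einsum("eqa,ea->eq", cs.nodal_dNdZ, Ue[:, :, 0])
        ps_R = np.einsum("eqa,ea->eq", cs.nodal_dNdR, Ue[:, :, 1])
        ps_Z = np.einsum("eqa,ea->eq", cs.nodal_dNdZ, Ue[:, :, 1])
        uz_R = np.einsum("eqa,ea->eq", cs.nodal_dNdR, Ue[:, :, 2])
        uz_Z = np.einsum("eqa,ea->eq", cs.nodal_dNdZ, Ue[:, :, 2])
        Rn = cs.R[cs.conn]
        r = Rn + ur
        hoop = np.where(Rn > 1e-9, r / np.where(Rn > 1e-9, Rn, 1.0), 1.0 + ur_R)
        Fe = np.zeros((cs.n_elems, 9, 3, 3))
        Fe[..., 0, 0] = 1.0 + ur_R
        Fe[..., 0, 2] = ur_Z
        Fe[..., 1, 0] = r * ps_R
        Fe[..., 1, 1] = hoop
        Fe[..., 1, 2] = r * ps_Z
        Fe[..., 2, 0] = uz_R
        Fe[..., 2, 2] = 1.0 + uz_Z
        # validity-weighted average: corner extrapolation on coarse elements
        # can invert; such contributions carry no weight
        det_e = np.linalg.det(Fe)
        w = (det_e > 0.05).astype(float)
        Fn = np.zeros((cs.n_nodes, 3, 3))
        count = np.zeros(cs.n_nodes)
        np.add.at(Fn, cs.conn.ravel(), (w[..., None, None] * Fe).reshape(-1, 3, 3))
        np.add.at(count, cs.conn.ravel(), w.ravel())
        no_valid = count < 0.5
        Fn[no_valid] = np.eye(3)
        count[no_valid] = 1.0
        return Fn / count[:, None, None]


# --------------------------------------------------------------------------
# cardiac cycle driver
# --------------------------------------------------------------------------

@dataclasses.dataclass
class CycleState:
    """Time-resolved record of one cardiac cycle."""

    t: np.ndarray                  # (n+1,), ms from activation onset
    p_lv: np.ndarray               # kPa
    V_lv: np.ndarray               # mL
    p_art: np.ndarray
    p_ven: np.ndarray
    q_mitral: np.ndarray           # (n,), mL/ms over each interval
    q_aortic: np.ndarray
    phase: list[PhaseLabel]        # (n,), phase of each interval
    lam_f: np.ndarray              # (n+1, nel, nqp) fiber stretch
    sig_f: np.ndarray              # (n+1, nel, nqp) fiber Cauchy stress, kPa
    psi: np.ndarray                # (n+1, n_nodes) rotation angle, rad
    uz: np.ndarray                 # (n+1, n_nodes) axial displacement, mm
    ur: np.ndarray                 # (n+1, n_nodes)
    F_nodal_ed: np.ndarray         # (n_nodes, 3, 3) at end-diastole
    F_nodal_ej: np.ndarray         # (n_ej_samples, n_nodes, 3, 3)
    newton_iters: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(0, dtype=int))  # (n,) per step

    @property
    def stroke_volume(self) -> float:
        """Ejected volume, mL (begin-ejection minus end-ejection volume)."""
        ej = [i for i, ph in enumerate(self.phase) if ph is PhaseLabel.EJECTION]
        if not ej:
            return 0.0
        return float(self.V_lv[ej[0]] - self.V_lv[ej[-1] + 1])

    @property
    def p_lv_max(self) -> float:
        return float(self.p_lv.max())

    @property
    def phase_bounds(self) -> dict[str, tuple[int, int]]:
        """First and one-past-last state index of each phase present."""
        out: dict[str, tuple[int, int]] = {}
        for i, ph in enumerate(self.phase):
            k = ph.value
            if k not in out:
                out[k] = (i, i + 1)
            else:
                out[k] = (out[k][0], i + 1)
        return out

    @property
    def begin_ejection_index(self) -> int:
        for i, ph in enumerate(self.phase):
            if ph is PhaseLabel.EJECTION:
                return i
        raise SolverError("cycle has no ejection phase")


def run_cardiac_cycle(model: FEModel, circ: CirculationState, dt: float | None = None,
                      n_ejection_samples: int = 5) -> tuple[CycleState, CirculationState]:
    """Simulate one cardiac cycle starting at activation onset (end-diastole).

    The model must hold a consistent end-diastolic state (U, p_lv) with
    ``circ.V_lv`` equal to the FE cavity volume.  Returns the cycle record
    and the advanced circulation state.
    """
    cfg = model.config
    dt = cfg.dt if dt is None else dt
    t_cycle = model.active.t_cycle
    n_steps = int(round(t_cycle / dt))
    cs = model.cs
    nel, nqp = cs.n_elems, cs.nqp

    V0 = model.cavity_volume(model.U) / ML_TO_MM3
    if abs(V0 - circ.V_lv) > 1e-3 * max(circ.V_lv, 1.0):
        raise SolverError("circulation V_lv inconsistent with FE cavity volume")

    t = np.zeros(n_steps + 1)
    p_lv = np.zeros(n_steps + 1)
    V_lv = np.zeros(n_steps + 1)
    p_art = np.zeros(n_steps + 1)
    p_ven = np.zeros(n_steps + 1)
    q_mit = np.zeros(n_steps)
    q_ao = np.zeros(n_steps)
    phases: list[PhaseLabel] = []
    lam_f = np.zeros((n_steps + 1, nel, nqp))
    sig_f = np.zeros((n_steps + 1, nel, nqp))
    psi = np.zeros((n_steps + 1, cs.n_nodes))
    uz = np.zeros((n_steps + 1, cs.n_nodes))
    ur = np.zeros((n_steps + 1, cs.n_nodes))
    n_iters = np.zeros(n_steps, dtype=int)

    # reset activation clock; contractile state carries over
    model.sarcomere.t_a = 0.0
    F = model.deformation_gradient(model.U)
    lam = model.fiber_stretch(F)
    model.sarcomere.l_s = lam * model.active.ls0

    p_lv[0] = model.p_lv
    V_lv[0] = V0
    p_art[0], p_ven[0] = circ.p_art, circ.p_ven
    lam_f[0] = lam
    sig_f[0] = model.fiber_cauchy_stress(F, 0.0)
    Un = model.U.reshape(-1, 3)
    ur[0], psi[0], uz[0] = Un[:, 0], Un[:, 1], Un[:, 2]
    F_nodal_ed = model.nodal_deformation_gradient(model.U)
    F_ej: list[np.ndarray] = []

    phase = PhaseLabel.IC
    for k in range(n_steps):
        t_new = (k + 1) * dt
        phase = detect_phase(phase, p_lv[k], circ.p_art, circ.p_ven,
                             at_activation_onset=False) if k > 0 else PhaseLabel.IC
        q, dqdp = phase_flow(phase, p_lv[k], circ.p_art, circ.p_ven, circ.params)
        V_target = (V_lv[k] + dt * q) * ML_TO_MM3
        try:
            U, p = model.solve_constrained(V_target, t_new,
                                           dq_dp_mm3=dt * dqdp * ML_TO_MM3,
                                           p_guess=p_lv[k])
        except SolverError:
            # stiff steps (large penalty, twitch onset): approach the volume
            # target in substeps from the last converged state
            V_prev = V_lv[k] * ML_TO_MM3
            n_sub = 8
            for s in range(1, n_sub + 1):
                Vt = V_prev + (V_target - V_prev) * s / n_sub
                U, p = model.solve_constrained(
                    Vt, t_new,
                    dq_dp_mm3=dt * dqdp * ML_TO_MM3 if s == n_sub else 0.0,
                    p_guess=model.p_lv)
        V_new = model.cavity_volume(U) / ML_TO_MM3
        q_net = (V_new - V_lv[k]) / dt
        # exact bookkeeping: the valve of the current phase carries the whole
        # volume change (isovolumic phases change V only by the constraint
        # tolerance, which is left on the FE side)
        qm = q_net if phase is PhaseLabel.FILLING else 0.0
        qa = -q_net if phase is PhaseLabel.EJECTION else 0.0
        circ = apply_valve_flows(circ, qm, qa, dt)
        circ.V_lv = V_new

        F = model.deformation_gradient(U)
        lam = model.fiber_stretch(F)
        _, model.sarcomere = _advance_sarcomere(model, lam, dt)
        t[k + 1] = t_new
        p_lv[k + 1] = p
        V_lv[k + 1] = V_new
        p_art[k + 1], p_ven[k + 1] = circ.p_art, circ.p_ven
        q_mit[k], q_ao[k] = qm, qa
        n_iters[k] = model.last_newton_iters
        phases.append(phase)
        lam_f[k + 1] = lam
        sig_f[k + 1] = model.fiber_cauchy_stress(F, t_new)
        Un = U.reshape(-1, 3)
        ur[k + 1], psi[k + 1], uz[k + 1] = Un[:, 0], Un[:, 1], Un[:, 2]
        if phase is PhaseLabel.EJECTION:
            F_ej.append(model.nodal_deformation_gradient(U))

    # thin the ejection samples to the requested count
    if F_ej:
        idx = np.unique(np.linspace(0, len(F_ej) - 1, min(n_ejection_samples, len(F_ej))).astype(int))
        F_nodal_ej = np.stack([F_ej[i] for i in idx])
    else:
        F_nodal_ej = np.zeros((0, cs.n_nodes, 3, 3))

    cycle = CycleState(t=t, p_lv=p_lv, V_lv=V_lv, p_art=p_art, p_ven=p_ven,
                       q_mitral=q_mit, q_aortic=q_ao, phase=phases,
                       lam_f=lam_f, sig_f=sig_f, psi=psi, uz=uz, ur=ur,
                       F_nodal_ed=F_nodal_ed, F_nodal_ej=F_nodal_ej,
                       newton_iters=n_iters)
    return cycle, circ


def _advance_sarcomere(model: FEModel, stretch: np.ndarray, dt: float):
    from .materials import active_stress_step
    return active_stress_step(model.sarcomere, stretch, dt, model.active)


def initialize_diastolic_state(model: FEModel, circ_params: CirculationParams
                               ) -> CirculationState:
    """Inflate the passive LV to the venous filling pressure and build the
    matching circulation state (the starting point of cycle 1)."""
    model.solve_equilibrium(circ_params.p_ven_init, t_a=-1.0)
    F = model.deformation_gradient(model.U)
    lam = model.fiber_stretch(F)
    model.sarcomere = SarcomereState.resting(lam, model.active)
    V0 = model.cavity_volume(model.U) / ML_TO_MM3
    return CirculationState.initial(circ_params, V0)
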