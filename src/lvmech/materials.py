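"""Myocardial constitutive behaviour.

Total Cauchy stress is the sum of a passive component and an active
component acting along the current (deformed) fiber direction:

    sigma = sigma_p(F) + sigma_a * (f_hat x f_hat),   f_hat = F e_f0 / |F e_f0|

Passive tissue is nonlinearly elastic, transversely isotropic and nearly
incompressible, modelled by a Fung-type strain energy

    W = a0 [exp(a1 * E:E) - 1] + af [exp(bf * E_ff^2) - 1] + kappa/2 (J - 1)^2

with E the Green-Lagrange strain and E_ff its fiber-fiber component.  The
active stress comes from a series arrangement of a contractile element
(length l_c) and a series elastic element: its magnitude depends on time
since activation t_a, sarcomere length l_s and the shortening velocity
through the contractile-element kinetics

    sigma_a = T0 * f_iso(l_c) * f_twitch(t_a, l_s) * E_a (l_s - l_c)
    dl_c/dt = (E_a (l_s - l_c) - 1) * v0

Activation is simultaneous throughout the wall.  All coefficients are
config-exposed model defaults (units: kPa, ms, micrometre), not measured
constants.
"""

from __future__ import annotations

import dataclasses

import numpy as np

_I3 = np.eye(3)


class MaterialError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PassiveParams:
    """Fung-type passive law coefficients (kPa where dimensional)."""

    a0: float = 0.5        # isotropic stiffness scale
    a1: float = 3.0        # isotropic exponential shape
    af: float = 0.01       # fiber reinforcement scale
    bf: float = 60.0       # fiber exponential shape
    kappa: float = 3000.0  # volumetric penalty (keeps |det F - 1| < 2% at
                           # end-systole of the full-resolution simulation)

    def validate(self) -> None:
        if min(self.a0, self.a1, self.af, self.bf, self.kappa) <= 0:
            raise MaterialError("passive coefficients must be positive")


@dataclasses.dataclass(frozen=True)
class ActiveParams:
    """Contractile/series-elastic active stress model.

    Twitch duration is length dependent, t_max = b_tw (l_s - l_d); the
    twitch shape is tanh^2 rise/decay.  ``t_cycle`` is the cardiac cycle
    time in ms.
    """

    T0: float = 250.0      # peak isometric stress scale, kPa
    a_len: float = 2.0     # length dependence steepness, 1/um
    lc0: float = 1.5       # zero-force contractile element length, um
    tau_r: float = 75.0    # twitch rise time constant, ms
    tau_d: float = 75.0    # twitch decay time constant, ms
    b_tw: float = 150.0    # twitch duration slope, ms/um
    l_d: float = -0.5      # twitch duration length intercept, um
    E_a: float = 20.0      # series element stiffness, 1/um
    v0: float = 0.0075     # unloaded shortening velocity, um/ms
    ls0: float = 1.9       # unloaded sarcomere length, um
    t_cycle: float = 800.0 # cycle time, ms
    ls_max: float = 3.0    # admissible sarcomere length bound, um
    ls_min: float = 1.0

    def validate(self) -> None:
        if self.T0 <= 0:
            raise MaterialError("T0 must be positive")
        if self.b_tw * (self.ls_max - self.l_d) >= self.t_cycle:
            raise MaterialError("twitch duration exceeds the cycle time")


@dataclasses.dataclass
class SarcomereState:
    """Internal contractile state at a set of material points."""

    l_c: np.ndarray   # contractile element length, um
    l_s: np.ndarray   # sarcomere length, um
    t_a: float        # time since activation onset, ms

    @classmethod
    def resting(cls, stretch: np.ndarray, params: ActiveParams) -> "SarcomereState":
        """State with the contractile element relaxed against the series
        element (the fixed point of the kinetics at zero activation)."""
        l_s = np.asarray(stretch, dtype=float) * params.ls0
        return cls(l_c=l_s - 1.0 / params.E_a, l_s=l_s.copy(), t_a=-1.0)

    def validate(self, params: ActiveParams) -> None:
        bad = (self.l_s < params.ls_min) | (self.l_s > params.ls_max)
        if np.any(bad):
            ids = np.flatnonzero(np.ravel(bad))[:5]
            raise MaterialError(f"sarcomere length out of physiological bounds at points {ids.tolist()}")


# --------------------------------------------------------------------------
# passive stress
# --------------------------------------------------------------------------

def strain_energy(F: np.ndarray, e_f0: np.ndarray, p: PassiveParams) -> np.ndarray:
    """Strain energy density (kPa) of the passive law; batched over leading axes."""
    F = np.asarray(F, dtype=float)
    C = np.einsum("...ki,...kj->...ij", F, F)
    E = 0.5 * (C - _I3)
    Q = np.einsum("...ij,...ij->...", E, E)
    Eff = np.einsum("...i,...ij,...j->...", e_f0, E, e_f0)
    J = np.linalg.det(F)
    return (p.a0 * (np.exp(p.a1 * Q) - 1.0)
            + p.af * (np.exp(p.bf * Eff**2) - 1.0)
            + 0.5 * p.kappa * (J - 1.0) ** 2)


def second_piola_passive(F: np.ndarray, e_f0: np.ndarray, p: PassiveParams) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise MaterialError("inverted element: det F <= 0")
    C = np.einsum("...ki,...kj->...ij", F, F)
    E = 0.5 * (C - _I3)
    Q = np.einsum("...ij,...ij->...", E, E)
    Eff = np.einsum("...i,...ij,...j->...", e_f0, E, e_f0)
    ff = np.einsum("...i,...j->...ij", e_f0, e_f0)
    Cinv = np.linalg.inv(C)
    S = (2.0 * p.a0 * p.a1 * np.exp(p.a1 * Q))[..., None, None] * E
    S = S + (2.0 * p.af * p.bf * Eff * np.exp(p.bf * Eff**2))[..., None, None] * ff
    S = S + (p.kappa * (J - 1.0) * J)[..., None, None] * Cinv
    return S


def passive_stress(F: np.ndarray, e_f0: np.ndarray, p: PassiveParams = PassiveParams()) -> np.ndarray:
    """Passive Cauchy stress (kPa); symmetric, zero at F = I, frame-indifferent."""
    S = second_piola_passive(F, e_f0, p)
    J = np.linalg.det(F)
    sig = np.einsum("...ik,...kl,...jl->...ij", F, S, F) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


# --------------------------------------------------------------------------
# active stress
# --------------------------------------------------------------------------

def _f_iso(l_c: np.ndarray, p: ActiveParams) -> np.ndarray:
    x = np.maximum(l_c - p.lc0, 0.0)
    return np.tanh(p.a_len * x) ** 2


def _f_twitch(t_a: float, l_s: np.ndarray, p: ActiveParams) -> np.ndarray:
    t_max = p.b_tw * (l_s - p.l_d)
    active = (t_a > 0.0) & (t_a < t_max)
    rise = np.tanh(np.maximum(t_a, 0.0) / p.tau_r) ** 2
    decay = np.tanh(np.maximum(t_max - t_a, 0.0) / p.tau_d) ** 2
    return np.where(active, rise * decay, 0.0)


def active_stress_magnitude(l_c: np.ndarray, l_s: np.ndarray, t_a: float,
                            p: ActiveParams) -> np.ndarray:
    """Scalar active fiber Cauchy stress (kPa); >= 0, zero before activation
    and after twitch end."""
    if t_a <= 0.0:
        return np.zeros(np.shape(l_s))
    se = np.maximum(p.E_a * (l_s - l_c), 0.0)
    return p.T0 * _f_iso(l_c, p) * _f_twitch(t_a, l_s, p) * se


def active_stress_step(state: SarcomereState, stretch: np.ndarray, dt: float,
                       p: ActiveParams = ActiveParams()) -> tuple[np.ndarray, SarcomereState]:
    """Advance the contractile state one step and return (sigma_a, new state).

    ``stretch`` is the fiber stretch lambda_f at the end of the step; the
    linear contractile-element kinetics are integrated exactly over dt with
    l_s frozen at its end-of-step value.
    """
    if dt <= 0.0:
        raise MaterialError("dt must be positive")
    l_s = np.asarray(stretch, dtype=float) * p.ls0
    new = SarcomereState(l_c=state.l_c.copy(), l_s=l_s, t_a=state.t_a + dt)
    new.validate(p)
    target = l_s - 1.0 / p.E_a
    decay = np.exp(-p.E_a * p.v0 * dt)
    new.l_c = target + (state.l_c - target) * decay
    sigma_a = active_stress_magnitude(new.l_c, new.l_s, new.t_a, p)
    return sigma_a, new


# --------------------------------------------------------------------------
# totals
# --------------------------------------------------------------------------

def total_stress(F: np.ndarray, e_f0: np.ndarray, sigma_a: np.ndarray | float,
                 p: PassiveParams = PassiveParams()) -> np.ndarray:
    """Total Cauchy stress: passive plus rank-one active along the deformed
    fiber direction."""
    F = np.asarray(F, dtype=float)
    sig = passive_stress(F, e_f0, p)
    f = np.einsum("...ij,...j->...i", F, e_f0)
    f = f / np.linalg.norm(f, axis=-1, keepdims=True)
    sig = sig + np.asarray(sigma_a)[..., None, None] * np.einsum("...i,...j->...ij", f, f)
    return sig


def first_piola_total(F: np.ndarray, e_f0: np.ndarray, l_c: np.ndarray, t_a: float,
                      passive: PassiveParams, active: ActiveParams) -> np.ndarray:
    """First Piola-Kirchhoff stress P = J sigma F^{-T} for the solver.

    The active magnitude is evaluated at the sarcomere length implied by F
    (l_s = |F e_f0| * ls0) with the contractile length l_c frozen, so the
    length dependence enters the consistent tangent.
    """
    F = np.asarray(F, dtype=float)
    S = second_piola_passive(F, e_f0, passive)
    P = np.einsum("...ik,...kj->...ij", F, S)
    f = np.einsum("...ij,...j->...i", F, e_f0)
    lam = np.linalg.norm(f, axis=-1)
    sigma_a = active_stress_magnitude(l_c, lam * active.ls0, t_a, active)
    # J sigma_a (f_hat x f_hat) F^{-T} = sigma_a / lam^2 * J * (F ef0)(F ef0) F^{-T}
    #   and (F ef0) F^{-T} applied: J F^{-T} ... keep explicit inverse (batched)
    if np.any(sigma_a > 0.0):
        J = np.linalg.det(F)
        FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)
        fhat = f / lam[..., None]
        P = P + (sigma_a * J)[..., None, None] * np.einsum(
            "...i,...k,...kj->...ij", fhat, fhat, FinvT)
    return P
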