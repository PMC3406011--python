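"""Synthetic inputs for testing every pipeline stage without external data.

Three families:

* analytic motion fields (rigid rotation, twist, incompressible radial
  inflation, simple shear) with closed-form deformation gradients, sampled
  on a mesh — oracles for kinematics, postprocessing and the solver;
* simple axisymmetric meshes (thick-walled cylinder cross-sections) for
  classical finite-elasticity benchmark solutions;
* MRT-like torsion trace sets: four cyclic section traces with optional
  additive noise and an end-of-cycle drift emulating tag fading, in the
  torsion CSV interchange format.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import CrossSection


class FixtureError(ValueError):
    pass


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

def cylinder_cross_section(r_inner: float = 10.0, r_outer: float = 20.0,
                           height: float = 10.0, n_r: int = 4, n_z: int = 2
                           ) -> CrossSection:
    """Structured cross-section of a thick-walled cylinder (annulus) for
    axisymmetric benchmark problems.  The inner edge plays the role of the
    pressurized 'endocardium'; the top edge is the 'base'."""
    if r_inner <= 0 or r_outer <= r_inner:
        raise FixtureError("need 0 < r_inner < r_outer")
    ni, nj = 2 * n_r + 1, 2 * n_z + 1
    v = np.linspace(-1.0, 1.0, ni)
    u = np.linspace(-1.0, 1.0, nj)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    R = r_inner + (vv + 1.0) / 2.0 * (r_outer - r_inner)
    Z = (uu + 1.0) / 2.0 * height
    cs = CrossSection(R.ravel(), Z.ravel(), uu.ravel(), vv.ravel(), n_r, n_z)
    cs.finalize()
    return cs


# --------------------------------------------------------------------------
# analytic motions
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AnalyticMotion:
    """Closed-form motion on an axisymmetric mesh.

    ``kind`` is one of 'rigid_rotation', 'twist', 'radial_inflation',
    'simple_shear'; ``amplitude`` scales the motion and ``profile(t)`` is a
    dimensionless time profile evaluated on ``times`` (ms).
    """

    kind: str
    amplitude: float
    times: np.ndarray
    z_ref: float = 0.0      # twist reference height

    def profile(self, t: np.ndarray) -> np.ndarray:
        # half-sine over the sampled span: starts and ends at zero
        t = np.asarray(t, dtype=float)
        span = self.times[-1] - self.times[0]
        return np.sin(np.pi * (t - self.times[0]) / span) ** 2


def make_motion(motion: AnalyticMotion, cs: CrossSection
                ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Sample an analytic motion on mesh nodes.

    Returns ``(fields, F)`` where ``fields`` holds nodal (n_t, n_nodes)
    arrays 'ur', 'psi', 'uz' and ``F`` is the closed-form deformation
    gradient (n_t, n_nodes, 3, 3) in cylindrical components at the nodes.
    """
    t = motion.times
    c = motion.amplitude * motion.profile(t)     # (n_t,)
    n_t, n_n = t.size, cs.n_nodes
    ur = np.zeros((n_t, n_n))
    psi = np.zeros((n_t, n_n))
    uz = np.zeros((n_t, n_n))
    F = np.tile(np.eye(3), (n_t, n_n, 1, 1))
    R, Z = cs.R, cs.Z

    if motion.kind == "rigid_rotation":
        psi[:] = c[:, None]
    elif motion.kind == "twist":
        # rotation angle linear in height: psi = c * (Z - z_ref)
        psi[:] = c[:, None] * (Z - motion.z_ref)[None, :]
        F[:, :, 1, 2] = c[:, None] * R[None, :]
    elif motion.kind == "radial_inflation":
        # volume-preserving: r = sqrt(R^2 + k), k = c * r_ref^2
        k = c[:, None] * (R.min() if R.min() > 0 else R.max()) ** 2
        r = np.sqrt(R[None, :] ** 2 + k)
        ur[:] = r - R[None, :]
        F[:, :, 0, 0] = R[None, :] / r
        F[:, :, 1, 1] = r / np.where(R > 1e-12, R, 1.0)[None, :]
        # on-axis limit of r/R equals dr/dR there only for k=0; exclude axis
        if np.any(R < 1e-12):
            raise FixtureError("radial inflation fixture requires an off-axis mesh")
    elif motion.kind == "simple_shear":
        # axial shear: u_z = c * (R - R_min), shear in the r-z plane
        uz[:] = c[:, None] * (R - R.min())[None, :]
        F[:, :, 2, 0] = c[:, None] * np.ones(n_n)[None, :]
    else:
        raise FixtureError(f"unknown motion kind {motion.kind!r}")
    return {"ur": ur, "psi": psi, "uz": uz}, F


def fd_deformation_gradient(cs: CrossSection, ur: np.ndarray, psi: np.ndarray,
                            uz: np.ndarray) -> np.ndarray:
    """F at quadrature points from nodal displacement samples via the element
    shape functions — the discrete route, used to cross-check closed forms."""
    from .solver import FEModel  # local import to avoid a cycle at module load

    U = np.stack([ur, psi, uz], axis=-1).reshape(-1)
    shim = type("_Shim", (), {"cs": cs, "_gather": FEModel._gather})()
    return FEModel.deformation_gradient(shim, U)


# --------------------------------------------------------------------------
# MRT-like torsion traces
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TorsionSetParams:
    """Synthetic 4-section torsion trace set over one cycle.

    ``template`` 'ss' gives homogeneous sections; 'sit' grades the peak from
    an SS-like (negative) sign apically to an inverted (positive) sign
    basally.  ``noise_sd`` is additive Gaussian noise (rad); ``drift`` is an
    end-of-cycle offset (rad) emulating the loss of tag signal towards late
    filling (a drift-free trace returns to zero at cycle end).
    """

    template: str = "ss"
    amplitude: float = 0.10          # rad
    t_cycle: float = 800.0           # ms
    n_times: int = 80
    n_sections: int = 4
    noise_sd: float = 0.0
    drift: float = 0.0
    ejection_fraction_of_cycle: float = 0.25


def make_torsion_set(params: TorsionSetParams, seed: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Generate (t, torsion) with torsion shaped (n_sections, n_times).

    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, params.t_cycle, params.n_times)
    x = t / params.t_cycle
    # smooth cyclic base shape: rises during 'ejection', returns through zero
    base = -np.sin(np.pi * np.minimum(x / (2 * params.ejection_fraction_of_cycle), 1.0)) \
        * np.exp(-3.0 * np.maximum(x - 2 * params.ejection_fraction_of_cycle, 0.0))
    base = base - base[-1] * x        # exact return to zero at cycle end
    if params.template == "ss":
        weights = np.ones(params.n_sections)
    elif params.template == "sit":
        # apical section keeps the SS sign, basal sections invert
        weights = np.linspace(1.0, -1.0, params.n_sections)
    else:
        raise FixtureError(f"unknown template {params.template!r}")
    tor = params.amplitude * weights[:, None] * base[None, :]
    tor = tor + params.drift * x[None, :] ** 3
    if params.noise_sd > 0.0:
        tor = tor + rng.normal(0.0, params.noise_sd, tor.shape)
    return t, tor


def write_torsion_set(path, params: TorsionSetParams, seed: int) -> None:
    """Write a synthetic trace set in the torsion CSV interchange format."""
    import pandas as pd

    t, tor = make_torsion_set(params, seed)
    rows = [(t[k], s, tor[s, k]) for s in range(tor.shape[0]) for k in range(t.size)]
    df = pd.DataFrame(rows, columns=["time_ms", "section_id", "torsion_rad"])
    df.to_csv(path, index=False, float_format="%.9g")
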