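"""Function and deformation metrics of the simulated cycle.

Local myofiber function: phase-wise natural (logarithmic) fiber strains
eps = ln(lambda_end / lambda_begin) for isovolumic contraction, ejection and
isovolumic relaxation, and the stroke work density W_f, the area enclosed by
the myofiber Cauchy stress - natural strain loop over one cycle (kPa =
kJ/m^3, positive for a work-producing loop).  Global function: maximum LV
pressure and stroke volume.

Torsion: the base-to-apex gradient of rotation about the LV long axis, as a
shear angle in rad.  Four sections are bounded by five equidistant axial
levels; the torsion of a section is the radially averaged rotation
difference between its apical and basal bounding levels, scaled by the
section's mean midwall radius over the level separation (the tangent-plane
shear angle, the quantity tagging-derived torsion measures), referenced to
begin-ejection.  Rotation is measured about the apex-to-base axis
(right-handed), so normal ejection twist is negative.  Statistics over the
wall exclude the basal and apical element layers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .geometry import CrossSection
from .solver import CycleState, FEModel


class PostprocessError(ValueError):
    pass


# --------------------------------------------------------------------------
# region statistics
# --------------------------------------------------------------------------

def region_mask(cs: CrossSection) -> np.ndarray:
    """Quadrature-point mask for wall statistics: excludes the basal-most and
    apical-most element layers (kept whole if the mesh is too coarse)."""
    if cs.n_long >= 3:
        keep = (cs.elem_long_index > 0) & (cs.elem_long_index < cs.n_long - 1)
    else:
        keep = np.ones(cs.n_elems, dtype=bool)
    return np.repeat(keep[:, None], cs.nqp, axis=1)


def region_stats(values: np.ndarray, weights: np.ndarray,
                 mask: np.ndarray | None = None) -> tuple[float, float]:
    """Volume-weighted mean and SD of a quadrature-point field."""
    if mask is not None:
        values, weights = values[mask], weights[mask]
    if values.size == 0:
        raise PostprocessError("empty region mask")
    w = weights / weights.sum()
    mean = float(np.sum(w * values))
    var = float(np.sum(w * (values - mean) ** 2))
    return mean, np.sqrt(var)


# --------------------------------------------------------------------------
# strains and work
# --------------------------------------------------------------------------

def natural_fiber_strain(lam_f: np.ndarray, phase_bounds: dict[str, tuple[int, int]],
                         phase: str) -> np.ndarray:
    """ln(lambda_end / lambda_begin) over a named phase, per material point."""
    if phase not in phase_bounds:
        raise PostprocessError(f"cycle has no {phase} phase")
    i0, i1 = phase_bounds[phase]
    return np.log(lam_f[i1] / lam_f[i0])


def stroke_work_density(sig_f: np.ndarray, eps_f: np.ndarray,
                        closure_tol: float = 1e-3) -> np.ndarray:
    """Area of the (eps_f, sig_f) loop by trapezoidal integration.

    Arrays have time on the first axis; the loop is closed from the last to
    the first sample (an endpoint mismatch in strain larger than
    ``closure_tol`` triggers a warning, and the closing segment is included
    either way).  Positive for loops traversed counterclockwise in the
    (strain, stress) plane, i.e. work-producing.
    """
    gap = np.abs(eps_f[-1] - eps_f[0])
    if np.any(gap > closure_tol):
        import warnings
        warnings.warn(f"stress-strain loop not closed (max strain gap {gap.max():.2e}); "
                      "forcing closure", stacklevel=2)
    s = np.concatenate([sig_f, sig_f[:1]], axis=0)
    e = np.concatenate([eps_f, eps_f[:1]], axis=0)
    return -np.sum(0.5 * (s[1:] + s[:-1]) * np.diff(e, axis=0), axis=0)


def local_function(model: FEModel, cycle: CycleState,
                   mask: np.ndarray | None = None) -> dict[str, float]:
    """Mean/SD of the four local function metrics over the analysis region."""
    cs = model.cs
    if mask is None:
        mask = region_mask(cs)
    pb = cycle.phase_bounds
    eps_ic = natural_fiber_strain(cycle.lam_f, pb, "isovolumic_contraction")
    eps_ej = natural_fiber_strain(cycle.lam_f, pb, "ejection")
    eps_ir = natural_fiber_strain(cycle.lam_f, pb, "isovolumic_relaxation")
    wf = stroke_work_density(cycle.sig_f, np.log(cycle.lam_f))
    out: dict[str, float] = {}
    for name, field in [("eps_ic", eps_ic), ("eps_ej", eps_ej),
                        ("eps_ir", eps_ir), ("wf", wf)]:
        mean, sd = region_stats(field, cs.w_qp, mask)
        out[f"{name}_mean"] = mean
        out[f"{name}_sd"] = sd
    return out


# --------------------------------------------------------------------------
# torsion
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TorsionTrace:
    t: np.ndarray               # ms
    levels: np.ndarray          # bounding slice levels (z, mm), apex -> base
    torsion: np.ndarray         # (4, n_t) rad, referenced to begin-ejection
    reference_index: int

    @property
    def amplitude(self) -> float:
        """Largest absolute torsion over all sections and times."""
        return float(np.abs(self.torsion).max())


def section_rotation(cs: CrossSection, psi: np.ndarray, z_levels: np.ndarray) -> np.ndarray:
    """Radially averaged rotation angle at given axial (slice) levels.

    ``psi`` has shape (..., n_nodes); returns (..., n_levels).  Rotation at a
    level is interpolated from adjacent nodal points along each transmural
    node line of the reference mesh (material slice tracking), then averaged
    transmurally over the lines that reach the level.
    """
    psi = np.asarray(psi)
    psi_grid = psi.reshape(psi.shape[:-1] + (cs.nj, cs.ni))
    z_grid = cs.Z.reshape(cs.nj, cs.ni)
    out = np.zeros(psi.shape[:-1] + (len(z_levels),))
    for li, z in enumerate(z_levels):
        acc = None
        n_used = 0
        for i in range(cs.ni):
            zcol = z_grid[:, i]
            if z < zcol[0] or z > zcol[-1]:
                continue
            j = np.clip(np.searchsorted(zcol, z) - 1, 0, cs.nj - 2)
            tloc = (z - zcol[j]) / (zcol[j + 1] - zcol[j])
            vals = psi_grid[..., j, i] * (1 - tloc) + psi_grid[..., j + 1, i] * tloc
            acc = vals if acc is None else acc + vals
            n_used += 1
        if n_used == 0:
            raise PostprocessError(f"slice level z={z} intersects no transmural node line")
        out[..., li] = acc / n_used
    return out


def default_slice_levels(cs: CrossSection, n_sections: int = 4,
                         margin: float = 0.25) -> np.ndarray:
    """Equidistant axial slice levels between apex and base (apical first),
    inset by ``margin`` of the axial extent on either side.  The default
    margin keeps the apical slice above the apex cap, which rotates
    essentially as a rigid block and carries no torsion gradient."""
    z_lo, z_hi = cs.Z.min(), cs.Z.max()
    span = z_hi - z_lo
    return np.linspace(z_lo + margin * span, z_hi - margin * span, n_sections + 1)


def torsion(cs: CrossSection, psi_history: np.ndarray, t: np.ndarray,
            reference_index: int, z_levels: np.ndarray | None = None,
            n_sections: int = 4) -> TorsionTrace:
    """Section-wise torsion from the rotation-angle history.

    ``psi_history`` is (n_t, n_nodes).  Torsion of section i is the rotation
    of its apical bounding slice minus its basal bounding slice, zeroed at
    ``reference_index`` (begin-ejection).
    """
    if not (0 <= reference_index < psi_history.shape[0]):
        raise PostprocessError("reference time outside the cycle")
    if z_levels is None:
        z_levels = default_slice_levels(cs, n_sections)
    z_levels = np.asarray(z_levels, dtype=float)
    if z_levels.min() < cs.Z.min() - 1e-9 or z_levels.max() > cs.Z.max() + 1e-9:
        raise PostprocessError("slice levels outside the mesh")
    rot = section_rotation(cs, psi_history, z_levels)     # (n_t, n_levels)
    dphi = rot[:, :-1] - rot[:, 1:]                       # apical minus basal
    # shear-angle normalization: rotation gradient scaled by the section's
    # mean reference midwall radius, as in tagging-derived torsion — makes
    # sections of different radius comparable
    mid = 0.5 * (z_levels[:-1] + z_levels[1:])
    rbar = section_rotation(cs, cs.R[None, :], mid)[0]
    tor = dphi * (rbar / np.diff(z_levels))[None, :]
    tor = tor - tor[reference_index]
    return TorsionTrace(t=np.asarray(t), levels=z_levels, torsion=tor.T,
                        reference_index=reference_index)


def torsion_from_cycle(model: FEModel, cycle: CycleState, **kw) -> TorsionTrace:
    return torsion(model.cs, cycle.psi, cycle.t, cycle.begin_ejection_index, **kw)


# --------------------------------------------------------------------------
# shear
# --------------------------------------------------------------------------

def _qp_basis(model: FEModel) -> np.ndarray:
    """Local cardiac basis at quadrature points, (nel, nqp, 3(basis), 3)."""
    if getattr(model, "_qp_basis_cache", None) is None:
        from .fibers import local_basis_uv

        cs = model.cs
        mesh_like = _MeshView(cs)
        B = np.empty((cs.n_elems, cs.nqp, 3, 3))
        for e in range(cs.n_elems):
            for q in range(cs.nqp):
                B[e, q] = local_basis_uv(mesh_like, cs.u_qp[e, q], cs.v_qp[e, q])
        model._qp_basis_cache = B
    return model._qp_basis_cache


class _MeshView:
    """Minimal adapter exposing ``chart`` for basis evaluation."""

    def __init__(self, cs: CrossSection):
        if cs.chart is None:
            raise PostprocessError("cross-section carries no wall chart")
        self.chart = cs.chart
        self.cross_section = cs


def circumferential_radial_shear(model: FEModel, cycle: CycleState,
                                 mask: np.ndarray | None = None) -> np.ndarray:
    """Mean Green-Lagrange circumferential-transmural shear E_ct per time step."""
    cs = model.cs
    if mask is None:
        mask = region_mask(cs)
    basis = _qp_basis(model)
    e_c, e_t = basis[:, :, 0, :], basis[:, :, 2, :]
    n_t = cycle.psi.shape[0]
    out = np.empty(n_t)
    U = np.zeros((cs.n_nodes, 3))
    for k in range(n_t):
        U[:, 0], U[:, 1], U[:, 2] = cycle.ur[k], cycle.psi[k], cycle.uz[k]
        F = model.deformation_gradient(U.ravel())
        E = 0.5 * (np.einsum("eqki,eqkj->eqij", F, F) - np.eye(3))
        ect = np.einsum("eqi,eqij,eqj->eq", e_c, E, e_t)
        w = cs.w_qp[mask]
        out[k] = float(np.sum(ect[mask] * w) / w.sum())
    return out


def green_strain_component(F: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a . E . b with E the Green-Lagrange strain of F (for oracle tests)."""
    E = 0.5 * (np.einsum("...ki,...kj->...ij", F, F) - np.eye(3))
    return np.einsum("...i,...ij,...j->...", a, E, b)


# --------------------------------------------------------------------------
# torsion trace CSV interchange
# --------------------------------------------------------------------------

def write_torsion_csv(trace: TorsionTrace, path) -> None:
    """(time_ms, section_id, torsion_rad) long-format CSV; section 0 is apical."""
    rows = []
    for s in range(trace.torsion.shape[0]):
        for k in range(trace.t.size):
            rows.append((trace.t[k], s, trace.torsion[s, k]))
    pd.DataFrame(rows, columns=["time_ms", "section_id", "torsion_rad"]).to_csv(
        path, index=False)


def read_torsion_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time_ms, section_id, torsion_rad) CSV; returns (t, torsion)
    with torsion shaped (n_sections, n_t)."""
    df = pd.read_csv(path)
    need = {"time_ms", "section_id", "torsion_rad"}
    if not need.issubset(df.columns):
        raise PostprocessError(f"torsion CSV must have columns {sorted(need)}")
    sections = np.sort(df["section_id"].unique())
    t = np.sort(df["time_ms"].unique())
    tor = np.empty((sections.size, t.size))
    for i, s in enumerate(sections):
        sub = df[df["section_id"] == s].sort_values("time_ms")
        tor[i] = sub["torsion_rad"].to_numpy()
    return t, tor


def plot_torsion_comparison(model_trace: TorsionTrace, t_exp: np.ndarray,
                            tor_exp: np.ndarray, path) -> None:
    """Overlay model torsion with an external (e.g. tagging-derived) trace set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for s in range(model_trace.torsion.shape[0]):
        axes[0].plot(model_trace.t, model_trace.torsion[s], label=f"section {s}")
    for s in range(tor_exp.shape[0]):
        axes[1].plot(t_exp, tor_exp[s], label=f"section {s}")
    axes[0].set_title("model")
    axes[1].set_title("reference")
    for ax in axes:
        ax.set_xlabel("time [ms]")
        ax.axhline(0.0, color="k", lw=0.5)
    axes[0].set_ylabel("torsion [rad]")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
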