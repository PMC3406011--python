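"""Myofiber orientation fields.

Fiber direction at a material point is described in the local cardiac basis
{e_c0, e_l0, e_t0} (circumferential, longitudinal, transmural, unloaded
state) by the helix angle alpha_h (between e_c0 and the projection of the
fiber onto the circumferential-longitudinal plane) and the transverse angle
alpha_t (between e_c0 and the projection onto the circumferential-transmural
plane).  Vectors carry components in the cylindrical frame (e_R, e_Phi, e_Z)
of the rotationally symmetric mesh.

The normal (Situs Solitus, SS) field is a parameterized transmural helix
distribution with zero transverse angle.  The Situs Inversus Totalis (SIT)
initial field equals the SS field apically and its inversion
``alpha_h -> -alpha_h`` basally, blended linearly across a transition zone
described by midwall location u_t, endo-epi slope and height.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import Mesh, CrossSection


class FiberError(ValueError):
    pass


# --------------------------------------------------------------------------
# local cardiac basis
# --------------------------------------------------------------------------

def local_basis_uv(mesh: Mesh, u: float, v: float, h: float = 1e-4) -> np.ndarray:
    """Local cardiac basis at chart point (u, v).

    Returns a 3x3 matrix with rows (e_c0, e_l0, e_t0) in cylindrical
    components (R, Phi, Z).  At the apex pole (u = -1) the basis is the
    limit along the meridian (e_l0 radially outward, e_t0 axially outward).
    """
    chart = mesh.chart
    u = float(np.clip(u, -1.0, 1.0))
    # meridian tangent by central/one-sided FD in u on the constant-v curve
    u0 = min(max(u, -1.0 + h), 1.0 - h)
    p_plus = chart.point(u0 + h, v)
    p_minus = chart.point(u0 - h, v)
    t = p_plus - p_minus
    nrm = np.linalg.norm(t)
    if nrm < 1e-14:
        raise FiberError("degenerate meridian tangent")
    t = t / nrm
    e_l0 = np.array([t[0], 0.0, t[1]])
    # outward transmural normal: rotate e_l0 by -90 deg in the (R, Z) plane
    e_t0 = np.array([t[1], 0.0, -t[0]])
    e_c0 = np.array([0.0, 1.0, 0.0])
    return np.stack([e_c0, e_l0, e_t0])


def local_basis_nodes(cs: CrossSection, mesh: Mesh) -> np.ndarray:
    """(n_nodes, 3, 3) basis at every cross-section node."""
    out = np.empty((cs.n_nodes, 3, 3))
    for n in range(cs.n_nodes):
        out[n] = local_basis_uv(mesh, cs.u[n], cs.v[n])
    return out


# --------------------------------------------------------------------------
# angle <-> vector conversion
# --------------------------------------------------------------------------

def angles_to_vector(alpha_h: np.ndarray, alpha_t: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Unit fiber vector(s) from helix/transverse angles and local basis.

    ``basis`` has rows (e_c0, e_l0, e_t0).  The fiber is the unit vector
    whose in-plane projections make angles alpha_h and alpha_t with e_c0;
    alpha_h = +/-pi/2 is only admissible with alpha_t = 0 (fiber = +/-e_l0).
    """
    alpha_h = np.asarray(alpha_h, dtype=float)
    alpha_t = np.asarray(alpha_t, dtype=float)
    on_pole = np.abs(np.abs(alpha_h) - np.pi / 2.0) < 1e-12
    if np.any(on_pole & ~np.isclose(alpha_t, 0.0)):
        raise FiberError("alpha_h = +/-pi/2 with nonzero alpha_t has no fiber vector")
    th, tt = np.tan(np.where(on_pole, 0.0, alpha_h)), np.tan(alpha_t)
    comp = np.stack([np.ones_like(th), th, tt], axis=-1)
    pole_comp = np.stack([np.zeros_like(th), np.sign(alpha_h), np.zeros_like(tt)], axis=-1)
    comp = np.where(on_pole[..., None], pole_comp, comp)
    comp = comp / np.linalg.norm(comp, axis=-1, keepdims=True)
    return np.einsum("...k,...kj->...j", comp, basis)


def canonicalize(vec: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Resolve the fiber sign ambiguity: positive e_c0 component, ties broken
    by positive e_l0 component (fibers are directionless)."""
    comp = np.einsum("...kj,...j->...k", basis, vec)
    sign = np.where(np.abs(comp[..., 0]) > 1e-12, np.sign(comp[..., 0]),
                    np.where(np.abs(comp[..., 1]) > 1e-12, np.sign(comp[..., 1]), 1.0))
    return vec * sign[..., None]


def vector_to_angles(vec: np.ndarray, basis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Helix and transverse angles of (directionless) fiber vector(s)."""
    vec = canonicalize(np.asarray(vec, dtype=float), basis)
    comp = np.einsum("...kj,...j->...k", basis, vec)
    fc, fl, ft = comp[..., 0], comp[..., 1], comp[..., 2]
    degenerate = (np.abs(fc) < 1e-12) & (np.abs(ft) > 1e-10)
    if np.any(degenerate):
        raise FiberError("fiber lies in the longitudinal-transmural plane; "
                         "transverse angle undefined")
    alpha_h = np.arctan2(fl, fc)
    alpha_t = np.arctan(np.where(np.abs(fc) < 1e-12, 0.0, ft / np.maximum(fc, 1e-300)))
    return alpha_h, alpha_t


# --------------------------------------------------------------------------
# parameterized distributions
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SSFiberParams:
    """Transmural helix-angle distribution of the normal LV.

    ``alpha_h(u, v) = (c0 + c1 v + c2 v^2 + c3 v^3) * (1 + long_mod * u^2)``
    (radians).  The default cubic runs from +70 deg at the endocardium
    (right-handed helix) through +15 deg at midwall to -50 deg at the
    epicardium (left-handed), strictly decreasing transmurally — the
    slightly endocardially biased pattern of the normal LV.  Coefficients
    are model choices.
    """

    c0: float = np.deg2rad(15.0)
    c1: float = np.deg2rad(-45.0)
    c2: float = np.deg2rad(-5.0)
    c3: float = np.deg2rad(-15.0)
    long_mod: float = 0.0


@dataclasses.dataclass(frozen=True)
class TransitionParams:
    """SIT transition-zone geometry in the (u, v) chart.

    The zone centre line is ``u = u_t + slope * v``; a positive slope places
    the transition more apically at the endocardium.  ``height`` is the
    u-extent of the linear blend (0 gives a sharp switch).
    """

    u_t: float = 0.0
    slope: float = 0.25
    height: float = 0.3

    def validate(self) -> None:
        if self.height < 0:
            raise FiberError("transition height must be >= 0")
        if abs(self.u_t) + abs(self.slope) + self.height / 2.0 > 1.0 + 1e-12:
            raise FiberError("transition zone exits the wall u-range")


def helix_ss(u, v, params: SSFiberParams = SSFiberParams()):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    poly = params.c0 + params.c1 * v + params.c2 * v**2 + params.c3 * v**3
    return poly * (1.0 + params.long_mod * u**2)


def transverse_initial(u, v):
    """Initial transverse angle: zero everywhere (both SS and SIT)."""
    return np.zeros(np.broadcast(np.asarray(u), np.asarray(v)).shape)


def invert_helix(alpha_h):
    """Mirror-image transmural course: alpha_h -> -alpha_h."""
    return -np.asarray(alpha_h, dtype=float)


def angle_difference(a, b):
    """Difference a - b of fiber angles, wrapped into (-pi/2, pi/2].

    Fiber angles are pi-periodic (fibers are directionless): an angle moving
    from +89 deg to -89 deg has changed by 2 deg, not 178 deg.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return -((np.pi / 2.0 - d) % np.pi - np.pi / 2.0)


def helix_sit_initial(u, v, ss_params: SSFiberParams = SSFiberParams(),
                      tp: TransitionParams = TransitionParams()):
    """Initial SIT helix angle: SS below (apical of) the transition zone,
    inverted above it, linear blend in u across the zone."""
    tp.validate()
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    centre = tp.u_t + tp.slope * v
    base = helix_ss(u, v, ss_params)
    if tp.height == 0.0:
        x = (u > centre).astype(float)
    else:
        x = np.clip((u - (centre - tp.height / 2.0)) / tp.height, 0.0, 1.0)
    return (1.0 - 2.0 * x) * base


# --------------------------------------------------------------------------
# fields on the mesh
# --------------------------------------------------------------------------

@dataclasses.dataclass
class FiberField:
    """Per-node unloaded fiber unit vectors on the cross-section mesh.

    ``vectors`` holds cylindrical components (R, Phi, Z); ``basis`` the local
    cardiac basis per node.  ``provenance`` is 'parameterized-initial' or
    'adapted'.
    """

    vectors: np.ndarray           # (n_nodes, 3)
    basis: np.ndarray             # (n_nodes, 3, 3)
    provenance: str

    def __post_init__(self) -> None:
        nrm = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(nrm - 1.0) > 1e-9):
            raise FiberError("fiber vectors must be unit length")

    def angles(self) -> tuple[np.ndarray, np.ndarray]:
        return vector_to_angles(self.vectors, self.basis)

    def copy(self) -> "FiberField":
        return FiberField(self.vectors.copy(), self.basis, self.provenance)


def build_fiber_field(mesh: Mesh, kind: str = "ss",
                      ss_params: SSFiberParams = SSFiberParams(),
                      transition: TransitionParams | None = None) -> FiberField:
    """Initial parameterized fiber field ('ss' or 'sit') on the mesh nodes."""
    cs = mesh.cross_section
    basis = local_basis_nodes(cs, mesh)
    if kind == "ss":
        ah = helix_ss(cs.u, cs.v, ss_params)
    elif kind == "sit":
        tp = transition or TransitionParams()
        ah = helix_sit_initial(cs.u, cs.v, ss_params, tp)
    else:
        raise FiberError(f"unknown fiber field kind {kind!r}")
    at = transverse_initial(cs.u, cs.v)
    vec = angles_to_vector(ah, at, basis)
    return FiberField(vectors=vec, basis=basis, provenance="parameterized-initial")


def fibers_at_qps(cs: CrossSection, field: FiberField) -> np.ndarray:
    """Interpolate nodal fiber vectors to quadrature points (renormalized).

    Returns (n_elems, nqp, 3) cylindrical components.
    """
    ve = field.vectors[cs.conn]                      # (nel, 9, 3)
    vq = np.einsum("qa,eak->eqk", cs.shape_N, ve)
    return vq / np.linalg.norm(vq, axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# streamline tracing
# --------------------------------------------------------------------------

class _ChartLookup:
    """Fast approximate (R, Z) -> (u, v) lookup via a dense forward sample."""

    def __init__(self, mesh: Mesh, n_u: int = 81, n_v: int = 25):
        from scipy.interpolate import LinearNDInterpolator
        ug = np.linspace(-1, 1, n_u)
        vg = np.linspace(-1, 1, n_v)
        uu, vv = np.meshgrid(ug, vg, indexing="ij")
        pts = mesh.chart.points(uu.ravel(), vv.ravel())
        self._interp_u = LinearNDInterpolator(pts, uu.ravel())
        self._interp_v = LinearNDInterpolator(pts, vv.ravel())

    def __call__(self, R: float, Z: float) -> tuple[float, float]:
        u = self._interp_u(R, Z)
        v = self._interp_v(R, Z)
        return float(u), float(v)


def _field_interpolator(mesh: Mesh, field: FiberField):
    """Return f(x, y, z) -> unit fiber vector in Cartesian components, or
    None outside the wall; uses the structured (u, v) node grid."""
    cs = mesh.cross_section
    lookup = _ChartLookup(mesh)
    comp = field.vectors.reshape(cs.nj, cs.ni, 3)  # (j longitudinal, i transmural, 3)
    ug, vg = cs.u_nodes_1d, cs.v_nodes_1d

    def evaluate(x: np.ndarray):
        R = float(np.hypot(x[0], x[1]))
        phi = float(np.arctan2(x[1], x[0]))
        u, v = lookup(R, x[2])
        if not np.isfinite(u) or not np.isfinite(v):
            return None
        if not (-1.0001 <= u <= 1.0001 and -1.0001 <= v <= 1.0001):
            return None
        ju = np.clip(np.searchsorted(ug, u) - 1, 0, len(ug) - 2)
        iv = np.clip(np.searchsorted(vg, v) - 1, 0, len(vg) - 2)
        tu = (u - ug[ju]) / (ug[ju + 1] - ug[ju])
        tv = (v - vg[iv]) / (vg[iv + 1] - vg[iv])
        c = (comp[ju, iv] * (1 - tu) * (1 - tv) + comp[ju + 1, iv] * tu * (1 - tv)
             + comp[ju, iv + 1] * (1 - tu) * tv + comp[ju + 1, iv + 1] * tu * tv)
        n = np.linalg.norm(c)
        if n < 1e-12:
            return None
        c = c / n
        # rotate cylindrical components to Cartesian at azimuth phi
        cp, sp = np.cos(phi), np.sin(phi)
        return np.array([c[0] * cp - c[1] * sp, c[0] * sp + c[1] * cp, c[2]])

    return evaluate


def trace_fiber_paths(mesh: Mesh, field: FiberField, seeds: np.ndarray,
                      step: float = 0.5, max_length: float = 400.0,
                      method: str = "rk4") -> list[np.ndarray]:
    """Trace fiber streamlines from Cartesian seed points.

    Each returned polyline is arc-length parameterized: every segment has
    length ``step`` (the final partial segment is dropped when the path
    leaves the wall).  ``method`` is 'rk4' or 'euler'.
    """
    evaluate = _field_interpolator(mesh, field)
    paths = []
    for seed in np.atleast_2d(np.asarray(seeds, dtype=float)):
        if evaluate(seed) is None:
            raise FiberError(f"seed point {seed} lies outside the wall")
        x = seed.copy()
        pts = [x.copy()]
        n_steps = int(max_length / step)
        for _ in range(n_steps):
            if method == "euler":
                d = evaluate(x)
                if d is None:
                    break
                inc = d * step
            else:
                k1 = evaluate(x)
                if k1 is None:
                    break
                k2 = evaluate(x + 0.5 * step * k1)
                k3 = evaluate(x + 0.5 * step * k2) if k2 is not None else None
                k4 = evaluate(x + step * k3) if k3 is not None else None
                if k2 is None or k3 is None or k4 is None:
                    break
                inc = (k1 + 2 * k2 + 2 * k3 + k4) / 6.0 * step
            nrm = np.linalg.norm(inc)
            if nrm < 1e-12:
                break
            inc = inc * (step / nrm)  # exact arc-length stepping
            x = x + inc
            if evaluate(x) is None:
                break
            pts.append(x.copy())
        paths.append(np.array(pts))
    return paths
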