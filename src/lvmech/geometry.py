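"""Unloaded left-ventricular geometry.

The passive stress-free LV wall is bounded by two confocal-ish truncated
ellipsoids of revolution (endocardium inside, epicardium outside), cut by a
flat base plane above the equator.  The wall carries a normalized coordinate
chart (u, v):

* ``u`` — longitudinal, linear in geodesic distance along a shell meridian;
  ``u = -1`` at the apex, ``0`` at the equator, ``+1`` on the base plane.
* ``v`` — transmural, linear in distance across the wall; ``v = -1`` on the
  endocardium, ``+1`` on the epicardium.

The mesh is rotationally symmetric: a structured grid of 9-node biquadratic
quadrilaterals discretizes the (R, Z) cross-section, and the 27-node
hexahedral mesh is obtained by revolving it with a single circumferential
element whose two circumferential faces are periodically identified.  All
lengths are in mm, volumes in mL (1 mL = 1000 mm^3).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

ML_TO_MM3 = 1000.0

# 3-point Gauss rule on [-1, 1]
GAUSS3_X = np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)])
GAUSS3_W = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent wall geometry."""


@dataclasses.dataclass(frozen=True)
class GeometryParams:
    """Wall geometry in the unloaded state.

    Volumes are in mL.  ``truncation_height`` is the height of the base plane
    above the equator as a fraction of the endocardial long semi-axis.  The
    axis ratios are long-semi-axis / short-semi-axis of each ellipsoid.
    Defaults describe a small human (large dog) sized LV; they are
    config-overridable model choices, not literature constants.
    """

    wall_volume: float = 136.0
    cavity_volume: float = 44.0
    truncation_height: float = 0.5
    endo_axis_ratio: float = 2.0
    epi_axis_ratio: float = 1.5

    def validate(self) -> None:
        if self.wall_volume <= 0 or self.cavity_volume <= 0:
            raise GeometryError("wall and cavity volumes must be positive")
        if not (0.0 < self.truncation_height < 1.0):
            raise GeometryError("truncation height must lie in (0, 1)")
        if self.endo_axis_ratio <= 0 or self.epi_axis_ratio <= 0:
            raise GeometryError("axis ratios must be positive")


def ellipsoid_segment_volume(a: float, c: float, z_top: float) -> float:
    """Volume (mm^3) of the ellipsoid x^2/a^2 + y^2/a^2 + z^2/c^2 <= 1
    below the plane z = z_top (apex pole at z = -c)."""
    if not (-c < z_top <= c):
        raise GeometryError("truncation plane does not intersect ellipsoid")
    return np.pi * a * a * ((z_top + c) - (z_top**3 + c**3) / (3.0 * c * c))


def solve_ellipsoid_axes(params: GeometryParams) -> tuple[float, float, float, float, float]:
    """Return (a_endo, c_endo, a_epi, c_epi, z_base) in mm.

    The endocardial ellipsoid is fixed by the cavity volume and its axis
    ratio (closed form); the epicardial ellipsoid by the total enclosed
    volume with the shared base plane (scalar root find).
    """
    params.validate()
    k_en, k_ep = params.endo_axis_ratio, params.epi_axis_ratio
    t = params.truncation_height
    g = (t + 1.0) - (t**3 + 1.0) / 3.0  # segment volume factor, V = pi k a^3 g
    a_en = (params.cavity_volume * ML_TO_MM3 / (np.pi * k_en * g)) ** (1.0 / 3.0)
    c_en = k_en * a_en
    z_base = t * c_en

    v_total = (params.cavity_volume + params.wall_volume) * ML_TO_MM3

    def f(a: float) -> float:
        return ellipsoid_segment_volume(a, k_ep * a, z_base) - v_total

    a_lo = max(a_en, z_base / k_ep) * (1.0 + 1e-9)
    a_hi = 10.0 * a_en
    if f(a_lo) >= 0.0:
        raise GeometryError("epicardial surface does not enclose endocardium")
    a_ep = brentq(f, a_lo, a_hi, xtol=1e-12, rtol=1e-14)
    c_ep = k_ep * a_ep
    if a_ep <= a_en or c_ep <= c_en:
        raise GeometryError("epicardial ellipsoid does not strictly enclose endocardial one")
    if z_base >= c_ep:
        raise GeometryError("base plane does not intersect the epicardial surface")
    return a_en, c_en, a_ep, c_ep, z_base


class WallChart:
    """Forward map (u, v) -> (R, Z) of the wall cross-section and its inverse.

    Interpolating shells between the two bounding ellipsoids are
    ``a(w) = a_en + w (a_ep - a_en)`` (same for c), w in [0, 1].  u is
    normalized geodesic distance from the equator on each shell; v is
    normalized transmural arc length along curves of constant u.
    """

    N_ETA = 481  # meridian samples per shell (split at the equator)
    N_W = 121    # transmural shell samples

    def __init__(self, params: GeometryParams):
        self.params = params
        (self.a_en, self.c_en, self.a_ep, self.c_ep, self.z_base) = solve_ellipsoid_axes(params)
        self._build_tables()

    # -- construction -----------------------------------------------------
    def _build_tables(self) -> None:
        m = self.N_ETA // 2
        self.w_grid = np.linspace(0.0, 1.0, self.N_W)
        self.a_w = self.a_en + self.w_grid * (self.a_ep - self.a_en)
        self.c_w = self.c_en + self.w_grid * (self.c_ep - self.c_en)
        self.eta_base = np.arccos(np.clip(-self.z_base / self.c_w, -1.0, 1.0))
        # per-shell meridian tables: eta, normalized u
        self.eta_tab = np.empty((self.N_W, 2 * m + 1))
        self.u_tab = np.empty_like(self.eta_tab)
        for k in range(self.N_W):
            eta_lo = np.linspace(0.0, np.pi / 2.0, m + 1)
            eta_hi = np.linspace(np.pi / 2.0, self.eta_base[k], m + 1)
            eta = np.concatenate([eta_lo, eta_hi[1:]])
            a, c = self.a_w[k], self.c_w[k]
            ds = np.sqrt((a * np.cos(eta)) ** 2 + (c * np.sin(eta)) ** 2)
            s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(eta))])
            s_eq = s[m]
            u = np.where(eta <= np.pi / 2.0,
                         (s - s_eq) / s_eq,
                         (s - s_eq) / (s[-1] - s_eq))
            self.eta_tab[k] = eta
            self.u_tab[k] = u
        # eta(u, w) on a fixed dense u grid for cross-shell interpolation
        self.u_dense = np.linspace(-1.0, 1.0, 601)
        self.eta_uw = np.empty((self.N_W, self.u_dense.size))
        for k in range(self.N_W):
            self.eta_uw[k] = np.interp(self.u_dense, self.u_tab[k], self.eta_tab[k])

    # -- forward map ------------------------------------------------------
    def _shell_point(self, u: float | np.ndarray, k: int) -> np.ndarray:
        eta = np.interp(u, self.u_tab[k], self.eta_tab[k])
        return np.stack([self.a_w[k] * np.sin(eta), -self.c_w[k] * np.cos(eta)], axis=-1)

    def transmural_curve(self, u: float) -> tuple[np.ndarray, np.ndarray]:
        """Points across the wall at fixed u on all table shells, and the
        transmural coordinate v of each shell (arc-length normalized)."""
        eta = np.array([np.interp(u, self.u_tab[k], self.eta_tab[k]) for k in range(self.N_W)])
        pts = np.stack([self.a_w * np.sin(eta), -self.c_w * np.cos(eta)], axis=-1)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        v = 2.0 * s / s[-1] - 1.0
        return pts, v

    def point(self, u: float, v: float) -> np.ndarray:
        """(R, Z) of chart point (u, v)."""
        if not (-1.0 - 1e-9 <= u <= 1.0 + 1e-9) or not (-1.0 - 1e-9 <= v <= 1.0 + 1e-9):
            raise GeometryError(f"chart coordinates out of range: u={u}, v={v}")
        pts, vv = self.transmural_curve(float(np.clip(u, -1, 1)))
        v = float(np.clip(v, -1, 1))
        r = np.interp(v, vv, pts[:, 0])
        z = np.interp(v, vv, pts[:, 1])
        return np.array([r, z])

    def points(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.array([self.point(ui, vi) for ui, vi in zip(np.ravel(u), np.ravel(v))])

    # -- inverse map ------------------------------------------------------
    def wall_coords(self, rz: np.ndarray, tol: float = 1e-8, maxiter: int = 60) -> tuple[float, float]:
        """Invert the chart at a cross-section point (R, Z).

        Raises :class:`GeometryError` for points outside the wall.
        """
        rz = np.asarray(rz, dtype=float)
        R, Z = rz
        eps = 1e-6
        if (R / self.a_en) ** 2 + (Z / self.c_en) ** 2 < 1.0 - 1e-6:
            raise GeometryError("point lies inside the cavity")
        if (R / self.a_ep) ** 2 + (Z / self.c_ep) ** 2 > 1.0 + 1e-6:
            raise GeometryError("point lies outside the epicardium")
        if Z > self.z_base + 1e-6:
            raise GeometryError("point lies above the base plane")
        # initial guess from coarse sampling
        ug = np.linspace(-1, 1, 41)
        vg = np.linspace(-1, 1, 9)
        best, best_d = (0.0, 0.0), np.inf
        for vi in vg:
            pts = self.points(ug, np.full_like(ug, vi))
            d = np.linalg.norm(pts - rz, axis=1)
            i = int(np.argmin(d))
            if d[i] < best_d:
                best_d, best = d[i], (float(ug[i]), float(vi))
        u, v = best
        for _ in range(maxiter):
            p0 = self.point(u, v)
            res = p0 - rz
            if np.linalg.norm(res) < tol * max(1.0, self.a_ep):
                break
            hu = eps if u < 1 - eps else -eps
            hv = eps if v < 1 - eps else -eps
            ju = (self.point(u + hu, v) - p0) / hu
            jv = (self.point(u, v + hv) - p0) / hv
            J = np.stack([ju, jv], axis=1)
            try:
                step = np.linalg.solve(J, res)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(J, res, rcond=None)[0]
            u = float(np.clip(u - step[0], -1.0, 1.0))
            v = float(np.clip(v - step[1], -1.0, 1.0))
        return u, v

    # -- analytic volumes -------------------------------------------------
    @property
    def cavity_volume_mm3(self) -> float:
        return ellipsoid_segment_volume(self.a_en, self.c_en, self.z_base)

    @property
    def wall_volume_mm3(self) -> float:
        return (ellipsoid_segment_volume(self.a_ep, self.c_ep, self.z_base)
                - self.cavity_volume_mm3)


def _lagrange_quad_shape(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Biquadratic 9-node shape functions on [-1,1]^2, tensor ordering
    local index = 3*j + i with i transmural (xi), j longitudinal (eta)."""
    def l(x):
        return np.array([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)])

    def dl(x):
        return np.array([x - 0.5, -2.0 * x, x + 0.5])

    Li, Lj, dLi, dLj = l(xi), l(eta), dl(xi), dl(eta)
    N = np.outer(Lj, Li).ravel()
    dNdxi = np.outer(Lj, dLi).ravel()
    dNdeta = np.outer(dLj, Li).ravel()
    return N, dNdxi, dNdeta


class CrossSection:
    """Structured biquadratic discretization of the wall cross-section.

    This is the computational view of the rotationally symmetric mesh: node
    unknowns are (u_r, psi, u_z) with psi the azimuthal rotation angle.  All
    quadrature data for the revolved (per-full-circle) volume integrals is
    precomputed here.
    """

    def __init__(self, R: np.ndarray, Z: np.ndarray, u: np.ndarray, v: np.ndarray,
                 n_trans: int, n_long: int, chart: WallChart | None = None):
        if n_trans < 1 or n_long < 1:
            raise GeometryError("subdivisions must be >= 1")
        self.chart = chart
        self.n_trans = n_trans
        self.n_long = n_long
        ni, nj = 2 * n_trans + 1, 2 * n_long + 1
        self.ni, self.nj = ni, nj
        self.R = np.asarray(R, dtype=float).ravel()
        self.Z = np.asarray(Z, dtype=float).ravel()
        self.u = np.asarray(u, dtype=float).ravel()
        self.v = np.asarray(v, dtype=float).ravel()
        self.n_nodes = ni * nj
        self.u_nodes_1d = self.u.reshape(nj, ni)[:, 0]
        self.v_nodes_1d = self.v.reshape(nj, ni)[0, :]

    @classmethod
    def from_chart(cls, chart: WallChart, n_trans: int, n_long: int) -> "CrossSection":
        ni, nj = 2 * n_trans + 1, 2 * n_long + 1
        v_nodes = np.linspace(-1.0, 1.0, ni)
        u_nodes = np.linspace(-1.0, 1.0, nj)
        uu, vv = np.meshgrid(u_nodes, v_nodes, indexing="ij")  # (nj, ni)
        pts = chart.points(uu.ravel(), vv.ravel())
        obj = cls(pts[:, 0], pts[:, 1], uu.ravel(), vv.ravel(), n_trans, n_long, chart)
        obj.finalize()
        return obj

    def finalize(self) -> None:
        self._build_topology()

    def _build_topology(self) -> None:
        ni, nj = self.ni, self.nj
        n_trans, n_long = self.n_trans, self.n_long

        def nid(i: int, j: int) -> int:
            return j * ni + i

        self._nid = nid
        conn = []
        for ej in range(n_long):
            for ei in range(n_trans):
                i0, j0 = 2 * ei, 2 * ej
                conn.append([nid(i0 + di, j0 + dj) for dj in range(3) for di in range(3)])
        self.conn = np.array(conn, dtype=int)  # (nel, 9)
        self.n_elems = self.conn.shape[0]

        # boundary node sets; axis nodes detected geometrically (R = 0)
        self.axis_nodes = np.flatnonzero(self.R < 1e-10)
        self.base_nodes = np.array([nid(i, nj - 1) for i in range(ni)])
        self.endo_nodes = np.array([nid(0, j) for j in range(nj)])
        self.epi_nodes = np.array([nid(ni - 1, j) for j in range(nj)])
        self.basal_endo_node = nid(0, nj - 1)

        # endocardial pressure edges, ordered apex -> base
        self.endo_edges = np.array(
            [[nid(0, 2 * ej), nid(0, 2 * ej + 1), nid(0, 2 * ej + 2)] for ej in range(n_long)],
            dtype=int,
        )

        self._precompute_quadrature()
        self._precompute_nodal_shape()

    def _precompute_quadrature(self) -> None:
        nqp = 9
        nel = self.n_elems
        self.nqp = nqp
        N = np.empty((nqp, 9))
        dNdxi = np.empty((nqp, 9))
        dNdeta = np.empty((nqp, 9))
        wq = np.empty(nqp)
        q = 0
        for jq, (eta, we) in enumerate(zip(GAUSS3_X, GAUSS3_W)):
            for iq, (xi, wx) in enumerate(zip(GAUSS3_X, GAUSS3_W)):
                N[q], dNdxi[q], dNdeta[q] = _lagrange_quad_shape(xi, eta)
                wq[q] = wx * we
                q += 1
        self.shape_N = N
        Re = self.R[self.conn]  # (nel, 9)
        Ze = self.Z[self.conn]
        # Jacobian of (xi, eta) -> (R, Z) per element/qp
        dRdxi = np.einsum("qa,ea->eq", dNdxi, Re)
        dRdeta = np.einsum("qa,ea->eq", dNdeta, Re)
        dZdxi = np.einsum("qa,ea->eq", dNdxi, Ze)
        dZdeta = np.einsum("qa,ea->eq", dNdeta, Ze)
        detJ = dRdxi * dZdeta - dRdeta * dZdxi
        if np.any(detJ <= 0.0):
            raise GeometryError("non-positive element Jacobian in cross-section mesh")
        self.detJ = detJ
        inv = 1.0 / detJ
        # dN/dR, dN/dZ (nel, nqp, 9)
        self.dNdR = (dNdxi[None, :, :] * dZdeta[:, :, None] - dNdeta[None, :, :] * dZdxi[:, :, None]) * inv[:, :, None]
        self.dNdZ = (-dNdxi[None, :, :] * dRdeta[:, :, None] + dNdeta[None, :, :] * dRdxi[:, :, None]) * inv[:, :, None]
        self.R_qp = np.einsum("qa,ea->eq", N, Re)
        self.Z_qp = np.einsum("qa,ea->eq", N, Ze)
        self.u_qp = np.einsum("qa,ea->eq", N, self.u[self.conn])
        self.v_qp = np.einsum("qa,ea->eq", N, self.v[self.conn])
        # full-revolution reference volume weight (mm^3)
        self.w_qp = wq[None, :] * detJ * 2.0 * np.pi * self.R_qp
        # element longitudinal index (apex=0) for region masks
        self.elem_long_index = np.repeat(np.arange(self.n_long), self.n_trans)
        self.elem_trans_index = np.tile(np.arange(self.n_trans), self.n_long)

    def _precompute_nodal_shape(self) -> None:
        """Shape-function derivatives at the 9 nodal parametric points of each
        element (for recovering F at nodes)."""
        pts = [(-1.0, -1.0), (0.0, -1.0), (1.0, -1.0),
               (-1.0, 0.0), (0.0, 0.0), (1.0, 0.0),
               (-1.0, 1.0), (0.0, 1.0), (1.0, 1.0)]
        npt = 9
        N = np.empty((npt, 9))
        dNdxi = np.empty((npt, 9))
        dNdeta = np.empty((npt, 9))
        for q, (xi, eta) in enumerate(pts):
            N[q], dNdxi[q], dNdeta[q] = _lagrange_quad_shape(xi, eta)
        Re = self.R[self.conn]
        Ze = self.Z[self.conn]
        dRdxi = np.einsum("qa,ea->eq", dNdxi, Re)
        dRdeta = np.einsum("qa,ea->eq", dNdeta, Re)
        dZdxi = np.einsum("qa,ea->eq", dNdxi, Ze)
        dZdeta = np.einsum("qa,ea->eq", dNdeta, Ze)
        detJ = dRdxi * dZdeta - dRdeta * dZdxi
        inv = 1.0 / detJ
        self.nodal_dNdR = (dNdxi[None] * dZdeta[:, :, None] - dNdeta[None] * dZdxi[:, :, None]) * inv[:, :, None]
        self.nodal_dNdZ = (-dNdxi[None] * dRdeta[:, :, None] + dNdeta[None] * dRdxi[:, :, None]) * inv[:, :, None]
        self.nodal_N = N

    # -- integrals --------------------------------------------------------
    def wall_volume_mm3(self) -> float:
        return float(self.w_qp.sum())

    def element_volumes_mm3(self) -> np.ndarray:
        return self.w_qp.sum(axis=1)

    def cavity_volume_mm3(self, ur: np.ndarray | None = None, uz: np.ndarray | None = None) -> float:
        """Disc-method cavity volume pi * int r^2 dz along the (possibly
        deformed) endocardial curve, apex to base."""
        r = self.R.copy() if ur is None else self.R + ur
        z = self.Z.copy() if uz is None else self.Z + uz
        vol = 0.0
        for edge in self.endo_edges:
            re, ze = r[edge], z[edge]
            for xi, w in zip(GAUSS3_X, GAUSS3_W):
                L = np.array([0.5 * xi * (xi - 1.0), 1.0 - xi * xi, 0.5 * xi * (xi + 1.0)])
                dL = np.array([xi - 0.5, -2.0 * xi, xi + 0.5])
                vol += w * (L @ re) ** 2 * (dL @ ze)
        return float(np.pi * vol)


VTK_TRIQUADRATIC_HEX = 29


@dataclasses.dataclass
class Mesh:
    """Rotationally symmetric 27-node hexahedral LV wall mesh.

    Nodes are stored in cylindrical coordinates (R, phi, Z); the single
    circumferential element spans the full circle with its two circumferential
    faces periodically identified (the wrap face reuses the phi = 0 node ids),
    so interpolation is tri-quadratic in (R-Z cross-section) x (phi).
    ``cross_section`` is the equivalent axisymmetric computational view.
    """

    params: GeometryParams
    chart: WallChart
    cross_section: CrossSection
    subdivisions: tuple[int, int, int]
    nodes_cyl: np.ndarray        # (n_nodes, 3): R, phi, Z
    conn: np.ndarray             # (n_elems, 27) node ids
    surfaces: dict[str, np.ndarray]
    u: np.ndarray                # chart coordinates per node
    v: np.ndarray

    @property
    def n_elems(self) -> int:
        return self.conn.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes_cyl.shape[0]

    @property
    def nodes_xyz(self) -> np.ndarray:
        R, phi, Z = self.nodes_cyl.T
        return np.stack([R * np.cos(phi), R * np.sin(phi), Z], axis=1)

    def wall_volume(self) -> float:
        """Quadrature wall volume in mL."""
        return self.cross_section.wall_volume_mm3() / ML_TO_MM3

    def cavity_volume(self) -> float:
        """Quadrature (disc-method) cavity volume in mL."""
        return self.cross_section.cavity_volume_mm3() / ML_TO_MM3

    def jacobians_positive(self) -> bool:
        """Positivity of the element volume Jacobian R * det(J_2D) * dphi/dzeta
        at all interior quadrature points."""
        return bool(np.all(self.cross_section.detJ > 0.0) and np.all(self.cross_section.R_qp > 0.0))


def build_mesh(params: GeometryParams | None = None,
               subdivisions: tuple[int, int, int] = (6, 1, 10)) -> Mesh:
    """Construct the truncated-ellipsoid wall mesh.

    ``subdivisions`` is (radial/transmural, circumferential, longitudinal);
    the default (6, 1, 10) gives the standard 60-element mesh.  Only one
    periodic circumferential element is supported.
    """
    params = params or GeometryParams()
    n_r, n_c, n_l = subdivisions
    if n_r < 1 or n_l < 1 or n_c != 1:
        raise GeometryError("subdivisions must be (>=1, 1, >=1); the mesh is "
                            "rotationally symmetric with one periodic circumferential element")
    chart = WallChart(params)
    cs = CrossSection.from_chart(chart, n_r, n_l)

    # two unique phi layers (0, pi); the zeta=+1 layer wraps to phi=0 nodes
    n2 = cs.n_nodes
    R = np.concatenate([cs.R, cs.R])
    Z = np.concatenate([cs.Z, cs.Z])
    phi = np.concatenate([np.zeros(n2), np.full(n2, np.pi)])
    nodes_cyl = np.stack([R, phi, Z], axis=1)
    u = np.concatenate([cs.u, cs.u])
    v = np.concatenate([cs.v, cs.v])

    conn = np.empty((cs.n_elems, 27), dtype=int)
    for e in range(cs.n_elems):
        q = cs.conn[e]
        conn[e, 0:9] = q              # phi = 0 layer
        conn[e, 9:18] = q + n2        # phi = pi layer
        conn[e, 18:27] = q            # wrap layer, identified with phi = 0
    surfaces = {
        "endocardium": np.concatenate([cs.endo_nodes, cs.endo_nodes + n2]),
        "epicardium": np.concatenate([cs.epi_nodes, cs.epi_nodes + n2]),
        "base": np.concatenate([cs.base_nodes, cs.base_nodes + n2]),
        "basal_endocardial_ring": np.array([cs.basal_endo_node, cs.basal_endo_node + n2]),
    }
    mesh = Mesh(params=params, chart=chart, cross_section=cs,
                subdivisions=(n_r, n_c, n_l), nodes_cyl=nodes_cyl, conn=conn,
                surfaces=surfaces, u=u, v=v)

    wv = mesh.wall_volume()
    if abs(wv - params.wall_volume) / params.wall_volume > 0.005:
        raise GeometryError(
            f"quadrature wall volume {wv:.2f} mL deviates from requested "
            f"{params.wall_volume:.2f} mL by more than 0.5%")
    cv = mesh.cavity_volume()
    if abs(cv - params.cavity_volume) / params.cavity_volume > 0.005:
        raise GeometryError(
            f"quadrature cavity volume {cv:.2f} mL deviates from requested "
            f"{params.cavity_volume:.2f} mL by more than 0.5%")
    return mesh


def wall_coords(mesh: Mesh, point_rz: np.ndarray) -> tuple[float, float]:
    """Normalized wall coordinates (u, v) of a cross-section point (R, Z)."""
    return mesh.chart.wall_coords(np.asarray(point_rz, dtype=float))
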