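"""Minimal ASCII VTK XML (.vtu) writer for the wall mesh and nodal fields.

Writes VTK unstructured grids with tri-quadratic hexahedra (cell type 29)
or biquadratic quads (cell type 28) in plain-text XML, sufficient for
ParaView inspection of meshes, wall coordinates and fiber/displacement
fields.  Only writing is supported.
"""

from __future__ import annotations

import numpy as np

# VTK node ordering of the 27-node hexahedron relative to our tensor
# ordering (i fast within layer, layers stacked): corners, edges, faces,
# centre.  Our local index = 9*zeta + 3*eta + xi (xi transmural, eta
# longitudinal, zeta circumferential layer).
_VTK27 = [0, 2, 8, 6, 18, 20, 26, 24,       # corners bottom/top
          1, 5, 7, 3, 19, 23, 25, 21,       # horizontal edges
          9, 11, 17, 15,                    # vertical edges
          12, 14, 10, 16, 4, 22,            # faces (xi-, xi+, eta-, eta+, zeta-, zeta+)
          13]                               # centre

_VTK9 = [0, 2, 8, 6, 1, 5, 7, 3, 4]


def _data_array(name: str, data: np.ndarray, n_comp: int) -> str:
    flat = np.asarray(data, dtype=float).reshape(-1)
    body = " ".join(f"{x:.9g}" for x in flat)
    return (f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{n_comp}" format="ascii">{body}</DataArray>')


def write_vtu(path, points: np.ndarray, conn: np.ndarray, cell_type: int,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write an unstructured grid.  ``points`` is (n, 3); ``conn`` is
    (n_cells, nodes_per_cell) in this package's tensor ordering."""
    points = np.asarray(points, dtype=float)
    conn = np.asarray(conn, dtype=int)
    if cell_type == 29:
        perm = _VTK27
    elif cell_type == 28:
        perm = _VTK9
    else:
        raise ValueError(f"unsupported VTK cell type {cell_type}")
    conn = conn[:, perm]
    n_pts, n_cells = points.shape[0], conn.shape[0]
    npc = conn.shape[1]
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             "<UnstructuredGrid>",
             f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
             "<Points>", _data_array("points", points, 3), "</Points>",
             "<Cells>",
             '<DataArray type="Int64" Name="connectivity" format="ascii">'
             + " ".join(map(str, conn.reshape(-1))) + "</DataArray>",
             '<DataArray type="Int64" Name="offsets" format="ascii">'
             + " ".join(str(npc * (i + 1)) for i in range(n_cells)) + "</DataArray>",
             '<DataArray type="UInt8" Name="types" format="ascii">'
             + " ".join([str(cell_type)] * n_cells) + "</DataArray>",
             "</Cells>"]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            n_comp = 1 if arr.ndim == 1 else arr.shape[1]
            lines.append(_data_array(name, arr, n_comp))
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_mesh_vtu(path, mesh, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Export the hexahedral LV mesh with (u, v) as point data."""
    data = {"u": mesh.u, "v": mesh.v}
    if point_data:
        data.update(point_data)
    write_vtu(path, mesh.nodes_xyz, mesh.conn, 29, data)


def write_cross_section_vtu(path, cs, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Export the (R, Z) cross-section as biquadratic quads (z as third axis)."""
    pts = np.stack([cs.R, cs.Z, np.zeros_like(cs.R)], axis=1)
    data = {"u": cs.u, "v": cs.v}
    if point_data:
        data.update(point_data)
    write_vtu(path, pts, cs.conn, 28, data)
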