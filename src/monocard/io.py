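"""Mesh and field input/output.

Supported formats (ASCII only, which covers the meshes this package targets):

* gmsh MSH v2.2 and v4.1 (read) with per-element physical labels,
* VTK XML UnstructuredGrid ``.vtu`` (read/write), with point-data and
  cell-data arrays; the per-element material label is stored/read as a cell
  array (``material_id``, with common gmsh export names accepted too).

Coordinates are rescaled to SI meters at import through ``scaling_factor``.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import Mesh, MeshError

__all__ = ["import_mesh", "read_msh", "read_vtu", "write_vtu"]

VTK_TET = 10
VTK_HEX = 12
_GMSH_TET = 4
_GMSH_HEX = 5

_MATERIAL_NAMES = ("material_id", "gmsh:physical", "MaterialID", "CellEntityIds")


def import_mesh(path, scaling_factor: float = 1.0) -> Mesh:
    """Read a volumetric mesh and rescale coordinates to meters.

    Parameters
    ----------
    path : .msh (gmsh v2.2/v4.1 ASCII) or .vtu (XML ASCII) file.
    scaling_factor : multiplies all coordinates, e.g. 1e-3 for a mesh whose
        file coordinates are millimeters.

    Meshes mixing tetrahedra and hexahedra are rejected.  Missing element
    labels are assigned 0 with a warning.
    """
    path = Path(path)
    if path.suffix == ".msh":
        mesh = read_msh(path)
    elif path.suffix == ".vtu":
        mesh = read_vtu(path)
    else:
        raise MeshError(f"unsupported mesh format: {path.suffix!r}")
    if scaling_factor != 1.0:
        mesh = mesh.scaled(scaling_factor)
    return mesh


def _mesh_from_cells(points, cells_by_type, labels_by_type, origin):
    kinds = [k for k in (VTK_TET, VTK_HEX) if len(cells_by_type.get(k, [])) > 0]
    if not kinds:
        raise MeshError(f"{origin}: no volumetric (tet/hex) cells found")
    if len(kinds) > 1:
        raise MeshError(f"{origin}: mixed tetrahedral/hexahedral meshes are not supported")
    k = kinds[0]
    elements = np.asarray(cells_by_type[k], dtype=np.int64)
    labels = labels_by_type.get(k)
    if labels is None:
        warnings.warn(f"{origin}: no cell labels found, assigning material id 0")
        labels = np.zeros(len(elements), dtype=np.int64)
    kind = "tetrahedron" if k == VTK_TET else "hexahedron"
    return Mesh(np.asarray(points, dtype=np.float64), elements, kind,
                np.asarray(labels, dtype=np.int64))


# ---------------------------------------------------------------------------
# gmsh MSH
# ---------------------------------------------------------------------------

def read_msh(path) -> Mesh:
    """Read a gmsh ASCII mesh, dispatching on the MeshFormat version."""
    lines = Path(path).read_text().splitlines()
    sections: dict[str, list[str]] = {}
    name = None
    for ln in lines:
        s = ln.strip()
        if s.startswith("$End"):
            name = None
        elif s.startswith("$"):
            name = s[1:]
            sections[name] = []
        elif name is not None:
            sections[name].append(s)
    if "MeshFormat" not in sections:
        raise MeshError(f"{path}: not a gmsh MSH file")
    version = float(sections["MeshFormat"][0].split()[0])
    if version < 3.0:
        return _read_msh22(sections, path)
    return _read_msh41(sections, path)


def _read_msh22(sec, origin) -> Mesh:
    node_lines = sec["Nodes"]
    n_nodes = int(node_lines[0])
    ids = np.empty(n_nodes, dtype=np.int64)
    pts = np.empty((n_nodes, 3))
    for r, ln in enumerate(node_lines[1 : 1 + n_nodes]):
        parts = ln.split()
        ids[r] = int(parts[0])
        pts[r] = [float(x) for x in parts[1:4]]
    remap = {int(i): r for r, i in enumerate(ids)}

    elem_lines = sec["Elements"]
    n_el = int(elem_lines[0])
    cells: dict[int, list] = {VTK_TET: [], VTK_HEX: []}
    labels: dict[int, list] = {VTK_TET: [], VTK_HEX: []}
    kindmap = {_GMSH_TET: VTK_TET, _GMSH_HEX: VTK_HEX}
    for ln in elem_lines[1 : 1 + n_el]:
        parts = [int(x) for x in ln.split()]
        etype, ntags = parts[1], parts[2]
        if etype not in kindmap:
            continue  # points/lines/surfaces: ignored
        k = kindmap[etype]
        phys = parts[3] if ntags >= 1 else 0
        conn = [remap[v] for v in parts[3 + ntags :]]
        cells[k].append(conn)
        labels[k].append(phys)
    labels_by_type = {k: np.asarray(v, dtype=np.int64)
                      for k, v in labels.items() if v}
    return _mesh_from_cells(pts, cells, labels_by_type, origin)


def _read_msh41(sec, origin) -> Mesh:
    # Entities give the physical tag of each volume entity (optional).
    vol_phys: dict[int, int] = {}
    if "Entities" in sec:
        counts = [int(x) for x in sec["Entities"][0].split()]
        np_, nc, ns, nv = counts
        row = 1 + np_ + nc + ns
        for ln in sec["Entities"][row : row + nv]:
            parts = ln.split()
            tag = int(parts[0])
            nphys = int(parts[7])
            if nphys > 0:
                vol_phys[tag] = int(parts[8])

    node_lines = sec["Nodes"]
    hdr = [int(x) for x in node_lines[0].split()]
    n_blocks, n_nodes = hdr[0], hdr[1]
    ids = []
    pts = []
    row = 1
    for _ in range(n_blocks):
        _, _, _, n_in = (int(x) for x in node_lines[row].split())
        row += 1
        ids.extend(int(node_lines[row + i]) for i in range(n_in))
        row += n_in
        for i in range(n_in):
            pts.append([float(x) for x in node_lines[row + i].split()[:3]])
        row += n_in
    remap = {i: r for r, i in enumerate(ids)}
    pts = np.asarray(pts)

    elem_lines = sec["Elements"]
    hdr = [int(x) for x in elem_lines[0].split()]
    n_blocks = hdr[0]
    cells: dict[int, list] = {VTK_TET: [], VTK_HEX: []}
    labels: dict[int, list] = {VTK_TET: [], VTK_HEX: []}
    kindmap = {_GMSH_TET: VTK_TET, _GMSH_HEX: VTK_HEX}
    row = 1
    for _ in range(n_blocks):
        ent_dim, ent_tag, etype, n_in = (int(x) for x in elem_lines[row].split())
        row += 1
        if etype in kindmap:
            k = kindmap[etype]
            phys = vol_phys.get(ent_tag, ent_tag)
            for i in range(n_in):
                parts = [int(x) for x in elem_lines[row + i].split()]
                cells[k].append([remap[v] for v in parts[1:]])
                labels[k].append(phys)
        row += n_in
    labels_by_type = {k: np.asarray(v, dtype=np.int64)
                      for k, v in labels.items() if v}
    return _mesh_from_cells(pts, cells, labels_by_type, origin)


# ---------------------------------------------------------------------------
# VTU
# ---------------------------------------------------------------------------

def _parse_data_array(elem) -> np.ndarray:
    if elem.get("format", "ascii") != "ascii":
        raise MeshError("only ascii VTU files are supported")
    dtype = np.float64 if "Float" in elem.get("type", "Float64") else np.int64
    tokens = (elem.text or "").split()
    data = np.array(tokens, dtype=np.float64) if tokens else np.empty(0)
    arr = data.astype(dtype) if dtype is np.int64 else data
    ncomp = int(elem.get("NumberOfComponents", "1"))
    if ncomp > 1:
        arr = arr.reshape(-1, ncomp)
    return arr


def read_vtu(path, return_data: bool = False):
    """Read an XML ascii .vtu file.

    Returns the :class:`Mesh`, or ``(mesh, point_data, cell_data)`` when
    ``return_data`` is true (arrays keyed by name).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DeprecationWarning)
        root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshError(f"{path}: no <Piece> element")

    pts_elem = piece.find("Points/DataArray")
    points = _parse_data_array(pts_elem).reshape(-1, 3)

    cells = piece.find("Cells")
    arrays = {da.get("Name"): _parse_data_array(da)
              for da in cells.findall("DataArray")}
    conn = arrays["connectivity"].astype(np.int64).ravel()
    offsets = arrays["offsets"].astype(np.int64).ravel()
    types = arrays["types"].astype(np.int64).ravel()

    point_data = {}
    pd = piece.find("PointData")
    if pd is not None:
        point_data = {da.get("Name"): _parse_data_array(da)
                      for da in pd.findall("DataArray")}
    cell_data = {}
    cd = piece.find("CellData")
    if cd is not None:
        cell_data = {da.get("Name"): _parse_data_array(da)
                     for da in cd.findall("DataArray")}

    cells_by_type: dict[int, list] = {VTK_TET: [], VTK_HEX: []}
    rows_by_type: dict[int, list] = {VTK_TET: [], VTK_HEX: []}
    start = 0
    for row, (off, t) in enumerate(zip(offsets, types)):
        if t in cells_by_type:
            cells_by_type[t].append(conn[start:off])
            rows_by_type[t].append(row)
        start = off

    labels_by_type = {}
    label_arr = next((cell_data[n] for n in _MATERIAL_NAMES if n in cell_data),
                     None)
    if label_arr is not None:
        label_arr = np.asarray(label_arr).astype(np.int64).ravel()
        for t, rows in rows_by_type.items():
            if rows:
                labels_by_type[t] = label_arr[rows]
    mesh = _mesh_from_cells(points, cells_by_type, labels_by_type, str(path))
    if return_data:
        return mesh, point_data, cell_data
    return mesh


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    if np.issubdtype(flat.dtype, np.integer):
        return " ".join(str(int(x)) for x in flat)
    return " ".join(repr(float(x)) for x in flat)


def write_vtu(path, mesh: Mesh, point_data=None, cell_data=None) -> None:
    """Write an ASCII .vtu file with optional point/cell data arrays.

    The material ids are always written as cell array ``material_id``.
    Float arrays use ``repr`` formatting, so a write/read round trip
    reproduces values exactly.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("material_id", mesh.material_id)

    nv = mesh.elements.shape[1]
    vtk_type = VTK_TET if mesh.element_kind == "tetrahedron" else VTK_HEX
    offsets = np.arange(1, mesh.n_elements + 1) * nv
    types = np.full(mesh.n_elements, vtk_type)

    def data_array(name, arr, indent):
        arr = np.asarray(arr)
        dtype = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        pad = " " * indent
        return (
            f'{pad}<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"{pad}  {_fmt(arr)}\n{pad}</DataArray>\n"
        )

    out = []
    out.append('<?xml version="1.0"?>\n')
    out.append('<VTKFile type="UnstructuredGrid" version="0.1" '
               'byte_order="LittleEndian">\n')
    out.append("  <UnstructuredGrid>\n")
    out.append(f'    <Piece NumberOfPoints="{mesh.n_nodes}" '
               f'NumberOfCells="{mesh.n_elements}">\n')
    out.append("      <Points>\n")
    out.append(data_array("Points", mesh.nodes, 8))
    out.append("      </Points>\n")
    out.append("      <Cells>\n")
    out.append(data_array("connectivity", mesh.elements, 8))
    out.append(data_array("offsets", offsets, 8))
    out.append(data_array("types", types, 8))
    out.append("      </Cells>\n")
    out.append("      <PointData>\n")
    for name, arr in point_data.items():
        out.append(data_array(name, arr, 8))
    out.append("      </PointData>\n")
    out.append("      <CellData>\n")
    for name, arr in cell_data.items():
        out.append(data_array(name, arr, 8))
    out.append("      </CellData>\n")
    out.append("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")
    Path(path).write_text("".join(out))
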