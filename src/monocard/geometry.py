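"""Mesh construction and subdomain bookkeeping.

The computational domain Ω ⊂ R³ is a conforming tetrahedral or hexahedral
mesh, optionally partitioned into N labelled subdomains Ω_i (one integer
material id per element).  Heterogeneous tissue properties — conductivities,
ionic model, pathological overrides, or full exclusion from conduction
("scar") — are attached per subdomain through :class:`SubdomainSpec`.

Internal conventions
--------------------
* all coordinates are in SI meters; unit rescaling happens at import time;
* node/element indices are 0-based (1-based only inside file formats);
* hexahedron connectivity follows the VTK ordering: the four corners of the
  bottom face counter-clockwise (---, +--, ++-, -+-) followed by the top
  face in the same order; tetrahedra use the VTK 4-node ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh",
    "SubdomainSpec",
    "SubdomainPartition",
    "build_slab_mesh",
    "build_subdomains",
    "refine_hex_mesh",
    "mesh_hash",
]

#: local vertex order (i, j, k) lattice offsets for a VTK hexahedron
HEX_VTK_CORNERS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (1, 1, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (1, 1, 1),
        (0, 1, 1),
    ],
    dtype=np.int64,
)


class MeshError(ValueError):
    """Raised for invalid meshes or invalid mesh construction parameters."""


@dataclass
class Mesh:
    """An unstructured conforming mesh of a single element kind.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, coordinates in meters.
    elements : (n_elements, nv) int array, nv = 4 (tet) or 8 (hex).
    element_kind : "tetrahedron" or "hexahedron".
    material_id : (n_elements,) int array, one subdomain label per element.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_kind: str
    material_id: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.material_id = np.ascontiguousarray(self.material_id, dtype=np.int64)
        if self.element_kind not in ("tetrahedron", "hexahedron"):
            raise MeshError(f"unknown element kind {self.element_kind!r}")
        nv = 4 if self.element_kind == "tetrahedron" else 8
        if self.elements.ndim != 2 or self.elements.shape[1] != nv:
            raise MeshError(
                f"{self.element_kind} elements must have {nv} vertices, "
                f"got shape {self.elements.shape}"
            )
        if self.material_id.shape != (self.n_elements,):
            raise MeshError("material_id must hold one label per element")
        if not np.isfinite(self.nodes).all():
            raise MeshError("node coordinates must be finite")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= self.n_nodes
        ):
            raise MeshError("element connectivity references invalid node indices")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def scaled(self, factor: float) -> "Mesh":
        """Return a copy with coordinates multiplied by ``factor``."""
        return Mesh(self.nodes * float(factor), self.elements, self.element_kind,
                    self.material_id)


@dataclass
class SubdomainSpec:
    """Physical description of one subdomain Ω_i.

    Conductivities are the (already membrane-rescaled) diffusion coefficients
    σ_l, σ_t, σ_n in m²/s along the fiber, sheet and sheet-normal directions.
    ``conductive=False`` excludes the region from the monodomain solve
    entirely, creating a conduction block (scar tissue).
    """

    label: str
    material_ids: frozenset = frozenset({0})
    sigma_l: float = 0.0
    sigma_t: float = 0.0
    sigma_n: float = 0.0
    ionic_model: str | None = None
    cell_type: str | None = None
    parameter_overrides: dict = field(default_factory=dict)
    conductive: bool = True

    def __post_init__(self) -> None:
        self.material_ids = frozenset(int(m) for m in self.material_ids)
        for name in ("sigma_l", "sigma_t", "sigma_n"):
            if getattr(self, name) < 0:
                raise MeshError(f"{self.label}: {name} must be >= 0")


@dataclass
class SubdomainPartition:
    """Element/node index sets realizing Ω = ∪ Ω_i on a given mesh.

    ``element_sets[i]`` are the element indices of ``specs[i]``;
    ``node_sets[i]`` the mesh nodes incident to those elements (interface
    nodes on Γ_ij belong to both neighbouring sets).  ``active_nodes`` are
    the nodes supported on at least one conductive subdomain: nodes interior
    to non-conductive regions drop out of the solve, while nodes shared with
    a conductive neighbour are retained.
    """

    mesh: Mesh
    specs: list
    element_sets: list
    node_sets: list
    active_nodes: np.ndarray

    @property
    def n_subdomains(self) -> int:
        return len(self.specs)

    def conductive_elements(self) -> np.ndarray:
        """Global indices of all elements in conductive subdomains, sorted."""
        sets = [
            es
            for es, spec in zip(self.element_sets, self.specs)
            if spec.conductive
        ]
        if not sets:
            return np.empty(0, dtype=np.int64)
        return np.sort(np.concatenate(sets))


def build_slab_mesh(extents, dx: float) -> Mesh:
    """Structured hexahedral mesh of the box [0, Lx]×[0, Ly]×[0, Lz].

    Parameters
    ----------
    extents : three edge lengths (m); each must be an integer multiple of dx.
    dx : lattice spacing (m), > 0.

    All elements receive material id 0.
    """
    dx = float(dx)
    if dx <= 0:
        raise MeshError(f"dx must be positive, got {dx}")
    extents = [float(e) for e in extents]
    if len(extents) != 3:
        raise MeshError("extents must be three lengths")
    counts = []
    for L in extents:
        n = int(round(L / dx))
        if n < 1 or abs(n * dx - L) > 1e-9 * max(L, dx):
            raise MeshError(
                f"extent {L} is not an integer multiple of dx={dx}"
            )
        counts.append(n)
    nx, ny, nz = counts
    xs = np.linspace(0.0, extents[0], nx + 1)
    ys = np.linspace(0.0, extents[1], ny + 1)
    zs = np.linspace(0.0, extents[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    # node index = i + (nx+1)*(j + (ny+1)*k)  (x fastest)
    nodes = np.stack(
        [X.transpose(2, 1, 0).ravel(), Y.transpose(2, 1, 0).ravel(),
         Z.transpose(2, 1, 0).ravel()], axis=1
    )

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    i = i.transpose(2, 1, 0).ravel()
    j = j.transpose(2, 1, 0).ravel()
    k = k.transpose(2, 1, 0).ravel()

    def nid(ii, jj, kk):
        return ii + (nx + 1) * (jj + (ny + 1) * kk)

    corners = [nid(i + di, j + dj, k + dk) for di, dj, dk in HEX_VTK_CORNERS]
    elements = np.stack(corners, axis=1)
    return Mesh(nodes, elements, "hexahedron",
                np.zeros(elements.shape[0], dtype=np.int64))


def build_subdomains(mesh: Mesh, specs) -> SubdomainPartition:
    """Partition a labelled mesh according to a list of SubdomainSpec.

    Every element label must be claimed by exactly one spec; duplicate or
    missing claims are rejected.  Interface nodes belong to the node sets of
    all adjacent subdomains.
    """
    specs = list(specs)
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise MeshError("subdomain labels must be unique")
    claimed: dict[int, str] = {}
    for s in specs:
        for m in s.material_ids:
            if m in claimed:
                raise MeshError(
                    f"material id {m} claimed by both {claimed[m]!r} and "
                    f"{s.label!r}"
                )
            claimed[m] = s.label
    present = set(int(m) for m in np.unique(mesh.material_id))
    orphans = sorted(present - set(claimed))
    if orphans:
        raise MeshError(f"mesh labels not covered by any subdomain: {orphans}")

    element_sets = []
    node_sets = []
    for s in specs:
        mask = np.isin(mesh.material_id, sorted(s.material_ids))
        els = np.flatnonzero(mask)
        element_sets.append(els)
        node_sets.append(np.unique(mesh.elements[els]))

    active = np.zeros(mesh.n_nodes, dtype=bool)
    for s, ns in zip(specs, node_sets):
        if s.conductive:
            active[ns] = True
    return SubdomainPartition(mesh, specs, element_sets, node_sets,
                              np.flatnonzero(active))


def refine_hex_mesh(mesh: Mesh) -> Mesh:
    """Uniformly refine a hexahedral mesh, splitting each cell into 8.

    New nodes are placed at edge/face/cell trilinear midpoints and
    deduplicated across neighbouring elements.  Tetrahedral meshes are
    rejected (hierarchical refinement is only supported for hexahedra).
    """
    if mesh.element_kind != "hexahedron":
        raise MeshError("uniform refinement is only available for hexahedral meshes")
    verts = mesh.nodes[mesh.elements]  # (ne, 8, 3)
    # local 3x3x3 lattice per element, via the trilinear map
    t = np.array([0.0, 0.5, 1.0])
    pts = []
    lat = {}
    idx = 0
    for kk in t:
        for jj in t:
            for ii in t:
                lat[(ii, jj, kk)] = idx
                idx += 1
                # trilinear shape functions at (ii, jj, kk), VTK corner order
                x, y, z = ii, jj, kk
                N = np.array([
                    (1 - x) * (1 - y) * (1 - z),
                    x * (1 - y) * (1 - z),
                    x * y * (1 - z),
                    (1 - x) * y * (1 - z),
                    (1 - x) * (1 - y) * z,
                    x * (1 - y) * z,
                    x * y * z,
                    (1 - x) * y * z,
                ])
                pts.append(np.einsum("ev,evi->ei", N[None, :], verts))
    lattice_pts = np.stack(pts, axis=1)  # (ne, 27, 3)

    flat = lattice_pts.reshape(-1, 3)
    scale = max(np.ptp(mesh.nodes, axis=0).max(), 1.0e-30)
    keys = np.round(flat / (1e-10 * scale)).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True,
                                  return_inverse=True)
    new_nodes = flat[first]
    gl = inverse.reshape(lattice_pts.shape[0], 27)  # global lattice ids

    sub = []
    for kk in (0.0, 0.5):
        for jj in (0.0, 0.5):
            for ii in (0.0, 0.5):
                corner_ids = [
                    lat[(ii + 0.5 * di, jj + 0.5 * dj, kk + 0.5 * dk)]
                    for di, dj, dk in HEX_VTK_CORNERS
                ]
                sub.append(gl[:, corner_ids])
    elements = np.concatenate(sub, axis=0)
    material = np.tile(mesh.material_id, 8)
    return Mesh(new_nodes, elements, "hexahedron", material)


def mesh_hash(mesh: Mesh) -> str:
    """Stable content hash of a mesh (used to guard checkpoint restores)."""
    import hashlib

    h = hashlib.sha256()
    h.update(mesh.element_kind.encode())
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.elements).tobytes())
    h.update(np.ascontiguousarray(mesh.material_id).tobytes())
    return h.hexdigest()
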