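"""Finite-element spaces, quadrature, BDF time schemes and assembly.

The transmembrane potential and the ionic state are approximated as
continuous piecewise polynomials of degree p — Lagrange elements Q_p on
hexahedra (any p ≥ 1) and P_p on tetrahedra (p ∈ {1, 2}).  Integrals are
evaluated with Gauss–Legendre rules using the minimum number of points that
integrates the mass matrix exactly on affine elements: (p+1)³ tensor points
per hexahedron and a conical-product rule of matching degree per
tetrahedron.  The mass matrix is kept consistent (never lumped).

Time derivatives are discretized with backward differentiation formulas
(BDF) of order σ ∈ {1, 2, 3},

    ∂f/∂t ≈ (α f_{n+1} − f_BDF,n) / Δt,   f_BDF,n = Σ_k b_k f_{n−k},

paired with explicit extrapolations f_EXT,n+1 = Σ_k e_k f_{n−k} of the same
order, which linearize the reaction terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from numpy.polynomial.legendre import leggauss
from scipy.special import roots_jacobi

from .geometry import HEX_VTK_CORNERS, Mesh, MeshError

__all__ = [
    "FESpace",
    "TimeScheme",
    "bdf_scheme",
    "assemble_mass",
    "assemble_stiffness",
    "build_system_matrix",
    "element_mass_blocks",
]


# ---------------------------------------------------------------------------
# BDF / extrapolation schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeScheme:
    """BDF(σ) coefficients: α, history weights b_k, extrapolation weights e_k.

    The weights reproduce polynomials of degree < σ exactly (on a uniform
    time grid): Σ b_k interpolates the derivative relation, Σ e_k the value
    at t_{n+1}.
    """

    order: int
    alpha: float
    bdf_weights: tuple
    ext_weights: tuple

    def combine(self, weights, history):
        """Σ_k weights[k]·history[k]; history[0] is the newest level."""
        acc = weights[0] * history[0]
        for w, h in zip(weights[1:], history[1:]):
            acc = acc + w * h
        return acc


_BDF_TABLE = {
    1: (1.0, (1.0,), (1.0,)),
    2: (1.5, (2.0, -0.5), (2.0, -1.0)),
    3: (11.0 / 6.0, (3.0, -1.5, 1.0 / 3.0), (3.0, -3.0, 1.0)),
}


def bdf_scheme(order: int) -> TimeScheme:
    """Return the BDF/extrapolation scheme of order σ ∈ {1, 2, 3}."""
    if order not in _BDF_TABLE:
        raise ValueError(f"BDF order must be 1, 2 or 3, got {order}")
    alpha, b, e = _BDF_TABLE[order]
    return TimeScheme(order, alpha, b, e)


# ---------------------------------------------------------------------------
# Reference elements and quadrature
# ---------------------------------------------------------------------------

def _gauss01(n: int):
    """n-point Gauss–Legendre rule on [0, 1]."""
    x, w = leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


@lru_cache(maxsize=None)
def hex_quadrature(p: int):
    """(p+1)³ tensor Gauss points on the unit cube (exact to degree 2p+1)."""
    x, w = _gauss01(p + 1)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    W = np.einsum("i,j,k->ijk", w, w, w)
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    return pts, W.ravel()


@lru_cache(maxsize=None)
def tet_quadrature(p: int):
    """Conical-product Gauss–Jacobi rule on the reference tetrahedron.

    With m = p+1 points per direction the rule integrates polynomials of
    degree ≤ 2m−1 ≥ 2p exactly, which makes the P_p mass matrix exact.
    Reference tet: vertices (0,0,0), (1,0,0), (0,1,0), (0,0,1).
    """
    m = p + 1
    # roots_jacobi works on [-1,1] with weight (1-x)^a (1+x)^b
    x1, w1 = roots_jacobi(m, 2.0, 0.0)
    x2, w2 = roots_jacobi(m, 1.0, 0.0)
    x3, w3 = leggauss(m)
    # map to [0,1]; absorb the Jacobi weight factors (1-t)^k
    t1, u1 = 0.5 * (x1 + 1.0), w1 / 8.0   # weight includes (1-t1)^2 /(2^2 scaling)
    t2, u2 = 0.5 * (x2 + 1.0), w2 / 4.0   # includes (1-t2)
    t3, u3 = 0.5 * (x3 + 1.0), 0.5 * np.asarray(w3)
    pts = []
    wts = []
    for a, wa in zip(t1, u1):
        for b, wb in zip(t2, u2):
            for c, wc in zip(t3, u3):
                x = a
                y = b * (1.0 - a)
                z = c * (1.0 - a) * (1.0 - b)
                pts.append((x, y, z))
                wts.append(wa * wb * wc)
    return np.asarray(pts), np.asarray(wts)


def _lagrange_1d(p: int, nodes: np.ndarray, x: np.ndarray):
    """Values and derivatives of the p+1 1D Lagrange basis at points x."""
    n = p + 1
    vals = np.ones((len(x), n))
    ders = np.zeros((len(x), n))
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            vals[:, i] *= (x - nodes[j]) / (nodes[i] - nodes[j])
        for k in range(n):
            if k == i:
                continue
            term = np.ones(len(x)) / (nodes[i] - nodes[k])
            for j in range(n):
                if j in (i, k):
                    continue
                term *= (x - nodes[j]) / (nodes[i] - nodes[j])
            ders[:, i] += term
    return vals, ders


def hex_basis(p: int, points: np.ndarray):
    """Tensor Lagrange basis on the unit cube at given reference points.

    Local DOF ordering is lexicographic on the (p+1)³ lattice (x fastest).
    Returns (phi (nq, nloc), dphi (nq, nloc, 3), lattice (nloc, 3) in [0,1]).
    """
    nodes = np.linspace(0.0, 1.0, p + 1)
    vx, dx_ = _lagrange_1d(p, nodes, points[:, 0])
    vy, dy_ = _lagrange_1d(p, nodes, points[:, 1])
    vz, dz_ = _lagrange_1d(p, nodes, points[:, 2])
    nloc = (p + 1) ** 3
    nq = len(points)
    phi = np.empty((nq, nloc))
    dphi = np.empty((nq, nloc, 3))
    lattice = np.empty((nloc, 3))
    idx = 0
    for k in range(p + 1):
        for j in range(p + 1):
            for i in range(p + 1):
                phi[:, idx] = vx[:, i] * vy[:, j] * vz[:, k]
                dphi[:, idx, 0] = dx_[:, i] * vy[:, j] * vz[:, k]
                dphi[:, idx, 1] = vx[:, i] * dy_[:, j] * vz[:, k]
                dphi[:, idx, 2] = vx[:, i] * vy[:, j] * dz_[:, k]
                lattice[idx] = (nodes[i], nodes[j], nodes[k])
                idx += 1
    return phi, dphi, lattice


def tet_basis(p: int, points: np.ndarray):
    """P1/P2 Lagrange basis on the reference tetrahedron."""
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    lam = np.stack([1.0 - x - y - z, x, y, z], axis=1)  # barycentric
    dlam = np.array([
        [-1.0, -1.0, -1.0],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
    ])
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    if p == 1:
        phi = lam
        dphi = np.broadcast_to(dlam[None, :, :], (len(points), 4, 3)).copy()
        return phi, dphi, verts
    if p == 2:
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        nq = len(points)
        phi = np.empty((nq, 10))
        dphi = np.empty((nq, 10, 3))
        for i in range(4):
            phi[:, i] = lam[:, i] * (2.0 * lam[:, i] - 1.0)
            dphi[:, i, :] = (4.0 * lam[:, i] - 1.0)[:, None] * dlam[i]
        for e, (a, b) in enumerate(edges):
            phi[:, 4 + e] = 4.0 * lam[:, a] * lam[:, b]
            dphi[:, 4 + e, :] = 4.0 * (
                lam[:, a][:, None] * dlam[b] + lam[:, b][:, None] * dlam[a]
            )
        support = np.vstack([verts, [(verts[a] + verts[b]) / 2.0
                                     for a, b in edges]])
        return phi, dphi, support
    raise MeshError("tetrahedral elements support degrees 1 and 2 only")


# map VTK hex corner order -> lexicographic lattice corner index (p=1)
_HEX_VTK_TO_LEX = np.array(
    [c[0] + 2 * c[1] + 4 * c[2] for c in HEX_VTK_CORNERS]
)


# ---------------------------------------------------------------------------
# FE space
# ---------------------------------------------------------------------------

class FESpace:
    """A scalar H¹-conforming Lagrange space of degree p on a mesh.

    Attributes
    ----------
    element_dofs : (n_elements, n_loc) global DOF per element, matching the
        local ordering of the reference basis.
    support_points : (n_dofs, 3) coordinates of the Lagrange nodes; for
        p = 1 these are exactly the mesh nodes in mesh order.
    """

    def __init__(self, mesh: Mesh, degree: int = 1):
        if degree < 1:
            raise MeshError("FE degree must be >= 1")
        if mesh.element_kind == "tetrahedron" and degree not in (1, 2):
            raise MeshError("tetrahedral meshes support degrees 1 and 2 only")
        self.mesh = mesh
        self.degree = int(degree)
        self._build()

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        mesh, p = self.mesh, self.degree
        if mesh.element_kind == "hexahedron":
            self.quad_points, self.quad_weights = hex_quadrature(p)
            self.phi, self.dphi, ref_support = hex_basis(p, self.quad_points)
            # geometry is trilinear: shape functions of the 8 VTK corners
            gphi, gdphi, _ = hex_basis(1, self.quad_points)
            self.geo_phi = gphi[:, _HEX_VTK_TO_LEX]
            self.geo_dphi = gdphi[:, _HEX_VTK_TO_LEX, :]
            self.affine_geometry = False
        else:
            self.quad_points, self.quad_weights = tet_quadrature(p)
            self.phi, self.dphi, ref_support = tet_basis(p, self.quad_points)
            gphi, gdphi, _ = tet_basis(1, self.quad_points)
            self.geo_phi = gphi
            self.geo_dphi = gdphi
            self.affine_geometry = True
        self._ref_support = ref_support
        self._number_dofs()

    def _number_dofs(self) -> None:
        mesh, p = self.mesh, self.degree
        if p == 1:
            if mesh.element_kind == "hexahedron":
                # reference lattice corner -> VTK corner column
                lex_to_vtk = np.argsort(_HEX_VTK_TO_LEX)
                self.element_dofs = mesh.elements[:, lex_to_vtk]
            else:
                self.element_dofs = mesh.elements.copy()
            self.support_points = mesh.nodes
            self.n_dofs = mesh.n_nodes
            return
        # higher order: map reference support points through the geometry
        # and deduplicate shared points across elements
        verts = mesh.nodes[mesh.elements]  # (ne, nvgeo, 3)
        if mesh.element_kind == "hexahedron":
            gphi, _, _ = hex_basis(1, self._ref_support)
            gphi = gphi[:, _HEX_VTK_TO_LEX]
        else:
            gphi, _, _ = tet_basis(1, self._ref_support)
        pts = np.einsum("sv,evi->esi", gphi, verts)  # (ne, nloc, 3)
        flat = pts.reshape(-1, 3)
        scale = max(np.ptp(mesh.nodes, axis=0).max(), 1e-30)
        keys = np.round(flat / (1e-8 * scale)).astype(np.int64)
        uniq, first, inverse = np.unique(keys, axis=0, return_index=True,
                                         return_inverse=True)
        self.support_points = flat[np.sort(first)]
        # renumber so DOF order follows first appearance
        order = np.argsort(first)
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        self.element_dofs = rank[inverse].reshape(pts.shape[0], pts.shape[1])
        self.n_dofs = len(uniq)

    # -- geometry at quadrature points -------------------------------------

    def jacobians(self, element_ids=None):
        """Jacobians J, |det J| and J^{-T} at quadrature points.

        Returns (detJ (ne, nq), invJT (ne, nq, 3, 3)).  Raises on degenerate
        (non-positive determinant) elements, reporting the element index.
        """
        els = self.mesh.elements if element_ids is None else \
            self.mesh.elements[element_ids]
        verts = self.mesh.nodes[els]
        J = np.einsum("evi,qvj->eqij", verts, self.geo_dphi)
        detJ = np.linalg.det(J)
        if (detJ <= 0).any():
            bad = np.argwhere(detJ <= 0)[0][0]
            gid = bad if element_ids is None else np.asarray(element_ids)[bad]
            raise MeshError(f"degenerate element {gid}: non-positive Jacobian")
        invJT = np.linalg.inv(J).transpose(0, 1, 3, 2)
        return detJ, invJT

    def subdomain_dofs(self, element_ids) -> np.ndarray:
        """Sorted unique DOFs supported on the given elements."""
        return np.unique(self.element_dofs[np.asarray(element_ids, dtype=np.int64)])


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

_CHUNK = 20000  # elements per assembly chunk (bounds peak memory)


def _accumulate_coo(space, element_ids, block_fn):
    """Assemble Σ_e block_fn(e) into a CSR matrix over all space DOFs."""
    n = space.n_dofs
    element_ids = (np.arange(space.mesh.n_elements, dtype=np.int64)
                   if element_ids is None else
                   np.asarray(element_ids, dtype=np.int64))
    rows, cols, vals = [], [], []
    for start in range(0, len(element_ids), _CHUNK):
        ids = element_ids[start:start + _CHUNK]
        blocks = block_fn(ids)  # (ne, nloc, nloc)
        ed = space.element_dofs[ids]
        nloc = ed.shape[1]
        rows.append(np.repeat(ed, nloc, axis=1).ravel())
        cols.append(np.tile(ed, (1, nloc)).ravel())
        vals.append(blocks.ravel())
    if not rows:
        return sp.csr_matrix((n, n))
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    A.sum_duplicates()
    return A


def _mass_blocks(space, ids):
    detJ, _ = space.jacobians(ids)
    w = space.quad_weights
    return np.einsum("q,eq,ql,qm->elm", w, detJ, space.phi, space.phi,
                     optimize=True)


def assemble_mass(space: FESpace, element_ids=None) -> sp.csr_matrix:
    """Consistent mass matrix M_jk = ∫ φ_k φ_j dx over an element subset.

    With no subset, the integral runs over the whole mesh; the sum of all
    entries then equals the mesh volume (partition of unity).
    """
    return _accumulate_coo(space, element_ids, lambda ids: _mass_blocks(space, ids))


def element_mass_blocks(space: FESpace, element_ids=None) -> np.ndarray:
    """Per-element mass blocks (ne, nloc, nloc), used by the ICI term."""
    element_ids = (np.arange(space.mesh.n_elements, dtype=np.int64)
                   if element_ids is None else
                   np.asarray(element_ids, dtype=np.int64))
    out = np.empty((len(element_ids), space.phi.shape[1], space.phi.shape[1]))
    for start in range(0, len(element_ids), _CHUNK):
        ids = element_ids[start:start + _CHUNK]
        out[start:start + len(ids)] = _mass_blocks(space, ids)
    return out


def assemble_stiffness(space: FESpace, diffusion, element_ids=None) -> sp.csr_matrix:
    """Anisotropic stiffness K_jk = ∫ D ∇φ_k · ∇φ_j dx.

    ``diffusion`` is either a constant 3×3 tensor, or a callable
    ``diffusion(element_ids, quad_xyz) -> (ne, nq, 3, 3)`` returning the
    tensor at the physical quadrature points of the listed elements (this is
    how fiber-based anisotropy enters; see fibers.assemble_diffusion).
    K is symmetric positive semidefinite and annihilates constants.
    """
    Dconst = None
    if not callable(diffusion):
        Dconst = np.asarray(diffusion, dtype=np.float64)
        if Dconst.shape == ():
            Dconst = Dconst * np.eye(3)

    def blocks(ids):
        detJ, invJT = space.jacobians(ids)
        # physical gradients: g[e,q,l,i] = invJT[e,q,i,j] dphi[q,l,j]
        g = np.einsum("eqij,qlj->eqli", invJT, space.dphi, optimize=True)
        if Dconst is not None:
            D = np.broadcast_to(Dconst, (len(ids), len(space.quad_weights), 3, 3))
        else:
            verts = space.mesh.nodes[space.mesh.elements[ids]]
            xq = np.einsum("qv,evi->eqi", space.geo_phi, verts)
            D = diffusion(ids, xq)
        Dg = np.einsum("eqij,eqlj->eqli", D, g, optimize=True)
        return np.einsum("q,eq,eqli,eqmi->elm", space.quad_weights, detJ, g,
                         Dg, optimize=True)

    K = _accumulate_coo(space, element_ids, blocks)
    return K


def build_system_matrix(scheme: TimeScheme, dt: float, M: sp.spmatrix,
                        K: sp.spmatrix) -> sp.csr_matrix:
    """System matrix A = (α_BDF/Δt) M + K of the time-discrete monodomain.

    A is assembled once per run (it does not change between steps) and is
    symmetric positive definite on the active DOFs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return (scheme.alpha / dt) * M.tocsr() + K.tocsr()
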