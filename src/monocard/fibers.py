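"""Myocardial fiber architecture and the anisotropic diffusion tensor.

Conduction in the myocardium is fastest along the muscle fibers f0, slower
along the sheetlet direction s0 and slowest along the sheet normal n0.  The
local orthonormal triplet (f0, s0, n0) defines the diffusion tensor

    D = σ_l f0⊗f0 + σ_t s0⊗s0 + σ_n n0⊗n0,

whose eigenvalues are exactly the three conductivities (in m²/s).

Two ways of prescribing the frame are supported: import from a VTU file
carrying three normalized point-data vector arrays, or the rule-based slab
construction in which the fiber angle rotates linearly across the wall,
driven by a transmural Laplace coordinate φ (φ = 0 on the endocardial face,
φ = 1 on the epicardial face).  Full ventricular/atrial rule-based methods
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from . import io as mio
from .fem import FESpace, assemble_stiffness
from .geometry import Mesh, MeshError

__all__ = [
    "FiberFrame",
    "transmural_laplace",
    "slab_fiber_rule",
    "axis_aligned_frame",
    "import_fibers",
    "export_fibers",
    "diffusion_tensor",
    "make_diffusion_callable",
]

DEFAULT_ARRAY_NAMES = ("fibers", "sheets", "sheet_normals")


@dataclass
class FiberFrame:
    """Per-DOF orthonormal triplet (f0, s0, n0), each of shape (n, 3)."""

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    def __post_init__(self):
        for name in ("f0", "s0", "n0"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name),
                                                     dtype=np.float64))
        if not (self.f0.shape == self.s0.shape == self.n0.shape):
            raise ValueError("f0, s0, n0 must have identical shapes")

    @property
    def n_points(self) -> int:
        return self.f0.shape[0]

    def validate(self, tol: float = 1e-6) -> None:
        """Check unit norms and pairwise orthogonality to ``tol``."""
        for name, v in (("f0", self.f0), ("s0", self.s0), ("n0", self.n0)):
            err = np.abs(np.linalg.norm(v, axis=1) - 1.0).max()
            if err > tol:
                raise ValueError(f"{name} is not unit-norm (max error {err:.2e})")
        for a, b, pair in ((self.f0, self.s0, "f0·s0"),
                           (self.f0, self.n0, "f0·n0"),
                           (self.s0, self.n0, "s0·n0")):
            err = np.abs(np.einsum("ni,ni->n", a, b)).max()
            if err > tol:
                raise ValueError(f"frame not orthogonal: max |{pair}| = {err:.2e}")


def _as_space(mesh_or_space, degree: int = 1) -> FESpace:
    if isinstance(mesh_or_space, FESpace):
        return mesh_or_space
    return FESpace(mesh_or_space, degree)


def transmural_laplace(mesh_or_space, endo_face_selector, epi_face_selector,
                       tol: float = 1e-10) -> np.ndarray:
    """Harmonic transmural coordinate φ with φ=0 / φ=1 on two face sets.

    The selectors are vectorized predicates on DOF coordinates,
    ``selector(points (n,3)) -> bool mask``; natural (zero-flux) conditions
    hold elsewhere.  By the maximum principle 0 ≤ φ ≤ 1.
    """
    space = _as_space(mesh_or_space)
    pts = space.support_points
    m0 = np.asarray(endo_face_selector(pts), dtype=bool)
    m1 = np.asarray(epi_face_selector(pts), dtype=bool)
    if not m0.any() or not m1.any():
        raise MeshError("both Dirichlet face sets must be non-empty")
    if (m0 & m1).any():
        raise MeshError("endocardial and epicardial face sets overlap")

    K = assemble_stiffness(space, np.eye(3))
    phi = np.zeros(space.n_dofs)
    phi[m1] = 1.0
    free = ~(m0 | m1)
    rhs = -np.asarray(K[free][:, m1].sum(axis=1)).ravel()
    Kff = K[free][:, free].tocsc()
    phi[free] = spla.spsolve(Kff, rhs)
    return np.clip(phi, 0.0, 1.0)  # clip FP noise outside [0,1]


def _orthonormalize(f, s, n):
    """Gram–Schmidt with f-priority; returns unit, pairwise-orthogonal rows."""
    f = f / np.linalg.norm(f, axis=1, keepdims=True)
    s = s - np.einsum("ni,ni->n", s, f)[:, None] * f
    s = s / np.linalg.norm(s, axis=1, keepdims=True)
    n = np.cross(f, s)
    return f, s, n


def slab_fiber_rule(mesh_or_space, phi, endo_angle_deg: float,
                    epi_angle_deg: float, long_axis=(0.0, 0.0, 1.0),
                    transmural_axis=(0.0, 1.0, 0.0)) -> FiberFrame:
    """Rule-based slab frame with linear transmural fiber rotation.

    The fiber angle α(φ) = endo + φ·(epi − endo) (degrees) is measured from
    the slab long axis, rotating within the sheet plane orthogonal to the
    transmural direction; n0 is transmural everywhere.  For example angles
    (60, −60) rotate the fibers from +60° at the endocardium (φ=0) through
    0° at mid-wall to −60° at the epicardium (φ=1).
    """
    space = _as_space(mesh_or_space)
    phi = np.asarray(phi, dtype=np.float64)
    if phi.shape != (space.n_dofs,):
        raise ValueError("phi must be a per-DOF scalar field")
    if phi.min() < -1e-12 or phi.max() > 1.0 + 1e-12:
        raise ValueError("phi must lie in [0, 1]")

    ez = np.asarray(long_axis, dtype=np.float64)
    ez = ez / np.linalg.norm(ez)
    en = np.asarray(transmural_axis, dtype=np.float64)
    en = en - (en @ ez) * ez
    nrm = np.linalg.norm(en)
    if nrm < 1e-12:
        raise ValueError("transmural axis must not be parallel to the long axis")
    en = en / nrm
    ec = np.cross(en, ez)  # in-plane direction orthogonal to the long axis

    alpha = np.deg2rad(endo_angle_deg + phi * (epi_angle_deg - endo_angle_deg))
    f0 = np.cos(alpha)[:, None] * ez + np.sin(alpha)[:, None] * ec
    n0 = np.broadcast_to(en, f0.shape).copy()
    s0 = np.cross(n0, f0)
    f0, s0, n0 = _orthonormalize(f0, s0, np.cross(f0, s0))
    return FiberFrame(f0, s0, n0)


def axis_aligned_frame(n_points: int, f_axis=(0.0, 0.0, 1.0),
                       s_axis=(1.0, 0.0, 0.0)) -> FiberFrame:
    """Spatially constant frame (e.g. slab-benchmark fibers along the long axis)."""
    f = np.tile(np.asarray(f_axis, float), (n_points, 1))
    s = np.tile(np.asarray(s_axis, float), (n_points, 1))
    f, s, n = _orthonormalize(f, s, None)
    return FiberFrame(f, s, n)


def import_fibers(path, scaling_factor: float, mesh_or_space,
                  array_names=DEFAULT_ARRAY_NAMES) -> FiberFrame:
    """Read (f0, s0, n0) point-data arrays from a VTU file.

    The file's point set, after coordinate rescaling, must coincide with the
    space's support points (to 1e-8 of the mesh scale).  Vectors are
    re-normalized on import; near-zero vectors are rejected naming the node.
    """
    space = _as_space(mesh_or_space)
    fmesh, point_data, _ = mio.read_vtu(path, return_data=True)
    pts = fmesh.nodes * float(scaling_factor)
    if pts.shape != space.support_points.shape:
        raise MeshError(
            f"fiber file has {pts.shape[0]} points, mesh has "
            f"{space.support_points.shape[0]} DOFs"
        )
    scale = max(np.ptp(space.support_points, axis=0).max(), 1e-30)
    if np.abs(pts - space.support_points).max() > 1e-8 * scale:
        raise MeshError("fiber file point coordinates do not match the mesh")

    vecs = []
    for name in array_names:
        if name not in point_data:
            raise MeshError(f"fiber file is missing point-data array {name!r}")
        v = np.asarray(point_data[name], dtype=np.float64)
        if v.shape != (space.n_dofs, 3):
            raise MeshError(f"array {name!r} must have shape (n_points, 3)")
        norms = np.linalg.norm(v, axis=1)
        bad = np.flatnonzero(norms < 1e-8)
        if bad.size:
            raise MeshError(f"array {name!r}: zero-length vector at node {bad[0]}")
        vecs.append(v / norms[:, None])
    f0, s0, n0 = _orthonormalize(*vecs)
    return FiberFrame(f0, s0, n0)


def export_fibers(path, mesh_or_space, frame: FiberFrame,
                  array_names=DEFAULT_ARRAY_NAMES) -> None:
    """Write a frame as VTU point-data arrays (inverse of import_fibers)."""
    space = _as_space(mesh_or_space)
    if space.degree != 1:
        raise MeshError("fiber export writes nodal (degree-1) data")
    mio.write_vtu(path, space.mesh, point_data={
        array_names[0]: frame.f0,
        array_names[1]: frame.s0,
        array_names[2]: frame.n0,
    })


def diffusion_tensor(frame: FiberFrame, sigma_l: float, sigma_t: float,
                     sigma_n: float) -> np.ndarray:
    """Per-point tensors D = σ_l f⊗f + σ_t s⊗s + σ_n n⊗n, shape (n, 3, 3)."""
    for name, s in (("sigma_l", sigma_l), ("sigma_t", sigma_t),
                    ("sigma_n", sigma_n)):
        if s < 0:
            raise ValueError(f"{name} must be non-negative")
    return (sigma_l * np.einsum("ni,nj->nij", frame.f0, frame.f0)
            + sigma_t * np.einsum("ni,nj->nij", frame.s0, frame.s0)
            + sigma_n * np.einsum("ni,nj->nij", frame.n0, frame.n0))


def make_diffusion_callable(space: FESpace, frame: FiberFrame, sigma_l: float,
                            sigma_t: float, sigma_n: float):
    """Diffusion evaluator at quadrature points for stiffness assembly.

    The nodal frame is interpolated to quadrature points with the FE basis
    and re-orthonormalized there (Gram–Schmidt, fiber priority), so that the
    tensor eigenvalues remain exactly {σ_l, σ_t, σ_n} at every quadrature
    point.
    """
    if frame.n_points != space.n_dofs:
        raise ValueError("frame must be defined at the space support points")

    def diffusion(element_ids, xq):
        ed = space.element_dofs[element_ids]
        shape = (len(element_ids), space.phi.shape[0], 3)
        f = np.einsum("ql,eli->eqi", space.phi, frame.f0[ed]).reshape(-1, 3)
        s = np.einsum("ql,eli->eqi", space.phi, frame.s0[ed]).reshape(-1, 3)
        f, s, n = _orthonormalize(f, s, None)
        D = (sigma_l * np.einsum("ni,nj->nij", f, f)
             + sigma_t * np.einsum("ni,nj->nij", s, s)
             + sigma_n * np.einsum("ni,nj->nij", n, n))
        return D.reshape(shape[0], shape[1], 3, 3)

    return diffusion
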