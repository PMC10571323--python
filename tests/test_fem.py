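"""FE spaces, quadrature exactness, BDF schemes and operator assembly."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from monocard.bench import hex_to_tet_mesh
from monocard.fem import (FESpace, assemble_mass, assemble_stiffness,
                          bdf_scheme, build_system_matrix, hex_quadrature,
                          tet_quadrature)
from monocard.geometry import build_slab_mesh


# ---------------------------------------------------------------------------
# BDF schemes
# ---------------------------------------------------------------------------

def _lagrange_weights_oracle(order):
    """Independent derivation of the BDF weights via Lagrange interpolation.

    Interpolate f at t_{n+1}, t_n, ..., t_{n+1-order} (unit spacing), then
    alpha and the history weights follow from the derivative of the
    interpolant at t_{n+1}; the extrapolation weights from evaluating the
    history-only interpolant at t_{n+1}.
    """
    ts = np.arange(order + 1)  # t_{n+1-order} ... t_{n+1} in units of dt
    n = order + 1

    def lagrange_deriv_at(k, x, nodes):
        tot = 0.0
        for m in range(len(nodes)):
            if m == k:
                continue
            p = 1.0 / (nodes[k] - nodes[m])
            for j in range(len(nodes)):
                if j in (k, m):
                    continue
                p *= (x - nodes[j]) / (nodes[k] - nodes[j])
            tot += p
        return tot

    derivs = [lagrange_deriv_at(k, ts[-1], ts) for k in range(n)]
    alpha = derivs[-1]
    bdf = [-d for d in derivs[:-1]][::-1]  # newest-history first
    hist = ts[:-1]
    ext = []
    for k in range(order):
        p = 1.0
        for j in range(order):
            if j != k:
                p *= (ts[-1] - hist[j]) / (hist[k] - hist[j])
        ext.append(p)
    return alpha, bdf, ext[::-1]


@pytest.mark.parametrize("order", [1, 2, 3])
def test_bdf_weights_match_lagrange_oracle(order):
    scheme = bdf_scheme(order)
    alpha, bdf, ext = _lagrange_weights_oracle(order)
    assert np.isclose(scheme.alpha, alpha)
    assert np.allclose(scheme.bdf_weights, bdf)
    assert np.allclose(scheme.ext_weights, ext)


def test_bdf_known_coefficients():
    s1, s2, s3 = bdf_scheme(1), bdf_scheme(2), bdf_scheme(3)
    assert s1.alpha == 1.0 and s1.bdf_weights == (1.0,)
    assert s2.alpha == 1.5 and s2.bdf_weights == (2.0, -0.5)
    assert s2.ext_weights == (2.0, -1.0)
    assert np.isclose(s3.alpha, 11 / 6)
    assert np.allclose(s3.bdf_weights, (3.0, -1.5, 1 / 3))
    assert s3.ext_weights == (3.0, -3.0, 1.0)
    with pytest.raises(ValueError):
        bdf_scheme(4)


def _integrate_decay(order, dt, T=1.0, lam=-1.0):
    """u' = lam*u with the implicit BDF update; exact history start-up."""
    scheme = bdf_scheme(order)
    n = int(round(T / dt))
    hist = [np.exp(lam * (-k) * dt) for k in range(order)]  # newest first
    for step in range(n):
        u_bdf = scheme.combine(scheme.bdf_weights, hist)
        u_new = u_bdf / (scheme.alpha - dt * lam)
        hist = [u_new] + hist[: order - 1]
    return hist[0]


@pytest.mark.parametrize("order", [1, 2, 3])
def test_bdf_observed_convergence_order(order):
    errs = []
    for dt in (0.01, 0.005, 0.0025):
        errs.append(abs(_integrate_decay(order, dt) - np.exp(-1.0)))
    rates = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
    assert np.allclose(rates, order, atol=0.1)


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p", [1, 2])
def test_hex_quadrature_integrates_degree_2p_monomials(p):
    pts, w = hex_quadrature(p)
    assert len(w) == (p + 1) ** 3
    rng = np.random.default_rng(0)
    for _ in range(10):
        a, b, c = rng.integers(0, 2 * p + 1, size=3)
        val = np.sum(w * pts[:, 0] ** a * pts[:, 1] ** b * pts[:, 2] ** c)
        exact = 1.0 / ((a + 1) * (b + 1) * (c + 1))
        assert np.isclose(val, exact, rtol=1e-13)


@pytest.mark.parametrize("p", [1, 2])
def test_tet_quadrature_integrates_degree_2p_monomials(p):
    from math import factorial

    pts, w = tet_quadrature(p)
    for a in range(2 * p + 1):
        for b in range(2 * p + 1 - a):
            for c in range(2 * p + 1 - a - b):
                val = np.sum(w * pts[:, 0] ** a * pts[:, 1] ** b
                             * pts[:, 2] ** c)
                exact = (factorial(a) * factorial(b) * factorial(c)
                         / factorial(a + b + c + 3))
                assert np.isclose(val, exact, rtol=1e-12), (a, b, c)


# ---------------------------------------------------------------------------
# spaces and assembly
# ---------------------------------------------------------------------------

def _spaces():
    hexm = build_slab_mesh((2e-3, 1e-3, 1e-3), 0.5e-3)
    tetm = hex_to_tet_mesh(hexm)
    return [
        FESpace(hexm, 1), FESpace(hexm, 2),
        FESpace(tetm, 1), FESpace(tetm, 2),
    ]


@pytest.mark.parametrize("space", _spaces(),
                         ids=["hexQ1", "hexQ2", "tetP1", "tetP2"])
def test_mass_sum_equals_mesh_volume(space):
    M = assemble_mass(space)
    assert np.isclose(M.sum(), 2e-9, rtol=1e-12)


def test_unit_cube_q1_mass_diagonal_is_1_27():
    mesh = build_slab_mesh((1.0, 1.0, 1.0), 1.0)
    M = assemble_mass(FESpace(mesh, 1)).toarray()
    assert np.allclose(np.diag(M), 1.0 / 27.0, rtol=1e-14)
    assert np.isclose(M.sum(), 1.0, rtol=1e-14)


def test_mass_subset_additivity():
    mesh = build_slab_mesh((2.0, 1.0, 1.0), 1.0)
    space = FESpace(mesh, 1)
    M = assemble_mass(space)
    M0 = assemble_mass(space, [0])
    M1 = assemble_mass(space, [1])
    assert abs(M - (M0 + M1)).max() < 1e-15


@pytest.mark.parametrize("space", _spaces(),
                         ids=["hexQ1", "hexQ2", "tetP1", "tetP2"])
def test_stiffness_annihilates_constants_and_is_symmetric_psd(space):
    K = assemble_stiffness(space, 2.5 * np.eye(3))
    scale = abs(K).max()
    ones = np.ones(space.n_dofs)
    assert np.abs(K @ ones).max() < 1e-12 * scale
    assert abs(K - K.T).max() < 1e-13 * scale
    eigs = np.linalg.eigvalsh(K.toarray())
    assert eigs.min() > -1e-12 * eigs.max()


def test_stiffness_matches_hand_assembled_p1_laplacian():
    """Brute-force per-element oracle on a 2-tet mesh: for affine P1
    elements K_e = sigma * |T| * G G^T with G the barycentric gradients."""
    import numpy.linalg as la

    from monocard.geometry import Mesh

    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [1, 1, 1]])
    elements = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    mesh = Mesh(nodes, elements, "tetrahedron", np.zeros(2, dtype=int))
    sigma = 3.7
    K = assemble_stiffness(FESpace(mesh, 1), sigma * np.eye(3)).toarray()

    K_ref = np.zeros((5, 5))
    for el in elements:
        v = nodes[el]
        A = np.column_stack([v[1] - v[0], v[2] - v[0], v[3] - v[0]])
        vol = abs(la.det(A)) / 6.0
        grads_ref = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        grads = grads_ref @ la.inv(A)
        K_ref[np.ix_(el, el)] += sigma * vol * grads @ grads.T
    assert np.allclose(K, K_ref, rtol=1e-12, atol=1e-15)


def test_anisotropic_stiffness_quadratic_form_scales_with_sigma_l():
    """Doubling sigma_l doubles x^T K x for a field linear along f0."""
    from monocard.fibers import axis_aligned_frame, make_diffusion_callable

    mesh = build_slab_mesh((2e-3, 1e-3, 1e-3), 0.5e-3)
    space = FESpace(mesh, 1)
    frame = axis_aligned_frame(space.n_dofs, f_axis=(1, 0, 0),
                               s_axis=(0, 1, 0))
    x = space.support_points @ np.array([1.0, 0.0, 0.0])  # linear in f0
    forms = []
    for sl in (1e-4, 2e-4):
        K = assemble_stiffness(
            space, make_diffusion_callable(space, frame, sl, 3e-5, 1e-5))
        forms.append(x @ (K @ x))
    assert np.isclose(forms[1], 2.0 * forms[0], rtol=1e-12)


def test_system_matrix_composition_and_reuse():
    mesh = build_slab_mesh((1e-3, 1e-3, 1e-3), 0.5e-3)
    space = FESpace(mesh, 1)
    M = assemble_mass(space)
    K = assemble_stiffness(space, 1e-4 * np.eye(3))
    scheme = bdf_scheme(2)
    dt = 1e-4
    A = build_system_matrix(scheme, dt, M, K)
    assert abs(A - ((scheme.alpha / dt) * M + K)).max() == 0.0
    # K = 0 collapse
    A0 = build_system_matrix(scheme, dt, M, K * 0.0)
    assert abs(A0 - (scheme.alpha / dt) * M).max() == 0.0
    # SPD on (all-active) DOFs
    eigs = np.linalg.eigvalsh(A.toarray())
    assert eigs.min() > 0
    with pytest.raises(ValueError):
        build_system_matrix(scheme, 0.0, M, K)


def test_system_matrix_object_reused_between_steps():
    """The simulator assembles the matrix once and reuses the same object."""
    import monocard as mc
    from monocard.solver import LinearSolverSettings

    mesh = build_slab_mesh((1e-3,) * 3, 0.5e-3)
    frame = mc.axis_aligned_frame(mesh.n_nodes)
    prob = mc.MonodomainProblem(
        mesh=mesh,
        subdomains=[mc.SubdomainSpec("t", frozenset({0}), 1e-5, 1e-5, 1e-5,
                                     "AlievPanfilov")],
        frame=frame, bdf_order=1, dt=1e-4, T=1e-3,
        linear_solver=LinearSolverSettings(method="direct"))
    sim = mc.MonodomainSimulator(prob)
    sim.step()
    A_first = sim._A[1]
    sim.step()
    assert sim._A[1] is A_first


def test_higher_order_spaces_share_interface_dofs():
    mesh = build_slab_mesh((2.0, 1.0, 1.0), 1.0)
    space = FESpace(mesh, 2)
    # 2 elements, (3x3x3) lattice each, sharing a 3x3 face: 45 unique DOFs
    assert space.n_dofs == 45
    shared = np.intersect1d(space.element_dofs[0], space.element_dofs[1])
    assert len(shared) == 9


def test_tet_degree_limited_to_two():
    tetm = hex_to_tet_mesh(build_slab_mesh((1.0, 1.0, 1.0), 1.0))
    with pytest.raises(Exception):
        FESpace(tetm, 3)


def test_degenerate_element_reported_with_index():
    from monocard.geometry import Mesh

    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0]])
    mesh = Mesh(nodes, np.array([[0, 1, 2, 3]]), "tetrahedron",
                np.zeros(1, dtype=int))
    with pytest.raises(Exception, match="0"):
        assemble_mass(FESpace(mesh, 1))
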