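"""The tissue time loop: 0D equivalence, conservation/symmetry properties,
activation mapping, partitions, ICI and checkpointing."""

import numpy as np
import pytest

import monocard as mc
from monocard.fem import FESpace, assemble_mass
from monocard.solver import (LinearSolverSettings, activation_from_series,
                             ici_ionic_vector)

MM = 1e-3


def _uniform_problem(model_name, amp, T=0.02, dt=2e-5, order=2, sigma=0.0):
    """One hex element with spatially uniform stimulus (0D-equivalent)."""
    mesh = mc.build_slab_mesh((MM,) * 3, MM)
    frame = mc.axis_aligned_frame(mesh.n_nodes)
    spec = mc.SubdomainSpec("t", frozenset({0}), sigma, sigma, sigma,
                            model_name)
    stim = mc.Stimulus("cube", {"center": (MM / 2,) * 3, "half_width": MM},
                       amplitude=amp, duration=0.002)
    return mc.MonodomainProblem(
        mesh=mesh, subdomains=[spec], frame=frame,
        protocol=mc.StimulusProtocol([stim]), bdf_order=order, dt=dt, T=T,
        linear_solver=LinearSolverSettings(method="direct"))


@pytest.mark.parametrize("model_name, amp", [
    ("AlievPanfilov", 120.0), ("BuenoOrovio", 300.0),
    ("TTP06", 60.0), ("CRN", 40.0),
])
def test_zero_conductivity_tissue_matches_0d_oracle(model_name, amp):
    """With K = 0 every DOF follows the standalone single-cell integrator
    to 1e-10 (same IMEX-BDF arithmetic, agreement limited by the mass-matrix
    solve round-off)."""
    prob = _uniform_problem(model_name, amp)
    sim = mc.MonodomainSimulator(prob)
    model = sim.models[0]
    _, tr = mc.single_cell_run(model, period=prob.T, n_cycles=1, dt=prob.dt,
                               amplitude=amp, duration=0.002,
                               order=prob.bdf_order, record=True)
    n_steps = int(round(prob.T / prob.dt))
    worst = 0.0
    for n in range(n_steps):
        sim.step()
        u_m = model.u_to_model(sim.u_hist[0])
        worst = max(worst, np.abs(u_m - tr["u"][n + 1]).max())
        worst = max(worst, np.abs(sim.w_hist[0][0]
                                  - tr["w"][:, n + 1][:, None]).max())
    assert worst < 1e-10


def test_rest_state_preserved_without_stimulus():
    """I_app = 0 from the exact resting equilibrium: u_n = u_0 to 1e-9."""
    mesh = mc.build_slab_mesh((2 * MM, MM, MM), MM)
    frame = mc.axis_aligned_frame(mesh.n_nodes)
    spec = mc.SubdomainSpec("t", frozenset({0}), 1e-4, 1e-5, 1e-5,
                            "AlievPanfilov")
    prob = mc.MonodomainProblem(
        mesh=mesh, subdomains=[spec], frame=frame, bdf_order=2,
        dt=1e-3, T=1.0, linear_solver=LinearSolverSettings(method="direct"))
    res = mc.run_simulation(prob)
    assert np.abs(res.u_final).max() < 1e-9
    assert not res.activation.activated.any()


def test_uniform_state_stays_uniform_under_uniform_stimulus():
    """Spatial symmetry: K·1 = 0, so a uniform state driven by a uniform
    current stays uniform at every step."""
    prob = _uniform_problem("TTP06", 60.0, sigma=9.5e-5, T=0.01)
    sim = mc.MonodomainSimulator(prob)
    for _ in range(int(round(prob.T / prob.dt))):
        sim.step()
        assert np.ptp(sim.u_hist[0]) < 1e-9


class TestActivationMap:
    def test_tanh_trace_activation_at_inflection(self):
        tstar, tau = 0.02, 0.004
        times = np.linspace(0, 0.05, 501)
        u = np.tanh((times - tstar) / tau)
        act = activation_from_series(times, u, rate_threshold=10.0)
        assert abs(act - tstar) <= times[1] - times[0] + 1e-12

    def test_constant_trace_never_activates(self):
        times = np.linspace(0, 1, 50)
        act = activation_from_series(times, np.full_like(times, -0.08))
        assert np.isnan(act)

    def test_stimulated_region_activates_first(self):
        """On a small excitable bar the earliest activation is inside the
        stimulus support."""
        mesh = mc.build_slab_mesh((4 * MM, MM, MM), 0.5 * MM)
        frame = mc.axis_aligned_frame(mesh.n_nodes, f_axis=(1, 0, 0),
                                      s_axis=(0, 1, 0))
        spec = mc.SubdomainSpec("t", frozenset({0}), 9.5e-5, 9.5e-5, 9.5e-5,
                                "BuenoOrovio")
        stim = mc.Stimulus("cube", {"center": (0.5 * MM, MM / 2, MM / 2),
                                    "half_width": (0.5 * MM, MM, MM)},
                           amplitude=300.0, duration=0.002)
        prob = mc.MonodomainProblem(
            mesh=mesh, subdomains=[spec], frame=frame,
            protocol=mc.StimulusProtocol([stim]), bdf_order=2, dt=5e-5,
            T=0.025, linear_solver=LinearSolverSettings(method="direct"))
        res = mc.run_simulation(prob)
        act = res.activation.full()
        assert np.isfinite(act).all()
        first = np.nanargmin(act)
        assert mesh.nodes[first, 0] <= MM + 1e-12
        # and the far end activates last
        assert np.nanargmax(act) in np.flatnonzero(
            mesh.nodes[:, 0] > 3.5 * MM - 1e-12)


class TestICI:
    def test_single_subdomain_collapse_and_zero(self):
        mesh = mc.build_slab_mesh((2 * MM, MM, MM), MM)
        space = FESpace(mesh, 1)
        M = assemble_mass(space)
        I = np.linspace(0.0, 1.0, space.n_dofs)
        assert np.allclose(ici_ionic_vector([M], [I]), M @ I)
        assert np.all(ici_ionic_vector([M], [np.zeros(space.n_dofs)]) == 0.0)

    def test_two_subdomain_sum_recovers_conductive_volume(self):
        """With I_ion = 1 everywhere, sum_j s_j = measure of the conductive
        region (partition of unity + mass row sums)."""
        mesh = mc.build_slab_mesh((2 * MM, MM, MM), MM)
        space = FESpace(mesh, 1)
        M0 = assemble_mass(space, [0])
        M1 = assemble_mass(space, [1])
        ones = np.ones(space.n_dofs)
        s = ici_ionic_vector([M0, M1], [ones, ones])
        assert np.isclose(s.sum(), 2 * MM ** 3, rtol=1e-12)
        with pytest.raises(ValueError):
            ici_ionic_vector([M0], [ones, ones])


class TestPartitionInvisibility:
    def test_multi_subdomain_identical_properties_bit_identical(self):
        from monocard.bench import benchmark_problem

        kw = dict(dx=0.5 * MM, dt=5e-5, T=2e-3)
        sim1 = mc.MonodomainSimulator(benchmark_problem(**kw))
        sim3 = mc.MonodomainSimulator(
            benchmark_problem(**kw, subdomain_splits=3))
        for _ in range(int(round(kw["T"] / kw["dt"]))):
            sim1.step()
            sim3.step()
            assert np.array_equal(sim1.u_hist[0], sim3.u_hist[0])

    def test_non_conductive_region_blocks_conduction(self):
        """A scar across the middle of a bar stops the wavefront: DOFs
        beyond the scar never activate, scar-interior DOFs leave the solve."""
        mesh = mc.build_slab_mesh((6 * MM, MM, MM), 0.5 * MM)
        xc = mesh.nodes[mesh.elements].mean(axis=1)[:, 0]
        mat = np.where(xc < 2.5 * MM, 0, np.where(xc < 3.5 * MM, 1, 2))
        mesh = mc.Mesh(mesh.nodes, mesh.elements, "hexahedron", mat)
        frame = mc.axis_aligned_frame(mesh.n_nodes, f_axis=(1, 0, 0),
                                      s_axis=(0, 1, 0))
        specs = [
            mc.SubdomainSpec("left", frozenset({0}), 9.5e-5, 9.5e-5, 9.5e-5,
                             "BuenoOrovio"),
            mc.SubdomainSpec("scar", frozenset({1}), conductive=False),
            mc.SubdomainSpec("right", frozenset({2}), 9.5e-5, 9.5e-5, 9.5e-5,
                             "BuenoOrovio"),
        ]
        stim = mc.Stimulus("plane", {"normal": (1, 0, 0), "offset": 0.0,
                                     "thickness": MM},
                           amplitude=300.0, duration=0.002)
        prob = mc.MonodomainProblem(
            mesh=mesh, subdomains=specs, frame=frame,
            protocol=mc.StimulusProtocol([stim]), bdf_order=2, dt=5e-5,
            T=0.02, linear_solver=LinearSolverSettings(method="direct"))
        res = mc.run_simulation(prob)
        act = res.activation.full()
        x = mesh.nodes[:, 0]
        assert np.isfinite(act[x < 2.0 * MM]).all()     # proximal side fires
        assert np.isnan(act[x > 4.0 * MM]).all()        # distal side blocked
        assert np.isnan(act[(x > 2.6 * MM) & (x < 3.4 * MM)]).all()


class TestCheckpoint:
    def _problem(self):
        return _uniform_problem("BuenoOrovio", 300.0, T=0.01, dt=1e-4,
                                sigma=1e-5)

    def test_round_trip_state_identical(self, tmp_path):
        sim = mc.MonodomainSimulator(self._problem())
        for _ in range(20):
            sim.step()
        path = tmp_path / "state.npz"
        sim.checkpoint(path)
        sim2 = mc.restore(self._problem(), path)
        assert sim2.n == sim.n
        for a, b in zip(sim.u_hist, sim2.u_hist):
            assert np.array_equal(a, b)
        for wa, wb in zip(sim.w_hist[0], sim2.w_hist[0]):
            assert np.array_equal(wa, wb)

    def test_resumed_run_matches_uninterrupted_bitwise(self, tmp_path):
        simA = mc.MonodomainSimulator(self._problem())
        for _ in range(100):
            simA.step()
        simB = mc.MonodomainSimulator(self._problem())
        for _ in range(50):
            simB.step()
        path = tmp_path / "mid.npz"
        simB.checkpoint(path)
        simC = mc.restore(self._problem(), path)
        for _ in range(50):
            simC.step()
        assert np.array_equal(simA.u_hist[0], simC.u_hist[0])
        assert np.array_equal(simA.w_hist[0][0], simC.w_hist[0][0])

    def test_restore_onto_different_mesh_rejected(self, tmp_path):
        sim = mc.MonodomainSimulator(self._problem())
        sim.step()
        path = tmp_path / "state.npz"
        sim.checkpoint(path)
        other = _uniform_problem("BuenoOrovio", 300.0, T=0.01, dt=1e-4,
                                 sigma=1e-5)
        other.mesh = mc.build_slab_mesh((2 * MM, MM, MM), MM)
        other.frame = mc.axis_aligned_frame(other.mesh.n_nodes)
        with pytest.raises(ValueError, match="mesh"):
            mc.restore(other, path)


def test_benchmark_activation_insensitive_to_cg_tolerance():
    """Tightening the CG relative residual from 1e-8 to 1e-12 moves the
    latest coarse-benchmark activation time by < 0.01 ms: the error budget
    is discretization-dominated, not solver-dominated."""
    from monocard.bench import run_niederer_benchmark

    latest = []
    for tol in (1e-8, 1e-12):
        res = run_niederer_benchmark(
            0.5 * MM, 0.05 * MM, T=0.07,
            solver=LinearSolverSettings(method="cg", tolerance=tol))
        latest.append(res.latest_ms)
    assert abs(latest[0] - latest[1]) < 0.01


def test_cg_and_direct_solvers_agree():
    prob_cg = _uniform_problem("BuenoOrovio", 300.0, T=5e-3, sigma=1e-5)
    prob_cg.linear_solver = LinearSolverSettings(method="cg", tolerance=1e-12)
    prob_dir = _uniform_problem("BuenoOrovio", 300.0, T=5e-3, sigma=1e-5)
    u_cg = mc.run_simulation(prob_cg).u_final
    u_dir = mc.run_simulation(prob_dir).u_final
    assert np.abs(u_cg - u_dir).max() < 1e-9
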