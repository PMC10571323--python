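"""Ionic model library: published right-hand sides, the IMEX gate update,
single-cell pacing and potential rescaling."""

import numpy as np
import pytest

from monocard.fem import bdf_scheme
from monocard.ionic import CRN, TTP06, AlievPanfilov, BuenoOrovio
from monocard.ionic.base import (MembraneScaling, create_model, evaluate_rhs,
                                 ionic_step, normalize_formulation,
                                 rescale_potential, single_cell_run)

ALL_MODELS = [AlievPanfilov, BuenoOrovio, TTP06, CRN]
MODEL_IDS = [m.name for m in ALL_MODELS]


# ---------------------------------------------------------------------------
# right-hand sides at rest
# ---------------------------------------------------------------------------

def test_aliev_panfilov_rest_is_exact_equilibrium():
    m = AlievPanfilov()
    i_ion, H = evaluate_rhs(m, 0.0, np.zeros(1))
    assert i_ion == 0.0
    assert np.all(H == 0.0)


def test_bueno_orovio_all_three_currents_vanish_at_rest():
    m = BuenoOrovio()
    u0, w0 = m.initial_state()
    i_ion, _ = evaluate_rhs(m, u0, w0)
    assert i_ion == 0.0
    # below the excitation thresholds every current is switched off,
    # independently of the gate values
    i_ion2, _ = evaluate_rhs(m, 0.0, np.array([0.3, 0.2, 0.9]))
    assert i_ion2 == 0.0


def test_ttp06_near_equilibrium_at_published_initial_state():
    m = TTP06()
    u0, w0 = m.initial_state()
    i_ion, _ = evaluate_rhs(m, u0, w0)
    assert abs(i_ion) < 1e-2  # |du/dt| < 1e-2 V/s at the published state


def test_crn_near_equilibrium_at_published_initial_state():
    m = CRN()
    u0, w0 = m.initial_state()
    i_ion, _ = evaluate_rhs(m, u0, w0)
    assert abs(i_ion) < 1e-2


def test_unknown_parameter_override_rejected_with_valid_names():
    with pytest.raises(KeyError, match="G_Na"):
        create_model("TTP06", overrides={"not_a_parameter": 1.0})


def test_override_and_restore_bit_reproduces_trajectory():
    base = BuenoOrovio()
    changed = BuenoOrovio(overrides={"tau_fi": 0.2})
    restored = BuenoOrovio(overrides={"tau_fi": 0.2})
    restored.set_parameter("tau_fi", base.params["tau_fi"])
    _, tr0 = single_cell_run(base, 0.05, 1, 1e-4, amplitude=300.0,
                             duration=0.002, record=True)
    _, tr1 = single_cell_run(changed, 0.05, 1, 1e-4, amplitude=300.0,
                             duration=0.002, record=True)
    _, tr2 = single_cell_run(restored, 0.05, 1, 1e-4, amplitude=300.0,
                             duration=0.002, record=True)
    assert np.array_equal(tr0["u"], tr2["u"])
    assert np.array_equal(tr0["w"], tr2["w"])
    assert not np.array_equal(tr0["u"], tr1["u"])


# ---------------------------------------------------------------------------
# the IMEX-BDF ionic step
# ---------------------------------------------------------------------------

from monocard.ionic.base import IonicModel


class _SingleGate(IonicModel):
    """Scalar test gate dw/dt = (w_inf - w)/tau."""

    name = "gate"
    var_names = ("g",)
    gate_mask = np.array([True])
    w_inf, tau = 0.8, 3.0

    def gating(self, u, w):
        shape = np.shape(u)
        return (np.full((1,) + shape, self.w_inf),
                np.full((1,) + shape, self.tau))

    def rhs(self, u, w):
        return np.zeros_like(u), (self.w_inf - w) / self.tau


def test_bdf1_gate_update_matches_closed_form():
    m = _SingleGate()
    w0 = np.array([[0.2]])
    dt = 0.5
    w1 = ionic_step(m, bdf_scheme(1), np.zeros(1), [w0], dt)
    expected = (0.2 + dt * m.w_inf / m.tau) / (1.0 + dt / m.tau)
    assert np.isclose(w1[0, 0], expected, rtol=1e-14)


def test_implicit_gate_is_unconditionally_stable():
    m = _SingleGate()
    for dt in (1.0, 10.0, 1e3, 1e6):
        w = np.array([[0.0]])
        for _ in range(50):
            w = ionic_step(m, bdf_scheme(1), np.zeros(1), [w], dt)
        assert np.isfinite(w).all() and 0.0 <= w[0, 0] <= 1.0


def test_dt_to_zero_limit_recovers_previous_state():
    for M in ALL_MODELS:
        m = M()
        u0, w0 = m.initial_state()
        w_hist = [w0.reshape(-1, 1) * 1.0]
        w1 = ionic_step(m, bdf_scheme(1), np.atleast_1d(u0), w_hist, 1e-14)
        assert np.abs(w1 - w_hist[0]).max() < 1e-10


def test_explicit_variable_bdf1_is_forward_euler():
    m = AlievPanfilov()
    u = np.array([0.4])
    w = np.array([[0.1]])
    dt = 0.05
    w1 = ionic_step(m, bdf_scheme(1), u, [w], dt)
    _, H = m.rhs(u, w)
    assert np.allclose(w1, w + dt * H, rtol=1e-14)


def test_ionic_step_rejects_bad_input():
    m = _SingleGate()
    with pytest.raises(ValueError):
        ionic_step(m, bdf_scheme(1), np.zeros(1), [np.zeros((1, 1))], -1.0)
    with pytest.raises(ValueError, match="history"):
        ionic_step(m, bdf_scheme(2), np.zeros(1), [np.zeros((1, 1))], 0.1)


# ---------------------------------------------------------------------------
# 0D runs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("Model", ALL_MODELS, ids=MODEL_IDS)
def test_quiescent_model_stays_at_rest(Model):
    """BDF1, dt = 1e-5 s, 1 s unpaced: the potential stays within 1 mV
    (physiological) / 0.01 (dimensionless) of its resting value."""
    m = Model()
    u0, _ = m.initial_state()
    state, _ = single_cell_run(m, period=1.0, n_cycles=1, dt=1e-5)
    drift = abs(float(state.u) - u0)
    assert drift < (1.0 if m.voltage_mv else 0.01)
    assert state.check_finite()


def test_zero_stimulus_exact_equilibrium_preserved():
    m = AlievPanfilov()
    state, _ = single_cell_run(m, period=0.02, n_cycles=1, dt=1e-4)
    assert abs(float(state.u)) < 1e-8
    assert np.abs(state.w).max() < 1e-8


def test_aliev_panfilov_paced_stays_in_unit_range():
    """u spans its nominal dimensionless range 0..1 (small transient
    overshoot above 1 is stimulus forcing, not model dynamics)."""
    m = AlievPanfilov()
    _, tr = single_cell_run(m, period=0.25, n_cycles=2, dt=5e-5,
                            amplitude=120.0, duration=0.002, record=True)
    assert tr["u"].min() >= -0.05 and tr["u"].max() <= 1.1
    assert tr["u"].max() > 0.9  # it actually fired


def test_paced_cell_converges_toward_a_limit_cycle():
    m = BuenoOrovio()
    period, dt = 0.4, 1e-4
    _, tr = single_cell_run(m, period=period, n_cycles=4, dt=dt,
                            amplitude=300.0, duration=0.002, record=True)
    n = int(round(period / dt))
    # state sampled at the end of each cycle
    samples = [np.concatenate(([tr["u"][k * n]], tr["w"][:, k * n]))
               for k in range(1, 5)]
    d_early = np.linalg.norm(samples[1] - samples[0])
    d_late = np.linalg.norm(samples[3] - samples[2])
    assert d_late < d_early


def test_divergence_aborts_with_cycle_index():
    m = AlievPanfilov()
    with pytest.raises(FloatingPointError, match="cycle 0"):
        # absurd amplitude explodes the explicit recovery update
        single_cell_run(m, period=0.05, n_cycles=1, dt=1e-3,
                        amplitude=1e12, duration=0.04)


def test_single_cell_csv_trace(tmp_path):
    m = AlievPanfilov()
    path = tmp_path / "trace.csv"
    single_cell_run(m, period=0.01, n_cycles=1, dt=1e-3, record=True,
                    csv_path=path)
    lines = path.read_text().splitlines()
    assert lines[0] == "time,u,w"
    assert len(lines) == 12  # header + initial + 10 steps


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model_name, u, expected", [
    ("AlievPanfilov", 0.0, -80.0),
    ("AlievPanfilov", 1.0, 20.0),
    ("BuenoOrovio", 0.0, -84.0),
    ("TTP06", -85.23, -85.23),
    ("CRN", -81.18, -81.18),
])
def test_rescale_potential_to_millivolts(model_name, u, expected):
    m = create_model(model_name)
    assert np.isclose(rescale_potential(m, u), expected)


def test_normalize_formulation():
    s = MembraneScaling(C_m=1.0, chi_m=1.0)
    i, a, d = normalize_formulation(2.0, 3.0, 4.0, s)
    assert (i, a, d) == (2.0, 3.0, 4.0)
    s2 = MembraneScaling(C_m=2.0, chi_m=7.0)
    i, a, d = normalize_formulation(2.0, 35.714 * 2.0, 4.0, s2)
    assert np.isclose(a, 35.714)   # benchmark convention amplitude
    assert np.isclose(i, 1.0)
    assert np.isclose(d, 4.0 / 14.0)
    # linearity in D-hat
    _, _, d2 = normalize_formulation(2.0, 3.0, 8.0, s2)
    assert np.isclose(d2, 2.0 * d)
    with pytest.raises(ValueError):
        MembraneScaling(C_m=0.0, chi_m=1.0)


def test_cell_types_change_published_conductances():
    epi, endo, mid = (TTP06(cell_type=c) for c in
                      ("Epicardium", "Endocardium", "Myocardium"))
    assert epi.params["G_to"] > endo.params["G_to"]
    assert mid.params["G_Ks"] < epi.params["G_Ks"]
    with pytest.raises(ValueError, match="cell type"):
        TTP06(cell_type="Pericardium")
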