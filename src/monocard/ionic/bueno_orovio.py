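"""Bueno–Orovio–Cherry–Fenton minimal ventricular model (4 variables).

A dimensionless potential u and three gates (v, w, s) reproduce human
ventricular action-potential morphology with three currents: fast inward
J_fi (sodium-like), slow outward J_so (potassium-like) and slow inward J_si
(calcium-like).  Time is in ms; u maps to millivolts via
u_mV = 85.7 u − 84.  The epicardial parameter set is the default; the
endocardial and mid-myocardial published sets are selectable as cell types.

All three gates have dynamics affine in the gate at frozen u, so the whole
w-vector is advanced implicitly.
"""

from __future__ import annotations

import numpy as np

from .base import IonicModel

__all__ = ["BuenoOrovio"]

_EPI = {
    "u_o": 0.0, "u_u": 1.55, "theta_v": 0.3, "theta_w": 0.13,
    "theta_vminus": 0.006, "theta_o": 0.006,
    "tau_v1minus": 60.0, "tau_v2minus": 1150.0, "tau_vplus": 1.4506,
    "tau_w1minus": 60.0, "tau_w2minus": 15.0, "k_wminus": 65.0,
    "u_wminus": 0.03, "tau_wplus": 200.0,
    "tau_fi": 0.11, "tau_o1": 400.0, "tau_o2": 6.0,
    "tau_so1": 30.0181, "tau_so2": 0.9957, "k_so": 2.0458, "u_so": 0.65,
    "tau_s1": 2.7342, "tau_s2": 16.0, "k_s": 2.0994, "u_s": 0.9087,
    "tau_si": 1.8875, "tau_winf": 0.07, "w_infstar": 0.94,
}

_ENDO = dict(_EPI, **{
    "u_o": 0.0, "u_u": 1.56, "theta_v": 0.3, "theta_w": 0.13,
    "theta_vminus": 0.2, "theta_o": 0.006,
    "tau_v1minus": 75.0, "tau_v2minus": 10.0, "tau_vplus": 1.4506,
    "tau_w1minus": 6.0, "tau_w2minus": 140.0, "k_wminus": 200.0,
    "u_wminus": 0.016, "tau_wplus": 280.0,
    "tau_fi": 0.1, "tau_o1": 470.0, "tau_o2": 6.0,
    "tau_so1": 40.0, "tau_so2": 1.2, "k_so": 2.0, "u_so": 0.65,
    "tau_s1": 2.7342, "tau_s2": 2.0, "k_s": 2.0994, "u_s": 0.9087,
    "tau_si": 2.9013, "tau_winf": 0.0273, "w_infstar": 0.78,
})

_MID = dict(_EPI, **{
    "u_o": 0.0, "u_u": 1.61, "theta_v": 0.3, "theta_w": 0.13,
    "theta_vminus": 0.1, "theta_o": 0.005,
    "tau_v1minus": 80.0, "tau_v2minus": 1.4506, "tau_vplus": 1.4506,
    "tau_w1minus": 70.0, "tau_w2minus": 8.0, "k_wminus": 200.0,
    "u_wminus": 0.016, "tau_wplus": 280.0,
    "tau_fi": 0.078, "tau_o1": 410.0, "tau_o2": 7.0,
    "tau_so1": 91.0, "tau_so2": 0.8, "k_so": 2.1, "u_so": 0.6,
    "tau_s1": 2.7342, "tau_s2": 4.0, "k_s": 2.0994, "u_s": 0.9087,
    "tau_si": 3.3849, "tau_winf": 0.01, "w_infstar": 0.5,
})

_SETS = {"Epicardium": _EPI, "Endocardium": _ENDO, "Myocardium": _MID}


def _H(x):
    """Heaviside step (1 for x >= 0) — the model's switching function."""
    return (np.asarray(x) >= 0.0).astype(np.float64)


class BuenoOrovio(IonicModel):
    name = "BuenoOrovio"
    var_names = ("v", "w", "s")
    gate_mask = np.array([True, True, True])
    voltage_mv = False
    time_unit_ms = 1.0
    rescale = (85.7, -84.0)
    CELL_TYPES = ("Epicardium", "Endocardium", "Myocardium")

    def __init__(self, cell_type=None, overrides=None):
        self.DEFAULTS = _SETS[cell_type or "Epicardium"]
        super().__init__(cell_type, overrides)

    def initial_state(self):
        return 0.0, np.array([1.0, 1.0, 0.0])

    def _infs_taus(self, u):
        p = self.params
        Hv = _H(u - p["theta_v"])
        Hw = _H(u - p["theta_w"])
        Hvm = _H(u - p["theta_vminus"])
        Ho = _H(u - p["theta_o"])

        tau_vminus = (1.0 - Hvm) * p["tau_v1minus"] + Hvm * p["tau_v2minus"]
        tau_wminus = p["tau_w1minus"] + (p["tau_w2minus"] - p["tau_w1minus"]) \
            * 0.5 * (1.0 + np.tanh(p["k_wminus"] * (u - p["u_wminus"])))
        tau_so = p["tau_so1"] + (p["tau_so2"] - p["tau_so1"]) \
            * 0.5 * (1.0 + np.tanh(p["k_so"] * (u - p["u_so"])))
        tau_s = (1.0 - Hw) * p["tau_s1"] + Hw * p["tau_s2"]
        tau_o = (1.0 - Ho) * p["tau_o1"] + Ho * p["tau_o2"]

        v_inf_lo = (u < p["theta_vminus"]).astype(np.float64)
        w_inf_lo = (1.0 - Ho) * (1.0 - u / p["tau_winf"]) + Ho * p["w_infstar"]

        # affine gate form: dv/dt = (v_eq - v)/tau_v
        v_eq = (1.0 - Hv) * v_inf_lo
        tau_v = (1.0 - Hv) * tau_vminus + Hv * p["tau_vplus"]
        w_eq = (1.0 - Hw) * w_inf_lo
        tau_w = (1.0 - Hw) * tau_wminus + Hw * p["tau_wplus"]
        s_eq = 0.5 * (1.0 + np.tanh(p["k_s"] * (u - p["u_s"])))
        tau_s_full = tau_s
        return (v_eq, tau_v, w_eq, tau_w, s_eq, tau_s_full,
                Hv, Hw, tau_so, tau_o)

    def gating(self, u, w):
        v_eq, tau_v, w_eq, tau_w, s_eq, tau_s, *_ = self._infs_taus(u)
        w_eq_all = np.stack([v_eq, w_eq, s_eq])
        tau_all = np.stack([np.broadcast_to(tau_v, u.shape),
                            np.broadcast_to(tau_w, u.shape),
                            np.broadcast_to(tau_s, u.shape)])
        return w_eq_all, tau_all

    def rhs(self, u, w):
        p = self.params
        v, wg, s = w[0], w[1], w[2]
        (v_eq, tau_v, w_eq, tau_w, s_eq, tau_s,
         Hv, Hw, tau_so, tau_o) = self._infs_taus(u)

        J_fi = -v * Hv * (u - p["theta_v"]) * (p["u_u"] - u) / p["tau_fi"]
        J_so = (u - p["u_o"]) * (1.0 - Hw) / tau_o + Hw / tau_so
        J_si = -Hw * wg * s / p["tau_si"]
        i_ion = J_fi + J_so + J_si

        H = np.stack([
            (v_eq - v) / tau_v,
            (w_eq - wg) / tau_w,
            (s_eq - s) / tau_s,
        ])
        return i_ion, H
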