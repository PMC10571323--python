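"""ten Tusscher–Panfilov 2006 human ventricular model (18 variables + V).

Biophysically detailed model with 12 Hodgkin–Huxley gates, dyadic-subspace
calcium dynamics (CaSS, CaSR, the release gate R̄) and intracellular Na⁺/K⁺
handling.  Potential in mV, time in ms, currents in pA/pF (≡ mV/ms), ionic
concentrations in mM.  Cell types Epicardium (default), Endocardium and
Myocardium (M cells) differ in G_to, G_Ks and the s-gate kinetics.

The 12 voltage gates plus R̄ (whose rate is affine in R̄ at frozen calcium)
are advanced implicitly; the five concentrations explicitly.
"""

from __future__ import annotations

import numpy as np

from .base import IonicModel

__all__ = ["TTP06"]

_BASE = {
    # physical constants and cell geometry
    "R": 8314.472, "T": 310.0, "F": 96485.3415,
    "Cm": 0.185, "V_C": 0.016404, "V_SR": 0.001094, "V_SS": 0.00005468,
    # external concentrations (mM)
    "K_o": 5.4, "Na_o": 140.0, "Ca_o": 2.0,
    # maximal conductances / fluxes
    "G_Na": 14.838, "G_K1": 5.405, "G_Kr": 0.153, "G_Ks": 0.392,
    "G_to": 0.294, "G_CaL": 3.98e-5, "G_pK": 0.0146, "G_pCa": 0.1238,
    "G_bNa": 0.00029, "G_bCa": 0.000592,
    "P_NaK": 2.724, "K_mK": 1.0, "K_mNa": 40.0,
    "k_NaCa": 1000.0, "gamma": 0.35, "K_mCa": 1.38, "K_mNai": 87.5,
    "K_sat": 0.1, "alpha_naca": 2.5,
    "p_KNa": 0.03, "K_pCa": 0.0005,
    # SR calcium handling
    "V_maxup": 0.006375, "K_up": 0.00025, "V_rel": 0.102,
    "k1_prime": 0.15, "k2_prime": 0.045, "k3": 0.060, "k4": 0.005,
    "EC": 1.5, "max_sr": 2.5, "min_sr": 1.0,
    "V_leak": 0.00036, "V_xfer": 0.0038,
    # buffers
    "Buf_c": 0.2, "K_bufc": 0.001, "Buf_sr": 10.0, "K_bufsr": 0.3,
    "Buf_ss": 0.4, "K_bufss": 0.00025,
}

# (G_to, G_Ks) per cell type; the s gate kinetics of the endocardial cell
# differ as well (handled in _gates).
_CELL = {
    "Epicardium": {"G_to": 0.294, "G_Ks": 0.392},
    "Endocardium": {"G_to": 0.073, "G_Ks": 0.392},
    "Myocardium": {"G_to": 0.294, "G_Ks": 0.098},
}

# published resting initial conditions
_V0 = -85.23
_W0 = {
    "xr1": 0.00621, "xr2": 0.4712, "xs": 0.0095,
    "m": 0.00172, "h": 0.7444, "j": 0.7045,
    "d": 3.373e-5, "f": 0.7888, "f2": 0.9755, "fcass": 0.9953,
    "s": 0.999998, "r": 2.42e-8,
    "ca_i": 0.000126, "ca_sr": 3.64, "ca_ss": 0.00036, "r_bar": 0.9073,
    "na_i": 8.604, "k_i": 136.89,
}


def _safe_exp(x):
    return np.exp(np.clip(x, -500.0, 500.0))


class TTP06(IonicModel):
    name = "TTP06"
    var_names = ("xr1", "xr2", "xs", "m", "h", "j", "d", "f", "f2", "fcass",
                 "s", "r", "ca_i", "ca_sr", "ca_ss", "r_bar", "na_i", "k_i")
    #               12 gates ----------------------------------^  + r_bar implicit
    gate_mask = np.array([True] * 12 + [False, False, False, True, False, False])
    voltage_mv = True
    time_unit_ms = 1.0
    rescale = None
    CELL_TYPES = ("Epicardium", "Endocardium", "Myocardium")

    def __init__(self, cell_type=None, overrides=None):
        self.DEFAULTS = dict(_BASE)
        ct = cell_type or "Epicardium"
        if ct in _CELL:
            self.DEFAULTS.update(_CELL[ct])
        super().__init__(cell_type, overrides)

    def initial_state(self):
        return _V0, np.array([_W0[k] for k in self.var_names])

    # -- gate kinetics ------------------------------------------------------

    def _gates(self, V, ca_ss):
        """(x_inf, tau_x) for the 12 voltage gates, in var_names order."""
        e = _safe_exp

        xr1_inf = 1.0 / (1.0 + e((-26.0 - V) / 7.0))
        a = 450.0 / (1.0 + e((-45.0 - V) / 10.0))
        b = 6.0 / (1.0 + e((V + 30.0) / 11.5))
        tau_xr1 = a * b

        xr2_inf = 1.0 / (1.0 + e((V + 88.0) / 24.0))
        a = 3.0 / (1.0 + e((-60.0 - V) / 20.0))
        b = 1.12 / (1.0 + e((V - 60.0) / 20.0))
        tau_xr2 = a * b

        xs_inf = 1.0 / (1.0 + e((-5.0 - V) / 14.0))
        a = 1400.0 / np.sqrt(1.0 + e((5.0 - V) / 6.0))
        b = 1.0 / (1.0 + e((V - 35.0) / 15.0))
        tau_xs = a * b + 80.0

        m_inf = 1.0 / (1.0 + e((-56.86 - V) / 9.03)) ** 2
        a = 1.0 / (1.0 + e((-60.0 - V) / 5.0))
        b = 0.1 / (1.0 + e((V + 35.0) / 5.0)) \
            + 0.1 / (1.0 + e((V - 50.0) / 200.0))
        tau_m = a * b

        h_inf = 1.0 / (1.0 + e((V + 71.55) / 7.43)) ** 2
        lo = V < -40.0
        a_h = np.where(lo, 0.057 * e(-(V + 80.0) / 6.8), 0.0)
        b_h = np.where(lo,
                       2.7 * e(0.079 * V) + 3.1e5 * e(0.3485 * V),
                       0.77 / (0.13 * (1.0 + e(-(V + 10.66) / 11.1))))
        tau_h = 1.0 / (a_h + b_h)

        j_inf = h_inf
        num = (-2.5428e4 * e(0.2444 * V) - 6.948e-6 * e(-0.04391 * V)) \
            * (V + 37.78)
        a_j = np.where(lo, num / (1.0 + e(0.311 * (V + 79.23))), 0.0)
        b_j = np.where(lo,
                       0.02424 * e(-0.01052 * V)
                       / (1.0 + e(-0.1378 * (V + 40.14))),
                       0.6 * e(0.057 * V) / (1.0 + e(-0.1 * (V + 32.0))))
        tau_j = 1.0 / (a_j + b_j)

        d_inf = 1.0 / (1.0 + e((-8.0 - V) / 7.5))
        a = 1.4 / (1.0 + e((-35.0 - V) / 13.0)) + 0.25
        b = 1.4 / (1.0 + e((V + 5.0) / 5.0))
        g = 1.0 / (1.0 + e((50.0 - V) / 20.0))
        tau_d = a * b + g

        f_inf = 1.0 / (1.0 + e((V + 20.0) / 7.0))
        tau_f = 1102.5 * e(-((V + 27.0) ** 2) / 225.0) \
            + 200.0 / (1.0 + e((13.0 - V) / 10.0)) \
            + 180.0 / (1.0 + e((V + 30.0) / 10.0)) + 20.0

        f2_inf = 0.67 / (1.0 + e((V + 35.0) / 7.0)) + 0.33
        tau_f2 = 562.0 * e(-((V + 27.0) ** 2) / 240.0) \
            + 31.0 / (1.0 + e((25.0 - V) / 10.0)) \
            + 80.0 / (1.0 + e((V + 30.0) / 10.0))

        ratio = (ca_ss / 0.05) ** 2
        fcass_inf = 0.6 / (1.0 + ratio) + 0.4
        tau_fcass = 80.0 / (1.0 + ratio) + 2.0

        if self.cell_type == "Endocardium":
            s_inf = 1.0 / (1.0 + e((V + 28.0) / 5.0))
            tau_s = 1000.0 * e(-((V + 67.0) ** 2) / 1000.0) + 8.0
        else:
            s_inf = 1.0 / (1.0 + e((V + 20.0) / 5.0))
            tau_s = 85.0 * e(-((V + 45.0) ** 2) / 320.0) \
                + 5.0 / (1.0 + e((V - 20.0) / 5.0)) + 3.0

        r_inf = 1.0 / (1.0 + e((20.0 - V) / 6.0))
        tau_r = 9.5 * e(-((V + 40.0) ** 2) / 1800.0) + 0.8

        infs = np.stack([xr1_inf, xr2_inf, xs_inf, m_inf, h_inf, j_inf,
                         d_inf, f_inf, f2_inf, fcass_inf, s_inf, r_inf])
        taus = np.stack([tau_xr1, tau_xr2, tau_xs, tau_m, tau_h, tau_j,
                         tau_d, tau_f, tau_f2, tau_fcass, tau_s, tau_r])
        return infs, taus

    def gating(self, u, w):
        p = self.params
        ca_ss, ca_sr = w[14], w[13]
        infs, taus = self._gates(u, ca_ss)
        # R-bar: dR/dt = -k2 CaSS R + k4 (1 - R), affine in R
        kcasr = p["max_sr"] - (p["max_sr"] - p["min_sr"]) \
            / (1.0 + (p["EC"] / ca_sr) ** 2)
        k2 = p["k2_prime"] * kcasr
        rate = k2 * ca_ss + p["k4"]
        r_eq = p["k4"] / rate
        r_tau = 1.0 / rate
        w_eq = np.concatenate([infs, r_eq[None, :]])
        tau = np.concatenate([taus, r_tau[None, :]])
        return w_eq, tau

    # -- currents and full right-hand side ----------------------------------

    def _membrane(self, u, w):
        """Membrane currents and concentration dynamics (no gate kinetics).

        Returns (I_ion, concentration rates (ca_i, ca_sr, ca_ss, na_i, k_i),
        dR̄/dt)."""
        p = self.params
        e = _safe_exp
        V = u
        (xr1, xr2, xs, m, h, j, d, f, f2, fcass, s, r,
         ca_i, ca_sr, ca_ss, r_bar, na_i, k_i) = w

        RTF = p["R"] * p["T"] / p["F"]
        E_Na = RTF * np.log(p["Na_o"] / na_i)
        E_K = RTF * np.log(p["K_o"] / k_i)
        E_Ks = RTF * np.log((p["K_o"] + p["p_KNa"] * p["Na_o"])
                            / (k_i + p["p_KNa"] * na_i))
        E_Ca = 0.5 * RTF * np.log(p["Ca_o"] / ca_i)

        I_Na = p["G_Na"] * m ** 3 * h * j * (V - E_Na)

        a = 0.1 / (1.0 + e(0.06 * (V - E_K - 200.0)))
        b = (3.0 * e(0.0002 * (V - E_K + 100.0)) + e(0.1 * (V - E_K - 10.0))) \
            / (1.0 + e(-0.5 * (V - E_K)))
        I_K1 = p["G_K1"] * (a / (a + b)) * np.sqrt(p["K_o"] / 5.4) * (V - E_K)

        I_Kr = p["G_Kr"] * np.sqrt(p["K_o"] / 5.4) * xr1 * xr2 * (V - E_K)
        I_Ks = p["G_Ks"] * xs ** 2 * (V - E_Ks)
        I_to = p["G_to"] * r * s * (V - E_K)

        z = 2.0 * (V - 15.0) * p["F"] / (p["R"] * p["T"])
        ez = e(z)
        small = np.abs(z) < 1e-6
        # (V-15)/(e^z - 1) -> RT/(2F) as z -> 0 (removable singularity)
        frac = np.where(small, 0.5 * RTF * (1.0 - 0.5 * z),
                        (V - 15.0) / np.where(small, 1.0, ez - 1.0))
        I_CaL = p["G_CaL"] * d * f * f2 * fcass * 4.0 * p["F"] \
            / RTF * frac * (0.25 * ca_ss * ez - p["Ca_o"])

        g = p["gamma"]
        egv = e(g * V / RTF)
        eg1v = e((g - 1.0) * V / RTF)
        I_NaCa = p["k_NaCa"] * (
            egv * na_i ** 3 * p["Ca_o"]
            - eg1v * p["Na_o"] ** 3 * ca_i * p["alpha_naca"]
        ) / ((p["K_mNai"] ** 3 + p["Na_o"] ** 3) * (p["K_mCa"] + p["Ca_o"])
             * (1.0 + p["K_sat"] * eg1v))

        I_NaK = p["P_NaK"] * p["K_o"] * na_i / (
            (p["K_o"] + p["K_mK"]) * (na_i + p["K_mNa"])
            * (1.0 + 0.1245 * e(-0.1 * V / RTF) + 0.0353 * e(-V / RTF))
        )

        I_pCa = p["G_pCa"] * ca_i / (ca_i + p["K_pCa"])
        I_pK = p["G_pK"] * (V - E_K) / (1.0 + e((25.0 - V) / 5.98))
        I_bNa = p["G_bNa"] * (V - E_Na)
        I_bCa = p["G_bCa"] * (V - E_Ca)

        i_ion = (I_Na + I_K1 + I_to + I_Kr + I_Ks + I_CaL + I_NaCa + I_NaK
                 + I_pCa + I_pK + I_bNa + I_bCa)

        # calcium subsystem
        kcasr = p["max_sr"] - (p["max_sr"] - p["min_sr"]) \
            / (1.0 + (p["EC"] / ca_sr) ** 2)
        k1 = p["k1_prime"] / kcasr
        k2 = p["k2_prime"] * kcasr
        d_rbar = -k2 * ca_ss * r_bar + p["k4"] * (1.0 - r_bar)
        O = k1 * ca_ss ** 2 * r_bar / (p["k3"] + k1 * ca_ss ** 2)
        I_rel = p["V_rel"] * O * (ca_sr - ca_ss)
        I_up = p["V_maxup"] / (1.0 + (p["K_up"] / ca_i) ** 2)
        I_leak = p["V_leak"] * (ca_sr - ca_i)
        I_xfer = p["V_xfer"] * (ca_ss - ca_i)

        CmF = p["Cm"] / p["F"]
        buf_c = 1.0 / (1.0 + p["Buf_c"] * p["K_bufc"]
                       / (ca_i + p["K_bufc"]) ** 2)
        d_cai = buf_c * (
            (I_leak - I_up) * p["V_SR"] / p["V_C"] + I_xfer
            - (I_bCa + I_pCa - 2.0 * I_NaCa) * CmF / (2.0 * p["V_C"])
        )
        buf_sr = 1.0 / (1.0 + p["Buf_sr"] * p["K_bufsr"]
                        / (ca_sr + p["K_bufsr"]) ** 2)
        d_casr = buf_sr * (I_up - I_rel - I_leak)
        buf_ss = 1.0 / (1.0 + p["Buf_ss"] * p["K_bufss"]
                        / (ca_ss + p["K_bufss"]) ** 2)
        d_cass = buf_ss * (
            -I_CaL * CmF / (2.0 * p["V_SS"])
            + I_rel * p["V_SR"] / p["V_SS"]
            - I_xfer * p["V_C"] / p["V_SS"]
        )

        d_nai = -(I_Na + I_bNa + 3.0 * I_NaK + 3.0 * I_NaCa) * CmF / p["V_C"]
        d_ki = -(I_K1 + I_to + I_Kr + I_Ks - 2.0 * I_NaK + I_pK) \
            * CmF / p["V_C"]

        conc = np.stack([d_cai, d_casr, d_cass, d_nai, d_ki])
        return i_ion, conc, d_rbar

    def rhs(self, u, w):
        i_ion, conc, d_rbar = self._membrane(u, w)
        infs, taus = self._gates(u, w[14])
        gate_rates = (infs - w[:12]) / taus
        H = np.concatenate([
            gate_rates,
            conc[:3], d_rbar[None, :], conc[3:],
        ])
        return i_ion, H

    def imex_eval(self, u, w):
        w_eq, tau = self.gating(u, w)
        _, conc, _ = self._membrane(u, w)
        return w_eq, tau, conc

    def i_ion(self, u, w):
        return self._membrane(u, w)[0]
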