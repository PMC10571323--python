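"""Courtemanche–Ramirez–Nattel human atrial model (20 variables + V).

Biophysically detailed atrial cell model: 15 gates (including the
calcium-release gates u, v, w driven by the flux signal Fn), SR calcium
handling (uptake and release compartments) and Na⁺/K⁺/Ca²⁺ concentration
dynamics.  Potential in mV, time in ms, currents in pA (the membrane
capacitance Cm = 100 pF divides the total current in dV/dt so the potential
rate is again mV/ms).

The ultrarapid potassium conductance g_Kur(V) = gKur_fix + gKur_var /
(1 + exp(−(V−15)/13)) exposes its two coefficients as named parameters, so
chronic-AF remodelling can scale them per subdomain.
"""

from __future__ import annotations

import numpy as np

from .base import IonicModel

__all__ = ["CRN"]

_P = {
    "R": 8.3143, "T": 310.0, "F": 96.4867, "Cm": 100.0,
    "V_i": 13668.0, "V_up": 1109.52, "V_rel": 96.48,
    "K_o": 5.4, "Na_o": 140.0, "Ca_o": 1.8,
    "gNa": 7.8, "gK1": 0.09, "gto": 0.1652,
    "gKr": 0.029411765, "gKs": 0.12941176, "gCaL": 0.12375,
    "gbCa": 0.001131, "gbNa": 0.0006744375,
    "gKur_fix": 0.005, "gKur_var": 0.05,
    "INaK_max": 0.59933874, "K_mNai": 10.0, "K_mKo": 1.5,
    "INaCa_max": 1600.0, "gamma": 0.35, "K_mNa": 87.5, "K_mCa": 1.38,
    "k_sat": 0.1, "ipCa_max": 0.275,
    "K_rel": 30.0, "K_up": 0.00092, "Iup_max": 0.005, "Ca_up_max": 15.0,
    "Cmdn_max": 0.05, "Trpn_max": 0.07, "Csqn_max": 10.0,
    "K_mCmdn": 0.00238, "K_mTrpn": 0.0005, "K_mCsqn": 0.8,
    "tau_tr": 180.0, "tau_fCa": 2.0, "tau_u": 8.0,
    "KQ10": 3.0,
}

_V0 = -81.18
_W0 = {
    "m": 2.908e-3, "h": 9.649e-1, "j": 9.775e-1,
    "oa": 3.043e-2, "oi": 9.992e-1, "ua": 4.966e-3, "ui": 9.986e-1,
    "xr": 3.296e-5, "xs": 1.869e-2, "d": 1.367e-4, "f": 9.996e-1,
    "fca": 7.755e-1, "u_rel": 0.0, "v_rel": 1.0, "w_rel": 9.992e-1,
    "na_i": 1.117e1, "k_i": 1.39e2, "ca_i": 1.013e-4,
    "ca_up": 1.488, "ca_rel": 1.488,
}


def _safe_exp(x):
    return np.exp(np.clip(x, -500.0, 500.0))


def _ratio(num, den, limit):
    """num/den with the removable singularity at den→0 replaced by limit."""
    small = np.abs(den) < 1e-10
    return np.where(small, limit, num / np.where(small, 1.0, den))


class CRN(IonicModel):
    name = "CRN"
    var_names = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f",
                 "fca", "u_rel", "v_rel", "w_rel",
                 "na_i", "k_i", "ca_i", "ca_up", "ca_rel")
    gate_mask = np.array([True] * 15 + [False] * 5)
    voltage_mv = True
    time_unit_ms = 1.0
    rescale = None
    DEFAULTS = _P

    def initial_state(self):
        return _V0, np.array([_W0[k] for k in self.var_names])

    # -- helpers -------------------------------------------------------------

    def _currents(self, V, w):
        p = self.params
        e = _safe_exp
        (m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca,
         u_rel, v_rel, w_rel, na_i, k_i, ca_i, ca_up, ca_rel) = w
        RTF = p["R"] * p["T"] / p["F"]
        Cm = p["Cm"]

        E_Na = RTF * np.log(p["Na_o"] / na_i)
        E_K = RTF * np.log(p["K_o"] / k_i)
        E_Ca = 0.5 * RTF * np.log(p["Ca_o"] / ca_i)

        I_Na = Cm * p["gNa"] * m ** 3 * h * j * (V - E_Na)
        I_K1 = Cm * p["gK1"] * (V - E_K) / (1.0 + e(0.07 * (V + 80.0)))
        I_to = Cm * p["gto"] * oa ** 3 * oi * (V - E_K)
        gKur = p["gKur_fix"] + p["gKur_var"] / (1.0 + e(-(V - 15.0) / 13.0))
        I_Kur = Cm * gKur * ua ** 3 * ui * (V - E_K)
        I_Kr = Cm * p["gKr"] * xr * (V - E_K) / (1.0 + e((V + 15.0) / 22.4))
        I_Ks = Cm * p["gKs"] * xs ** 2 * (V - E_K)
        I_CaL = Cm * p["gCaL"] * d * f * fca * (V - 65.0)

        sigma = (e(p["Na_o"] / 67.3) - 1.0) / 7.0
        f_NaK = 1.0 / (1.0 + 0.1245 * e(-0.1 * V / RTF)
                       + 0.0365 * sigma * e(-V / RTF))
        I_NaK = Cm * p["INaK_max"] * f_NaK \
            / (1.0 + (p["K_mNai"] / na_i) ** 1.5) \
            * p["K_o"] / (p["K_o"] + p["K_mKo"])

        g = p["gamma"]
        I_NaCa = Cm * p["INaCa_max"] * (
            e(g * V / RTF) * na_i ** 3 * p["Ca_o"]
            - e((g - 1.0) * V / RTF) * p["Na_o"] ** 3 * ca_i
        ) / ((p["K_mNa"] ** 3 + p["Na_o"] ** 3) * (p["K_mCa"] + p["Ca_o"])
             * (1.0 + p["k_sat"] * e((g - 1.0) * V / RTF)))

        I_bNa = Cm * p["gbNa"] * (V - E_Na)
        I_bCa = Cm * p["gbCa"] * (V - E_Ca)
        I_pCa = Cm * p["ipCa_max"] * ca_i / (0.0005 + ca_i)

        # SR fluxes
        I_rel = p["K_rel"] * u_rel ** 2 * v_rel * w_rel * (ca_rel - ca_i)
        I_tr = (ca_up - ca_rel) / p["tau_tr"]
        I_up = p["Iup_max"] / (1.0 + p["K_up"] / ca_i)
        I_up_leak = p["Iup_max"] * ca_up / p["Ca_up_max"]

        return dict(I_Na=I_Na, I_K1=I_K1, I_to=I_to, I_Kur=I_Kur, I_Kr=I_Kr,
                    I_Ks=I_Ks, I_CaL=I_CaL, I_NaK=I_NaK, I_NaCa=I_NaCa,
                    I_bNa=I_bNa, I_bCa=I_bCa, I_pCa=I_pCa, I_rel=I_rel,
                    I_tr=I_tr, I_up=I_up, I_up_leak=I_up_leak)

    def _gate_kinetics(self, V, w, cur=None):
        """(x_inf, tau_x) for all 15 gates, in var_names order.

        ``cur`` lets callers reuse already-evaluated currents (the release
        gates need I_rel, I_CaL and I_NaCa through the flux signal Fn)."""
        p = self.params
        e = _safe_exp
        KQ10 = p["KQ10"]

        a_m = _ratio(0.32 * (V + 47.13), 1.0 - e(-0.1 * (V + 47.13)), 3.2)
        b_m = 0.08 * e(-V / 11.0)
        tau_m = 1.0 / (a_m + b_m)
        m_inf = a_m * tau_m

        lo = V < -40.0
        a_h = np.where(lo, 0.135 * e(-(V + 80.0) / 6.8), 0.0)
        b_h = np.where(lo, 3.56 * e(0.079 * V) + 3.1e5 * e(0.35 * V),
                       1.0 / (0.13 * (1.0 + e(-(V + 10.66) / 11.1))))
        tau_h = 1.0 / (a_h + b_h)
        h_inf = a_h * tau_h

        a_j = np.where(
            lo,
            (-1.2714e5 * e(0.2444 * V) - 3.474e-5 * e(-0.04391 * V))
            * (V + 37.78) / (1.0 + e(0.311 * (V + 79.23))),
            0.0,
        )
        b_j = np.where(lo,
                       0.1212 * e(-0.01052 * V)
                       / (1.0 + e(-0.1378 * (V + 40.14))),
                       0.3 * e(-2.535e-7 * V) / (1.0 + e(-0.1 * (V + 32.0))))
        tau_j = 1.0 / (a_j + b_j)
        j_inf = a_j * tau_j

        a_oa = 0.65 / (e(-(V + 10.0) / 8.5) + e(-(V - 30.0) / 59.0))
        b_oa = 0.65 / (2.5 + e((V + 82.0) / 17.0))
        tau_oa = 1.0 / ((a_oa + b_oa) * KQ10)
        oa_inf = 1.0 / (1.0 + e(-(V + 20.47) / 17.54))

        a_oi = 1.0 / (18.53 + e((V + 113.7) / 10.95))
        b_oi = 1.0 / (35.56 + e(-(V + 1.26) / 7.44))
        tau_oi = 1.0 / ((a_oi + b_oi) * KQ10)
        oi_inf = 1.0 / (1.0 + e((V + 43.1) / 5.3))

        tau_ua = tau_oa  # same alpha/beta pair as oa in the published model
        ua_inf = 1.0 / (1.0 + e(-(V + 30.3) / 9.6))

        a_ui = 1.0 / (21.0 + e(-(V - 185.0) / 28.0))
        b_ui = e((V - 158.0) / 16.0)
        tau_ui = 1.0 / ((a_ui + b_ui) * KQ10)
        ui_inf = 1.0 / (1.0 + e((V - 99.45) / 27.48))

        a_xr = _ratio(0.0003 * (V + 14.1), 1.0 - e(-(V + 14.1) / 5.0),
                      0.0015)
        b_xr = _ratio(7.3898e-5 * (V - 3.3328),
                      e((V - 3.3328) / 5.1237) - 1.0, 3.7861e-4)
        tau_xr = 1.0 / (a_xr + b_xr)
        xr_inf = 1.0 / (1.0 + e(-(V + 14.1) / 6.5))

        a_xs = _ratio(4e-5 * (V - 19.9), 1.0 - e(-(V - 19.9) / 17.0),
                      6.8e-4)
        b_xs = _ratio(3.5e-5 * (V - 19.9), e((V - 19.9) / 9.0) - 1.0,
                      3.15e-4)
        tau_xs = 0.5 / (a_xs + b_xs)
        xs_inf = 1.0 / np.sqrt(1.0 + e(-(V - 19.9) / 12.7))

        ex = e(-(V + 10.0) / 6.24)
        tau_d = _ratio(1.0 - ex, 0.035 * (V + 10.0) * (1.0 + ex),
                       1.0 / (2.0 * 0.035 * 6.24))
        d_inf = 1.0 / (1.0 + e(-(V + 10.0) / 8.0))

        tau_f = 9.0 / (0.0197 * e(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)
        f_inf = 1.0 / (1.0 + e((V + 28.0) / 6.9))

        w_val = w
        ca_i = w_val[17]
        fca_inf = 1.0 / (1.0 + ca_i / 0.00035)
        tau_fca = np.broadcast_to(p["tau_fCa"], np.shape(V)).astype(float)

        # Ca-release gates driven by the flux signal Fn
        if cur is None:
            cur = self._currents(V, w_val)
        Fn = 1e-12 * p["V_rel"] * cur["I_rel"] \
            - 5e-13 / p["F"] * (0.5 * cur["I_CaL"] - 0.2 * cur["I_NaCa"])
        u_inf = 1.0 / (1.0 + e(-(Fn - 3.4175e-13) / 13.67e-16))
        tau_u = np.broadcast_to(p["tau_u"], np.shape(V)).astype(float)
        tau_v = 1.91 + 2.09 / (1.0 + e(-(Fn - 3.4175e-13) / 13.67e-16))
        v_inf = 1.0 - 1.0 / (1.0 + e(-(Fn - 6.835e-14) / 13.67e-16))
        ew = e(-(V - 7.9) / 5.0)
        tau_w = _ratio(6.0 * (1.0 - ew), (1.0 + 0.3 * ew) * (V - 7.9),
                       6.0 * 0.2 / 1.3)
        w_inf = 1.0 - 1.0 / (1.0 + e(-(V - 40.0) / 17.0))

        infs = np.stack([m_inf, h_inf, j_inf, oa_inf, oi_inf, ua_inf, ui_inf,
                         xr_inf, xs_inf, d_inf, f_inf, fca_inf,
                         u_inf, v_inf, w_inf])
        taus = np.stack([tau_m, tau_h, tau_j, tau_oa, tau_oi, tau_ua, tau_ui,
                         tau_xr, tau_xs, tau_d, tau_f, tau_fca,
                         tau_u, tau_v, tau_w])
        return infs, taus

    # -- public interface ----------------------------------------------------

    def gating(self, u, w):
        return self._gate_kinetics(u, w)

    def _i_total(self, cur):
        return (cur["I_Na"] + cur["I_K1"] + cur["I_to"] + cur["I_Kur"]
                + cur["I_Kr"] + cur["I_Ks"] + cur["I_CaL"] + cur["I_pCa"]
                + cur["I_NaK"] + cur["I_NaCa"] + cur["I_bNa"] + cur["I_bCa"])

    def _conc_rates(self, w, cur):
        p = self.params
        F, V_i = p["F"], p["V_i"]
        d_nai = (-3.0 * cur["I_NaK"] - 3.0 * cur["I_NaCa"] - cur["I_bNa"]
                 - cur["I_Na"]) / (F * V_i)
        d_ki = (2.0 * cur["I_NaK"] - cur["I_K1"] - cur["I_to"] - cur["I_Kur"]
                - cur["I_Kr"] - cur["I_Ks"]) / (F * V_i)

        ca_i, ca_rel = w[17], w[19]
        B1 = (2.0 * cur["I_NaCa"] - cur["I_pCa"] - cur["I_CaL"]
              - cur["I_bCa"]) / (2.0 * F * V_i) \
            + (p["V_up"] * (cur["I_up_leak"] - cur["I_up"])
               + cur["I_rel"] * p["V_rel"]) / V_i
        B2 = 1.0 + p["Trpn_max"] * p["K_mTrpn"] / (ca_i + p["K_mTrpn"]) ** 2 \
            + p["Cmdn_max"] * p["K_mCmdn"] / (ca_i + p["K_mCmdn"]) ** 2
        d_cai = B1 / B2
        d_caup = cur["I_up"] - cur["I_up_leak"] \
            - cur["I_tr"] * p["V_rel"] / p["V_up"]
        d_carel = (cur["I_tr"] - cur["I_rel"]) / (
            1.0 + p["Csqn_max"] * p["K_mCsqn"] / (ca_rel + p["K_mCsqn"]) ** 2
        )
        return np.stack([d_nai, d_ki, d_cai, d_caup, d_carel])

    def rhs(self, u, w):
        cur = self._currents(u, w)
        i_ion = self._i_total(cur) / self.params["Cm"]  # pA -> mV/ms
        infs, taus = self._gate_kinetics(u, w, cur)
        gate_rates = (infs - w[:15]) / taus
        H = np.concatenate([gate_rates, self._conc_rates(w, cur)])
        return i_ion, H

    def imex_eval(self, u, w):
        cur = self._currents(u, w)
        w_eq, tau = self._gate_kinetics(u, w, cur)
        return w_eq, tau, self._conc_rates(w, cur)

    def i_ion(self, u, w):
        return self._i_total(self._currents(u, w)) / self.params["Cm"]
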