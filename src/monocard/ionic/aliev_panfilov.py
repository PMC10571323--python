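"""Aliev–Panfilov two-variable phenomenological model.

The dimensionless excitation–recovery system

    du/dt = −k u (u − a)(u − 1) − u w  (+ I_app)
    dw/dt = (ε0 + μ1 w / (u + μ2)) (−w − k u (u − a − 1))

with u ∈ [0, 1] (rest at u = 0, w = 0, an exact equilibrium).  One model
time unit corresponds to 12.9 ms of physical time, and the potential maps to
millivolts through u_mV = 100 u − 80.

The recovery variable enters its own rate nonlinearly through ε(u, w), so it
is advanced explicitly (the gating set is empty).
"""

from __future__ import annotations

import numpy as np

from .base import IonicModel

__all__ = ["AlievPanfilov"]


class AlievPanfilov(IonicModel):
    name = "AlievPanfilov"
    var_names = ("w",)
    gate_mask = np.array([False])
    voltage_mv = False
    time_unit_ms = 12.9
    rescale = (100.0, -80.0)

    DEFAULTS = {
        "k": 8.0,
        "a": 0.15,
        "eps0": 0.002,
        "mu1": 0.2,
        "mu2": 0.3,
    }

    def initial_state(self):
        return 0.0, np.array([0.0])

    def rhs(self, u, w):
        p = self.params
        wv = w[0]
        k, a = p["k"], p["a"]
        i_ion = k * u * (u - a) * (u - 1.0) + u * wv
        eps = p["eps0"] + p["mu1"] * wv / (u + p["mu2"])
        dw = eps * (-wv - k * u * (u - a - 1.0))
        return i_ion, dw[None, :]

    def gating(self, u, w):  # no implicitly-treated variables
        raise NotImplementedError("Aliev-Panfilov has no gating variables")
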