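"""Common machinery for cardiac ionic models.

An ionic model is the ODE system

    du/dt = −I_ion(u, w) + I_app,      dw/dt = H(u, w),

for the transmembrane potential u and M ionic variables w (gating variables
and ionic concentrations).  Models declare their native units: the
physiological models (TTP06, CRN) work in mV with time in ms, the
phenomenological ones (Aliev–Panfilov, Bueno–Orovio) use a dimensionless
potential — Aliev–Panfilov additionally has a dimensionless time unit worth
``time_unit_ms`` milliseconds.  All unit conversion between model units and
the tissue solver's SI units (V, s) is concentrated in the small adapter
methods of :class:`IonicModel`, so the model files transcribe the published
equations verbatim.

Time discretization follows the IMEX-BDF update: Hodgkin–Huxley-type gating
variables — whose dynamics dw/dt = (w∞(u) − w)/τ(u) is affine in the gate at
frozen potential — are advanced implicitly by closed-form inversion of the
BDF relation; all other variables (concentrations, the Aliev–Panfilov
recovery variable) are advanced explicitly from extrapolated arguments.  No
iterative nonlinear solve appears anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..fem import TimeScheme

logger = logging.getLogger(__name__)

__all__ = [
    "IonicModel",
    "IonicState",
    "MembraneScaling",
    "evaluate_rhs",
    "ionic_step",
    "single_cell_run",
    "rescale_potential",
    "normalize_formulation",
    "create_model",
]


@dataclass
class IonicState:
    """A (possibly vectorized) ionic state: u scalar/(n,), w (M,)/(M, n)."""

    u: np.ndarray
    w: np.ndarray

    def check_finite(self) -> bool:
        return bool(np.isfinite(self.u).all() and np.isfinite(self.w).all())


@dataclass
class MembraneScaling:
    """Membrane capacitance C_m (F/m²) and surface-to-volume ratio χ_m (1/m).

    The monodomain equation is frequently written with Î_ion, Î_app and D̂
    carrying these factors; dividing by C_m (currents) and χ_m·C_m
    (diffusion) recovers the rescaled formulation used internally.
    """

    C_m: float = 1.0
    chi_m: float = 1.0

    def __post_init__(self):
        if self.C_m <= 0 or self.chi_m <= 0:
            raise ValueError("C_m and chi_m must be positive")


def normalize_formulation(I_ion_hat, I_app_hat, D_hat,
                          scaling: MembraneScaling):
    """(Î_ion, Î_app, D̂) → (Î/C_m, Î/C_m, D̂/(χ_m C_m))."""
    c = scaling.C_m
    return (np.asarray(I_ion_hat) / c, np.asarray(I_app_hat) / c,
            np.asarray(D_hat) / (scaling.chi_m * c))


class IonicModel:
    """Base class; subclasses transcribe one published model.

    Class attributes set by subclasses: ``name``, ``var_names`` (tuple of M
    names), ``gate_mask`` (True for implicitly-treated gating variables),
    ``voltage_mv`` (model potential in mV?), ``time_unit_ms`` (physical ms
    per model time unit), ``rescale`` ((a, b) of u_mV = a·u + b for
    dimensionless models, None for physiological ones) and ``DEFAULTS``
    (the published parameter table).
    """

    name: str = ""
    var_names: tuple = ()
    gate_mask: np.ndarray = np.zeros(0, dtype=bool)
    voltage_mv: bool = True
    time_unit_ms: float = 1.0
    rescale: tuple | None = None
    DEFAULTS: dict = {}
    CELL_TYPES: tuple = ()

    def __init__(self, cell_type: str | None = None, overrides: dict | None = None):
        self.params = dict(self.DEFAULTS)
        self.cell_type = self._resolve_cell_type(cell_type)
        for k, v in (overrides or {}).items():
            self.set_parameter(k, v)

    def _resolve_cell_type(self, cell_type):
        if not self.CELL_TYPES:
            return None
        if cell_type is None:
            cell_type = self.CELL_TYPES[0]
        if cell_type not in self.CELL_TYPES:
            raise ValueError(
                f"{self.name}: unknown cell type {cell_type!r}; "
                f"valid: {list(self.CELL_TYPES)}"
            )
        return cell_type

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def set_parameter(self, name: str, value: float) -> None:
        if name not in self.params:
            raise KeyError(
                f"{self.name}: unknown parameter {name!r}; valid names: "
                f"{sorted(self.params)}"
            )
        self.params[name] = float(value)

    # -- interface implemented by subclasses (model units) ------------------

    def initial_state(self):
        raise NotImplementedError

    def rhs(self, u, w):
        """(I_ion, H) in model units per model time unit."""
        raise NotImplementedError

    def gating(self, u, w):
        """(w_eq, tau) of the gating subset, evaluated at frozen (u, w)."""
        raise NotImplementedError

    def imex_eval(self, u, w):
        """Everything the IMEX step needs at frozen (u, w) in one pass:
        (w_eq, tau) for the gates and the explicit rates of the remaining
        variables (None where a group is empty).  Subclasses override this
        to share intermediate quantities between the two groups.
        """
        w_eq = tau = h_ng = None
        if self.gate_mask.any():
            w_eq, tau = self.gating(u, w)
        if (~self.gate_mask).any():
            h_ng = self.rhs(u, w)[1][~self.gate_mask]
        return w_eq, tau, h_ng

    def i_ion(self, u, w):
        """The total ionic current alone (cheaper than the full rhs where a
        subclass can skip the gate kinetics)."""
        return self.rhs(u, w)[0]

    # -- unit adapters (single audited location) -----------------------------

    def dt_to_model(self, dt_s: float) -> float:
        """Physical seconds → model time units."""
        return dt_s * 1000.0 / self.time_unit_ms

    def u_to_model(self, u_tissue):
        """Tissue potential (V, or dimensionless) → model potential."""
        return u_tissue * 1000.0 if self.voltage_mv else u_tissue

    def u_to_tissue(self, u_model):
        return u_model / 1000.0 if self.voltage_mv else u_model

    def iion_to_tissue(self, i_model):
        """Model du/dt units → tissue units per second (V/s or 1/s)."""
        factor = (0.001 if self.voltage_mv else 1.0) * (1000.0 / self.time_unit_ms)
        return i_model * factor

    def iapp_to_model(self, i_tissue):
        factor = (1000.0 if self.voltage_mv else 1.0) * (self.time_unit_ms / 1000.0)
        return i_tissue * factor


def evaluate_rhs(model: IonicModel, u, w):
    """The model's (I_ion(u, w), H(u, w)) exactly as published (model units).

    Accepts a scalar state (u float, w (M,)) or a vectorized one
    (u (n,), w (M, n)) and returns matching shapes.
    """
    scalar = np.ndim(u) == 0
    u_arr = np.atleast_1d(np.asarray(u, dtype=np.float64))
    w_arr = np.asarray(w, dtype=np.float64).reshape(model.n_vars, -1)
    i_ion, H = model.rhs(u_arr, w_arr)
    if scalar:
        return float(i_ion[0]), H[:, 0]
    return i_ion, H


_clamp_events = 0


def ionic_step(model: IonicModel, scheme: TimeScheme, u_ext, w_history,
               dt: float):
    """One BDF step of the ionic variables (model time units).

    Gating variables are inverted in closed form from the BDF relation with
    w∞/τ frozen at (u_EXT, w_EXT); the remainder is updated explicitly.
    Gates are clamped to [0, 1] afterwards (guards against extrapolation
    overshoot; occurrences are counted and logged at debug level).

    Parameters
    ----------
    w_history : sequence of (M, n) arrays, newest first, length ≥ scheme.order.
    dt : time step in model time units, > 0.
    """
    global _clamp_events
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(w_history) < scheme.order:
        raise ValueError("history depth must be >= scheme order")
    w_history = [np.asarray(w, dtype=np.float64).reshape(model.n_vars, -1)
                 for w in w_history[: scheme.order]]
    u_ext = np.asarray(u_ext, dtype=np.float64)
    w_bdf = scheme.combine(scheme.bdf_weights, w_history)
    w_ext = scheme.combine(scheme.ext_weights, w_history)
    alpha = scheme.alpha

    w_new = np.empty_like(w_history[0])
    g = model.gate_mask
    w_eq, tau, h_ng = model.imex_eval(u_ext, w_ext)
    if g.any():
        r = dt / tau
        w_new[g] = (w_bdf[g] + r * w_eq) / (alpha + r)
        low = w_new[g] < 0.0
        high = w_new[g] > 1.0
        if low.any() or high.any():
            _clamp_events += int(low.sum() + high.sum())
            logger.debug("clamped %d gate values to [0, 1]",
                         int(low.sum() + high.sum()))
            w_new[g] = np.clip(w_new[g], 0.0, 1.0)
    if (~g).any():
        w_new[~g] = (w_bdf[~g] + dt * h_ng) / alpha
    return w_new


def single_cell_run(model: IonicModel, period: float, n_cycles: int,
                    dt: float, amplitude: float = 0.0, duration: float = 0.0,
                    order: int = 1, record: bool = False,
                    csv_path=None):
    """Integrate the model in 0D under periodic square-pulse pacing.

    Parameters (SI): ``period``/``dt``/``duration`` in seconds, ``amplitude``
    in V/s (model-units/s for dimensionless models).  One stimulus is
    delivered at the start of each cycle.  Returns ``(IonicState, trace)``;
    the trace dict carries per-step time (s), u and w in model units.  This
    is the standard way to obtain a tissue initial condition consistent with
    per-subdomain parameters (e.g. 1000 cycles at 0.8 s period), and also
    serves as the 0D oracle for the tissue stepper.
    """
    from ..fem import bdf_scheme

    if amplitude and not (period > duration > 0):
        raise ValueError("need period > duration > 0 for a paced run")
    scheme_full = bdf_scheme(order)
    dtm = model.dt_to_model(dt)
    amp_m = model.iapp_to_model(amplitude)
    u0, w0 = model.initial_state()
    n_steps_cycle = int(round(period / dt))
    u_hist = [np.full(1, float(u0))]
    w_hist = [np.asarray(w0, dtype=np.float64).reshape(-1, 1).copy()]

    times, u_tr, w_tr = [], [], []
    if record:
        times.append(0.0)
        u_tr.append(u_hist[0][0])
        w_tr.append(w_hist[0][:, 0].copy())

    step = 0
    for cycle in range(n_cycles):
        for k in range(n_steps_cycle):
            step += 1
            t_new = step * dt
            eff = bdf_scheme(min(order, len(u_hist)))
            u_bdf = eff.combine(eff.bdf_weights, u_hist)
            u_ext = eff.combine(eff.ext_weights, u_hist)
            w_new = ionic_step(model, eff, u_ext, w_hist, dtm)
            i_ion = model.i_ion(u_ext, w_new)
            # same half-open gate convention [t0, t0 + duration) as in tissue
            i_app = amp_m if (amplitude
                              and cycle * period <= t_new < cycle * period + duration) \
                else 0.0
            u_new = (u_bdf + dtm * (-i_ion + i_app)) / eff.alpha
            if not (np.isfinite(u_new).all() and np.isfinite(w_new).all()):
                raise FloatingPointError(
                    f"{model.name}: state diverged in cycle {cycle} "
                    f"(t = {t_new:.6g} s)"
                )
            u_hist = [u_new] + u_hist[: order - 1]
            w_hist = [w_new] + w_hist[: order - 1]
            if record:
                times.append(t_new)
                u_tr.append(u_new[0])
                w_tr.append(w_new[:, 0].copy())

    trace = None
    if record:
        trace = {
            "time": np.asarray(times),
            "u": np.asarray(u_tr),
            "w": np.asarray(w_tr).T,
        }
        if csv_path is not None:
            header = "time,u," + ",".join(model.var_names)
            data = np.column_stack([trace["time"], trace["u"], trace["w"].T])
            np.savetxt(csv_path, data, delimiter=",", header=header,
                       comments="")
    state = IonicState(u_hist[0][0], w_hist[0][:, 0].copy())
    return state, trace


def rescale_potential(model: IonicModel, u):
    """Model potential → millivolts for visualization.

    Phenomenological models apply their published affine map (Aliev–Panfilov
    u_mV = 100u − 80; Bueno–Orovio u_mV = 85.7u − 84); the physiological
    models already work in mV and are returned unchanged.
    """
    if model.rescale is None:
        return np.asarray(u, dtype=np.float64)
    a, b = model.rescale
    return a * np.asarray(u, dtype=np.float64) + b


def create_model(name: str, cell_type: str | None = None,
                 overrides: dict | None = None) -> IonicModel:
    """Instantiate a model by name (AlievPanfilov, BuenoOrovio, TTP06, CRN)."""
    from .aliev_panfilov import AlievPanfilov
    from .bueno_orovio import BuenoOrovio
    from .crn import CRN
    from .ttp06 import TTP06

    registry = {
        "alievpanfilov": AlievPanfilov,
        "apf": AlievPanfilov,
        "buenoorovio": BuenoOrovio,
        "bo": BuenoOrovio,
        "ttp06": TTP06,
        "crn": CRN,
    }
    key = name.replace("-", "").replace("_", "").replace(" ", "").lower()
    if key not in registry:
        raise ValueError(f"unknown ionic model {name!r}; "
                         f"valid: AlievPanfilov, BuenoOrovio, TTP06, CRN")
    return registry[key](cell_type=cell_type, overrides=overrides)
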