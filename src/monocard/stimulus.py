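"""Applied current protocols I_app(x, t) = Σ_i g_t^i(t) · g_x^i(x).

Each stimulus factors into a spatial shape g_x — the indicator of a cube,
sphere or plane slab, or a Gaussian bump with peak value 1 at its center so
that the configured amplitude is read directly in V/s — and a time gate g_t
that is 1 on [t0, t0 + duration) for each entry of ``initial_times``
(half-open, so a pulse ending at a step boundary does not fire twice).
Periodic pulse trains are expressed either as an explicit list of initial
times or with the (period, count) shorthand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Stimulus", "StimulusProtocol", "stimulus_support", "applied_current"]

_SHAPES = ("cube", "sphere", "plane", "gaussian")


@dataclass
class Stimulus:
    """One applied-current impulse (or periodic train of impulses).

    geometry keys by shape:
      cube:     center (3,), half_width (scalar or (3,))
      sphere:   center (3,), radius
      plane:    normal (3,), offset (n·x = offset mid-plane), thickness
      gaussian: center (3,), width (standard deviation, m)
    """

    shape: str
    geometry: dict
    amplitude: float  # V/s (model-units/s for dimensionless ionic models)
    duration: float   # s
    initial_times: tuple = (0.0,)

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown stimulus shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        self.initial_times = tuple(sorted(float(t) for t in self.initial_times))

    @classmethod
    def train(cls, shape, geometry, amplitude, duration, start: float,
              period: float, count: int) -> "Stimulus":
        """(period, count) shorthand for a periodic pulse train."""
        times = tuple(start + k * period for k in range(count))
        return cls(shape, geometry, amplitude, duration, times)

    def time_gate(self, t: float) -> float:
        for t0 in self.initial_times:
            if t0 <= t < t0 + self.duration:
                return 1.0
        return 0.0


def stimulus_support(stim: Stimulus, x) -> np.ndarray:
    """Evaluate g_x at points x (n, 3) or a single point (3,).

    Indicator shapes return {0, 1} (boundary inclusive); the Gaussian is
    exp(−|x−c|²/(2 width²)), smooth with peak 1 at the center.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    g = stim.geometry
    tol = 1e-12
    if stim.shape == "cube":
        c = np.asarray(g["center"], float)
        hw = np.broadcast_to(np.asarray(g["half_width"], float), (3,))
        out = (np.abs(x - c) <= hw + tol).all(axis=1).astype(np.float64)
    elif stim.shape == "sphere":
        c = np.asarray(g["center"], float)
        out = (np.linalg.norm(x - c, axis=1)
               <= g["radius"] + tol).astype(np.float64)
    elif stim.shape == "plane":
        n = np.asarray(g["normal"], float)
        n = n / np.linalg.norm(n)
        d = x @ n - float(g["offset"])
        out = (np.abs(d) <= 0.5 * g["thickness"] + tol).astype(np.float64)
    else:  # gaussian
        c = np.asarray(g["center"], float)
        w = float(g["width"])
        out = np.exp(-np.sum((x - c) ** 2, axis=1) / (2.0 * w * w))
    return out if out.shape[0] > 1 else out.reshape(())


@dataclass
class StimulusProtocol:
    """The full applied current: a (possibly empty) list of stimuli."""

    stimuli: list = field(default_factory=list)

    @property
    def n_stim(self) -> int:
        return len(self.stimuli)

    def evaluate(self, x, t: float) -> np.ndarray:
        """I_app at points x and time t, in V/s (superposition of stimuli)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        out = np.zeros(x.shape[0])
        for stim in self.stimuli:
            gt = stim.time_gate(t)
            if gt:
                out += stim.amplitude * gt * stimulus_support(stim, x)
        return out

    def is_active(self, t: float) -> bool:
        return any(s.time_gate(t) for s in self.stimuli)


def applied_current(protocol: StimulusProtocol, x, t: float):
    """I_app(x, t) = Σ_i amplitude_i g_t^i(t) g_x^i(x)."""
    out = protocol.evaluate(x, t)
    return out if out.shape[0] > 1 else float(out[0])
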