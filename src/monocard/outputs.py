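"""Simulation outputs: VTU snapshot series, activation maps and CSV traces.

Field snapshots are written as an ASCII VTU time series (one file per
output step plus a ParaView ``.pvd`` collection) containing the potential
both in model units (``u``) and rescaled to millivolts (``u_mV``).  CSV
traces carry the per-step min/max of the potential over the mesh and
optional pointwise probe values.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .io import write_vtu

__all__ = ["SnapshotWriter", "write_trace_csv", "write_activation_csv"]


class SnapshotWriter:
    """Writes numbered VTU snapshots and a .pvd collection for a running
    simulation (nodal fields only; higher-degree DOFs are sampled at the
    mesh nodes)."""

    def __init__(self, sim, directory, basename: str = "solution"):
        from .ionic.base import rescale_potential  # local import, no cycle

        self.sim = sim
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.basename = basename
        self.entries = []
        self._rescale = rescale_potential
        self._node_map = self._mesh_node_dofs()

    def _mesh_node_dofs(self):
        space = self.sim.space
        if space.degree == 1:
            return np.arange(space.mesh.n_nodes)
        # locate mesh nodes among the support points by rounded coordinates
        scale = max(np.ptp(space.mesh.nodes, axis=0).max(), 1e-30)
        keys = {tuple(k): i for i, k in enumerate(
            np.round(space.support_points / (1e-8 * scale)).astype(np.int64))}
        return np.array([
            keys[tuple(k)] for k in
            np.round(space.mesh.nodes / (1e-8 * scale)).astype(np.int64)
        ])

    def _nodal(self, full_field):
        return full_field[self._node_map]

    def write(self, step: int) -> None:
        sim = self.sim
        u_full = sim.full_field(sim.u_hist[0])
        u = self._nodal(u_full)
        # rescale to mV per subdomain model (models may differ per region)
        u_mv = np.full_like(u_full, np.nan)
        for model, loc in zip(sim.models, sim.sub_local):
            g = sim.active_dofs[loc]
            u_mv[g] = self._rescale(model, model.u_to_model(u_full[g]))
        fname = f"{self.basename}_{step:06d}.vtu"
        write_vtu(self.dir / fname, sim.space.mesh,
                  point_data={"u": np.nan_to_num(u, nan=0.0),
                              "u_mV": np.nan_to_num(self._nodal(u_mv), nan=0.0)})
        self.entries.append((sim.time, fname))
        self._write_pvd()

    def finalize(self, activation) -> None:
        act = self._nodal(activation.full())
        write_vtu(self.dir / f"{self.basename}_activation.vtu",
                  self.sim.space.mesh,
                  point_data={"activation_time": np.nan_to_num(act, nan=-1.0)})
        if self.sim.problem.output.csv_trace:
            write_trace_csv(self.dir / f"{self.basename}_trace.csv", self.sim)
        self._write_pvd()

    def _write_pvd(self) -> None:
        lines = ['<?xml version="1.0"?>',
                 '<VTKFile type="Collection" version="0.1">',
                 "  <Collection>"]
        for t, fname in self.entries:
            lines.append(f'    <DataSet timestep="{t!r}" file="{fname}"/>')
        lines += ["  </Collection>", "</VTKFile>", ""]
        (self.dir / f"{self.basename}.pvd").write_text("\n".join(lines))


def write_trace_csv(path, sim) -> None:
    """Per-step min/max (and probe) potential trace.

    Columns: time (s), u_min, u_max and one column per probe point, all in
    tissue units (V for physiological models, dimensionless otherwise).
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["time", "u_min", "u_max"]
        probes = sim.trace_probe
        if probes is not None:
            header += [f"probe_{k}" for k in range(len(probes[0]))]
        w.writerow(header)
        w.writerow(["# s", "tissue units", "tissue units"]
                   + (["tissue units"] * (len(header) - 3)))
        for k, t in enumerate(sim.trace_t):
            row = [repr(float(t)), repr(float(sim.trace_min[k])),
                   repr(float(sim.trace_max[k]))]
            if probes is not None:
                row += [repr(float(v)) for v in probes[k]]
            w.writerow(row)


def write_activation_csv(path, space, activation) -> None:
    """Activation time per DOF with its support-point coordinates (s; empty
    field for never-activated DOFs)."""
    full = activation.full()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "z", "activation_time"])
        for p, t in zip(space.support_points, full):
            w.writerow([repr(float(p[0])), repr(float(p[1])),
                        repr(float(p[2])),
                        "" if np.isnan(t) else repr(float(t))])
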