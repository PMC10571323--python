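"""Plain-text parameter files: schema, templates, parsing and problem setup.

The configuration format mirrors self-documenting solver parameter files:
key = value lines grouped under bracketed section headers, with ``#``
comments.  Every key has a documented default; keys absent from a file
retain their defaults, and unknown keys or sections are rejected with the
offending line number.  Templates can be emitted at three verbosity levels
(minimal / default / full), and the subdomain sections are generated from
user-supplied volume labels — parsing a file against a different label set
than the one used to generate it is an error.

Example (three pathological subdomains)::

    [Healthy]
      Material IDs = 1
      Ionic model = CRN
    [Fibrosis]
      Material IDs = 2
      Ionic model = CRN
      Parameter overrides = gCaL = 0.030938; gK1 = 0.18
    [Scar]
      Material IDs = 3
      Disable conduction = true
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

__all__ = [
    "ConfigError",
    "ParameterTree",
    "parse_parameter_file",
    "generate_template",
    "problem_from_parameters",
]

LEVELS = {"minimal": 0, "default": 1, "full": 2}
DEFAULT_VOLUME_LABELS = ("Volumetric",)

# benchmark-style monodomain conductivities (m²/s): harmonic mean of the
# intra/extracellular values divided by chi_m * C_m
SIGMA_L_DEFAULT = 0.17 * 0.62 / (0.17 + 0.62) / 1400.0
SIGMA_T_DEFAULT = 0.019 * 0.24 / (0.019 + 0.24) / 1400.0


class ConfigError(ValueError):
    """Invalid configuration (bad file syntax, unknown key, bad value)."""


def _schema(volume_labels):
    """section -> {key: (default, doc, level)}; order defines emission order."""
    s = {}
    s["Mesh and space discretization"] = {
        "Element type": ("Hexahedra", "Hexahedra | Tetrahedra", 0),
        "Mesh file": ("", "gmsh .msh or .vtu file; empty generates a slab", 0),
        "Scaling factor": (1.0, "coordinate rescaling to meters (1e-3 for mm meshes)", 0),
        "Slab extents": ((0.003, 0.007, 0.02), "built-in slab edge lengths (m)", 1),
        "Slab element size": (0.0005, "built-in slab lattice spacing (m)", 1),
        "FE space degree": (1, "polynomial degree p (tetrahedra: 1 or 2)", 1),
        "Number of refinements": (0, "uniform refinements (hexahedral meshes only)", 1),
    }
    s["Time discretization"] = {
        "BDF order": (2, "time scheme order (1, 2 or 3)", 0),
        "Time step": (5e-5, "dt (s)", 0),
        "Final time": (0.05, "T (s)", 0),
    }
    s["Membrane scaling"] = {
        "Membrane capacitance": (1.0, "C_m; file conductivities/amplitudes are "
                                 "divided by C_m (chi_m C_m for D)", 2),
        "Surface-to-volume ratio": (1.0, "chi_m (1/m)", 2),
    }
    s["Linear solver"] = {
        "Method": ("CG", "CG | Direct", 2),
        "Tolerance": (1e-10, "relative residual for CG", 2),
        "Max iterations": (2000, "", 2),
        "Preconditioner": ("Jacobi", "Jacobi | None", 2),
    }
    s["Fiber generation"] = {
        "Geometry type": ("Slab", "Slab | Import from file", 0),
        "Endocardium angle": (60.0, "fiber angle (deg) at the endocardial face", 1),
        "Epicardium angle": (-60.0, "fiber angle (deg) at the epicardial face", 1),
        "Long axis": ((0.0, 0.0, 1.0), "slab long-axis direction", 2),
        "Transmural axis": ((0.0, 1.0, 0.0), "endo-to-epi direction", 2),
        "Fiber file": ("", "VTU file for Import from file", 1),
        "Fiber scaling factor": (1.0, "coordinate rescaling of the fiber file", 1),
        "Fiber array name": ("fibers", "", 2),
        "Sheet array name": ("sheets", "", 2),
        "Sheet normal array name": ("sheet_normals", "", 2),
    }
    for label in volume_labels:
        s[label] = {
            "Material IDs": ((0,), "element labels belonging to this volume", 0),
            "Longitudinal conductivity": (SIGMA_L_DEFAULT, "sigma_l (m^2/s)", 0),
            "Transversal conductivity": (SIGMA_T_DEFAULT, "sigma_t (m^2/s)", 0),
            "Normal conductivity": (SIGMA_T_DEFAULT, "sigma_n (m^2/s)", 0),
            "Ionic model": ("TTP06", "AlievPanfilov | BuenoOrovio | TTP06 | CRN", 0),
            "Cell type": ("Epicardium", "Epicardium | Endocardium | Myocardium", 1),
            "Parameter overrides": ("", "semicolon-separated name = value pairs", 2),
            "Disable conduction": (False, "exclude this volume from conduction", 1),
        }
    for shape, extra in (
        ("Cubic", {"Half-width": (0.00075, "cube half edge (m)", 1),
                   "Center": ((0.00075, 0.00075, 0.00075), "cube center (m)", 1)}),
        ("Spherical", {"Radius": (0.003, "sphere radius (m)", 1),
                       "Center": ((0.0, 0.0, 0.0), "sphere center (m)", 1)}),
        ("Planar", {"Normal": ((0.0, 0.0, 1.0), "plane normal", 1),
                    "Offset": (0.0, "normal . x at the mid-plane (m)", 1),
                    "Thickness": (0.001, "slab thickness (m)", 1)}),
        ("Gaussian", {"Width": (0.002, "standard deviation (m)", 1),
                      "Center": ((0.0, 0.0, 0.0), "peak location (m)", 1)}),
    ):
        sec = {"Enabled": (False, "", 0)}
        sec.update(extra)
        sec.update({
            "Amplitude": (35.714, "V/s (model-units/s for dimensionless models)", 1),
            "Duration": (0.002, "pulse duration (s)", 1),
            "Impulse initial times": ((0.0,), "pulse start times (s)", 1),
            "Impulse period": (0.0, "optional (period, count) train shorthand", 2),
            "Impulse count": (1, "", 2),
        })
        s[f"Applied current/{shape}"] = sec
    s["Electrophysiology/Output"] = {
        "Enabled": (False, "write VTU snapshots and CSV traces", 1),
        "Directory": ("output", "", 1),
        "Filename": ("solution", "", 2),
        "Output cadence": (20, "write every n-th step", 1),
        "CSV trace": (True, "min/max/pointwise potential over time", 2),
    }
    s["Electrophysiology/Activation time"] = {
        "Enabled": (True, "track time of maximum du/dt per DOF", 1),
        "Rate threshold": (10.0, "minimum max-du/dt (tissue units/s) to count "
                           "a DOF as activated", 2),
    }
    s["Single cell initialization"] = {
        "Enabled": (False, "initialize each volume from a paced 0D run", 1),
        "Cycles": (1000, "number of pacing cycles", 1),
        "Period": (0.8, "pacing period (s)", 1),
        "Stimulus amplitude": (50.0, "V/s", 2),
        "Stimulus duration": (0.002, "s", 2),
        "Time step": (1e-4, "0D integration step (s)", 2),
    }
    return s


class ParameterTree:
    """Parsed configuration: defaults overlaid with file values."""

    def __init__(self, volume_labels=None):
        self.volume_labels = tuple(volume_labels or DEFAULT_VOLUME_LABELS)
        self.schema = _schema(self.volume_labels)
        self.values = {sec: {k: v[0] for k, v in keys.items()}
                       for sec, keys in self.schema.items()}

    def get(self, section: str, key: str):
        try:
            return self.values[section][key]
        except KeyError:
            raise ConfigError(f"unknown parameter [{section}] {key}") from None

    def set(self, section: str, key: str, value) -> None:
        if section not in self.schema or key not in self.schema[section]:
            raise ConfigError(f"unknown parameter [{section}] {key}")
        self.values[section][key] = value

    # -- emission -----------------------------------------------------------

    def emit(self, verbosity: str = "default") -> str:
        if verbosity not in LEVELS:
            raise ConfigError(f"verbosity must be one of {sorted(LEVELS)}")
        lvl = LEVELS[verbosity]
        out = ["# monocard parameter file", ""]
        for sec, keys in self.schema.items():
            shown = [(k, spec) for k, spec in keys.items() if spec[2] <= lvl]
            if not shown:
                continue
            out.append(f"[{sec}]")
            for k, (_, doc, _) in shown:
                if doc:
                    out.append(f"  # {doc}")
                out.append(f"  {k} = {_format(self.values[sec][k])}")
            out.append("")
        return "\n".join(out)


def _format(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (tuple, list)):
        return ", ".join(_format(x) for x in v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _convert(raw: str, default, where: str):
    raw = raw.strip()
    if isinstance(default, bool):
        if raw.lower() in ("true", "yes", "1"):
            return True
        if raw.lower() in ("false", "no", "0"):
            return False
        raise ConfigError(f"{where}: expected true/false, got {raw!r}")
    if isinstance(default, (tuple, list)):
        inner = type(default[0]) if default else float
        if not raw:
            return ()
        try:
            return tuple(inner(float(x)) if inner is not str else x.strip()
                         for x in raw.split(","))
        except ValueError:
            raise ConfigError(f"{where}: cannot parse list {raw!r}") from None
    if isinstance(default, int) and not isinstance(default, bool):
        try:
            return int(float(raw))
        except ValueError:
            raise ConfigError(f"{where}: expected integer, got {raw!r}") from None
    if isinstance(default, float):
        try:
            return float(raw)
        except ValueError:
            raise ConfigError(f"{where}: expected number, got {raw!r}") from None
    return raw


def generate_template(volume_labels=None, verbosity: str = "default") -> str:
    """Template parameter file with documented defaults."""
    return ParameterTree(volume_labels).emit(verbosity)


def parse_parameter_file(path, volume_labels=None) -> ParameterTree:
    """Parse a parameter file; missing keys retain their defaults.

    ``volume_labels`` must match the labels the file was generated with
    (they name the subdomain sections).
    """
    tree = ParameterTree(volume_labels)
    text = Path(path).read_text()
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        m = re.match(r"\s*\[(.+)\]\s*$", line)
        if m:
            section = m.group(1).strip()
            if section not in tree.schema:
                raise ConfigError(
                    f"{path}:{lineno}: unknown section [{section}] — volume "
                    f"labels must match the ones used for generating the "
                    f"parameter file (have {list(tree.volume_labels)})")
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got "
                              f"{line.strip()!r}")
        if section is None:
            raise ConfigError(f"{path}:{lineno}: key outside any section")
        key, val = (x.strip() for x in line.split("=", 1))
        if key not in tree.schema[section]:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r} in "
                              f"[{section}]")
        default = tree.schema[section][key][0]
        tree.values[section][key] = _convert(val, default,
                                             f"{path}:{lineno}")
    return tree


def _parse_overrides(raw: str):
    out = {}
    for part in raw.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ConfigError(f"bad parameter override {part!r}")
        name, val = (x.strip() for x in part.split("=", 1))
        out[name] = float(val)
    return out


def problem_from_parameters(tree: ParameterTree):
    """Build a ready-to-run MonodomainProblem from a parameter tree."""
    from . import fibers as fib
    from . import io as mio
    from .fem import FESpace
    from .geometry import (SubdomainSpec, build_slab_mesh, refine_hex_mesh)
    from .ionic.base import MembraneScaling, create_model, single_cell_run
    from .solver import (LinearSolverSettings, MonodomainProblem,
                         OutputSettings)
    from .stimulus import Stimulus, StimulusProtocol

    g = tree.get
    sec = "Mesh and space discretization"
    kind = g(sec, "Element type").lower()
    if kind not in ("hexahedra", "tetrahedra"):
        raise ConfigError(f"unknown element type {g(sec, 'Element type')!r}")
    mesh_file = g(sec, "Mesh file")
    if mesh_file:
        mesh = mio.import_mesh(mesh_file, g(sec, "Scaling factor"))
        want = "hexahedron" if kind == "hexahedra" else "tetrahedron"
        if mesh.element_kind != want:
            raise ConfigError(f"mesh holds {mesh.element_kind}s but the "
                              f"parameter file requests {want}s")
    else:
        mesh = build_slab_mesh(g(sec, "Slab extents"),
                               g(sec, "Slab element size"))
        if kind == "tetrahedra":
            from .bench import hex_to_tet_mesh
            mesh = hex_to_tet_mesh(mesh)
    for _ in range(g(sec, "Number of refinements")):
        mesh = refine_hex_mesh(mesh)
    degree = g(sec, "FE space degree")
    space = FESpace(mesh, degree)

    scaling = MembraneScaling(g("Membrane scaling", "Membrane capacitance"),
                              g("Membrane scaling", "Surface-to-volume ratio"))
    cdiv = scaling.C_m
    ddiv = scaling.chi_m * scaling.C_m

    subdomains = []
    models = []
    initial_states = {}
    init_sec = "Single cell initialization"
    for label in tree.volume_labels:
        spec = SubdomainSpec(
            label=label,
            material_ids=frozenset(g(label, "Material IDs")),
            sigma_l=g(label, "Longitudinal conductivity") / ddiv,
            sigma_t=g(label, "Transversal conductivity") / ddiv,
            sigma_n=g(label, "Normal conductivity") / ddiv,
            ionic_model=g(label, "Ionic model"),
            cell_type=g(label, "Cell type"),
            parameter_overrides=_parse_overrides(g(label, "Parameter overrides")),
            conductive=not g(label, "Disable conduction"),
        )
        subdomains.append(spec)
        if spec.conductive:
            model = create_model(spec.ionic_model, spec.cell_type,
                                 spec.parameter_overrides)
            if tree.get(init_sec, "Enabled"):
                state, _ = single_cell_run(
                    model,
                    period=g(init_sec, "Period"),
                    n_cycles=g(init_sec, "Cycles"),
                    dt=g(init_sec, "Time step"),
                    amplitude=g(init_sec, "Stimulus amplitude") / cdiv,
                    duration=g(init_sec, "Stimulus duration"),
                )
                initial_states[label] = state
            models.append(model)
        else:
            models.append(None)
    # the simulator wants models indexed like subdomains
    model_list = models

    fsec = "Fiber generation"
    gtype = g(fsec, "Geometry type").lower()
    if gtype == "slab":
        axis = np.asarray(g(fsec, "Transmural axis"), float)
        coords = space.support_points @ (axis / np.linalg.norm(axis))
        lo, hi = coords.min(), coords.max()
        tol = 1e-9 * max(hi - lo, 1.0)
        phi = fib.transmural_laplace(
            space,
            lambda p, c=coords: c <= lo + tol,
            lambda p, c=coords: c >= hi - tol,
        )
        frame = fib.slab_fiber_rule(space, phi,
                                    g(fsec, "Endocardium angle"),
                                    g(fsec, "Epicardium angle"),
                                    long_axis=g(fsec, "Long axis"),
                                    transmural_axis=g(fsec, "Transmural axis"))
    elif gtype == "import from file":
        frame = fib.import_fibers(
            g(fsec, "Fiber file"), g(fsec, "Fiber scaling factor"), space,
            array_names=(g(fsec, "Fiber array name"),
                         g(fsec, "Sheet array name"),
                         g(fsec, "Sheet normal array name")))
    else:
        raise ConfigError(
            f"Geometry type {g(fsec, 'Geometry type')!r} is not available "
            f"(only Slab and Import from file; ventricular/atrial rule-based "
            f"methods are out of scope)")

    stimuli = []
    for shape, key in (("cube", "Cubic"), ("sphere", "Spherical"),
                       ("plane", "Planar"), ("gaussian", "Gaussian")):
        ssec = f"Applied current/{key}"
        if not g(ssec, "Enabled"):
            continue
        if shape == "cube":
            geom = {"center": g(ssec, "Center"),
                    "half_width": g(ssec, "Half-width")}
        elif shape == "sphere":
            geom = {"center": g(ssec, "Center"), "radius": g(ssec, "Radius")}
        elif shape == "plane":
            geom = {"normal": g(ssec, "Normal"), "offset": g(ssec, "Offset"),
                    "thickness": g(ssec, "Thickness")}
        else:
            geom = {"center": g(ssec, "Center"), "width": g(ssec, "Width")}
        times = g(ssec, "Impulse initial times")
        period = g(ssec, "Impulse period")
        count = g(ssec, "Impulse count")
        if period > 0 and count > 1:
            start = times[0] if times else 0.0
            times = tuple(start + k * period for k in range(count))
        stimuli.append(Stimulus(shape, geom, g(ssec, "Amplitude") / cdiv,
                                g(ssec, "Duration"), times))

    out_sec = "Electrophysiology/Output"
    output = OutputSettings(
        every_n_steps=g(out_sec, "Output cadence"),
        directory=(g(out_sec, "Directory") if g(out_sec, "Enabled") else None),
        write_vtu=g(out_sec, "Enabled"),
        csv_trace=g(out_sec, "CSV trace"),
    )
    ls = LinearSolverSettings(
        method=g("Linear solver", "Method").lower(),
        tolerance=g("Linear solver", "Tolerance"),
        max_iterations=g("Linear solver", "Max iterations"),
        preconditioner=g("Linear solver", "Preconditioner").lower(),
    )
    problem = MonodomainProblem(
        mesh=mesh,
        subdomains=subdomains,
        frame=frame,
        protocol=StimulusProtocol(stimuli),
        degree=degree,
        bdf_order=g("Time discretization", "BDF order"),
        dt=g("Time discretization", "Time step"),
        T=g("Time discretization", "Final time"),
        linear_solver=ls,
        output=output,
        activation_rate_threshold=g("Electrophysiology/Activation time",
                                    "Rate threshold"),
        models=model_list,
        initial_states=initial_states or None,
    )
    return problem
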