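"""Parameter files: defaults, templates, strict parsing, problem building."""

import numpy as np
import pytest

from monocard.params import (ConfigError, ParameterTree, generate_template,
                             parse_parameter_file, problem_from_parameters)


def test_empty_file_yields_pure_defaults(tmp_path):
    path = tmp_path / "empty.prm"
    path.write_text("")
    tree = parse_parameter_file(path)
    ref = ParameterTree()
    assert tree.values == ref.values
    assert tree.get("Time discretization", "BDF order") == 2
    assert tree.get("Volumetric", "Ionic model") == "TTP06"


def test_volume_labels_create_sections():
    text = generate_template(["Healthy", "Fibrosis", "Scar"])
    for label in ("Healthy", "Fibrosis", "Scar"):
        assert f"[{label}]" in text
    assert "[Volumetric]" not in text


def test_template_parse_reemit_is_idempotent(tmp_path):
    for verbosity in ("minimal", "default", "full"):
        text = generate_template(["A", "B"], verbosity)
        path = tmp_path / f"{verbosity}.prm"
        path.write_text(text)
        tree = parse_parameter_file(path, ["A", "B"])
        assert tree.emit(verbosity) == text


def test_verbosity_levels_nest():
    mini = generate_template(verbosity="minimal")
    full = generate_template(verbosity="full")
    assert "Time step" in mini
    assert "Preconditioner" not in mini
    assert "Preconditioner" in full
    for line in mini.splitlines():
        if "=" in line:
            key = line.split("=")[0].strip()
            assert key in full


def test_mismatched_volume_labels_rejected(tmp_path):
    path = tmp_path / "v.prm"
    path.write_text(generate_template(["Healthy", "Scar"]))
    with pytest.raises(ConfigError, match="must match"):
        parse_parameter_file(path, ["Healthy", "Fibrosis"])


def test_malformed_lines_reported_with_line_number(tmp_path):
    path = tmp_path / "bad.prm"
    path.write_text("[Time discretization]\n  nonsense line\n")
    with pytest.raises(ConfigError, match="bad.prm:2"):
        parse_parameter_file(path)
    path.write_text("[Time discretization]\n  No such key = 3\n")
    with pytest.raises(ConfigError, match="unknown key"):
        parse_parameter_file(path)
    path.write_text("Key = 1\n")
    with pytest.raises(ConfigError, match="outside"):
        parse_parameter_file(path)


def test_values_parsed_with_types_and_comments(tmp_path):
    path = tmp_path / "v.prm"
    path.write_text("""
# comment
[Mesh and space discretization]
  Scaling factor = 1e-3   # mm input
  FE space degree = 2
[Volumetric]
  Material IDs = 1, 2, 3
  Disable conduction = true
""")
    tree = parse_parameter_file(path)
    assert tree.get("Mesh and space discretization", "Scaling factor") == 1e-3
    assert tree.get("Mesh and space discretization", "FE space degree") == 2
    assert tree.get("Volumetric", "Material IDs") == (1, 2, 3)
    assert tree.get("Volumetric", "Disable conduction") is True


def test_problem_built_from_defaults_smoke(tmp_path):
    """The all-defaults tree builds a runnable slab problem (coarse here)."""
    path = tmp_path / "p.prm"
    path.write_text("""
[Mesh and space discretization]
  Slab element size = 0.001
[Time discretization]
  Time step = 1e-4
  Final time = 1e-3
[Applied current/Cubic]
  Enabled = true
""")
    tree = parse_parameter_file(path)
    problem = problem_from_parameters(tree)
    assert problem.mesh.n_elements == 3 * 7 * 20
    assert problem.protocol.n_stim == 1
    assert problem.subdomains[0].ionic_model == "TTP06"
    from monocard.solver import run_simulation

    res = run_simulation(problem)  # 10 coarse steps
    assert np.isfinite(res.u_final).all()


def test_scaling_factor_lands_mm_mesh_in_meters(tmp_path):
    from monocard.geometry import build_slab_mesh
    from monocard.io import write_vtu

    mesh_mm = build_slab_mesh((3.0, 7.0, 20.0), 1.0)  # mm-unit file
    write_vtu(tmp_path / "slab.vtu", mesh_mm)
    path = tmp_path / "p.prm"
    path.write_text(f"""
[Mesh and space discretization]
  Mesh file = {tmp_path / 'slab.vtu'}
  Scaling factor = 1e-3
[Time discretization]
  Time step = 1e-4
  Final time = 1e-3
""")
    problem = problem_from_parameters(parse_parameter_file(path))
    assert np.isclose(problem.mesh.nodes.max(), 0.02)


def test_parameter_overrides_reach_the_model(tmp_path):
    path = tmp_path / "p.prm"
    path.write_text("""
[Volumetric]
  Ionic model = CRN
  Parameter overrides = gCaL = 0.03; gK1 = 0.18
[Mesh and space discretization]
  Slab element size = 0.001
[Time discretization]
  Time step = 1e-4
  Final time = 1e-3
""")
    problem = problem_from_parameters(parse_parameter_file(path))
    model = problem.models[0]
    assert model.params["gCaL"] == 0.03
    assert model.params["gK1"] == 0.18


def test_unavailable_fiber_geometry_types_rejected(tmp_path):
    path = tmp_path / "p.prm"
    path.write_text("""
[Fiber generation]
  Geometry type = Left atrium
[Mesh and space discretization]
  Slab element size = 0.001
[Time discretization]
  Time step = 1e-4
  Final time = 1e-3
""")
    with pytest.raises(ConfigError, match="out of scope"):
        problem_from_parameters(parse_parameter_file(path))


class TestCLI:
    def _run(self, *args):
        import subprocess
        import sys

        return subprocess.run([sys.executable, "-m", "monocard.cli", *args],
                              capture_output=True, text=True)

    def test_generate_run_roundtrip(self, tmp_path):
        prm = tmp_path / "case.prm"
        r = self._run("generate-params", "default", "-o", str(prm))
        assert r.returncode == 0 and prm.exists()
        text = prm.read_text().replace(
            "Final time = 0.05", "Final time = 0.0005").replace(
            "Slab element size = 0.0005", "Slab element size = 0.001")
        prm.write_text(text)
        r = self._run("run", "-f", str(prm))
        assert r.returncode == 0, r.stderr
        assert "steps: 10" in r.stdout

    def test_config_error_exit_code_1(self, tmp_path):
        prm = tmp_path / "bad.prm"
        prm.write_text("[No such section]\nkey = 1\n")
        r = self._run("run", "-f", str(prm))
        assert r.returncode == 1
        assert "configuration error" in r.stderr
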