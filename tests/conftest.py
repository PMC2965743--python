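"""Shared fixtures: meshes, calibrated amplitude, and the scenario battery.

3-D runs use a desk-scale study geometry (tubule radii scaled up so a
0.15 µm grid resolves them) and a coarse cylindrical variant; the shipped
default spec at its calibration resolution is generated once for the
geometry checks.  Everything heavy is session-scoped.
"""

from dataclasses import replace

import numpy as np
import pytest

from ttcasim import (
    LineScanSpec,
    TTubuleSpec,
    extract_linescan,
    generate_ttubule_mesh,
    run_3d,
)
from ttcasim.geometry import DEFAULT_EDGE_LENGTH
from ttcasim.presets import PRESETS, calibrated_lcc_amplitude

# desk-scale branched geometry for solver property tests: same topology and
# box, tubule radii scaled up ~1.6x so the coarse 0.15 µm grid resolves them
COARSE_SPEC = TTubuleSpec(radius_min=0.15, radius_max=0.35, mouth_radius=0.45,
                          branch_length=0.5, seed=20101028)
COARSE_H = 0.15

CYL_SPEC = TTubuleSpec(variant="cylindrical", radius_min=0.25, radius_max=0.25)
CYL_H = 0.25


@pytest.fixture(scope="session")
def coarse_mesh():
    return generate_ttubule_mesh(COARSE_SPEC, COARSE_H)


@pytest.fixture(scope="session")
def cyl_mesh():
    return generate_ttubule_mesh(CYL_SPEC, CYL_H)


@pytest.fixture(scope="session")
def default_mesh():
    """The shipped default branched spec at its calibration resolution."""
    return generate_ttubule_mesh(TTubuleSpec(), DEFAULT_EDGE_LENGTH)


@pytest.fixture(scope="session")
def lcc_amplitude():
    """Amplitude calibrated so the dye-present 0-D peak equals 163 nM."""
    return calibrated_lcc_amplitude()


@pytest.fixture(scope="session")
def linescan_spec():
    return LineScanSpec(offset=0.2)


@pytest.fixture(scope="session")
def scenario_solutions(coarse_mesh, lcc_amplitude):
    """All six study scenarios run on the desk-scale branched mesh."""
    out = {}
    for name in ("fig4_heterogeneous", "fig4_uniform6x", "fig4_homogeneous",
                 "fig6_nodye", "fig7_immobile", "fig8_zeroNa"):
        cfg = PRESETS[name].simulation_config(dt=0.5, output_stride=4)
        cfg = replace(cfg, lcc=replace(cfg.lcc, amplitude=lcc_amplitude))
        out[name] = run_3d(coarse_mesh, cfg)
    return out


@pytest.fixture(scope="session")
def scenario_linescans(scenario_solutions, linescan_spec):
    return {name: extract_linescan(sol, linescan_spec)
            for name, sol in scenario_solutions.items()}


def local_peak(image, depth):
    """Peak over time of the line-scan value at a given depth."""
    trace = np.array([np.interp(depth, image.positions, image.values[i])
                      for i in range(len(image.times))])
    return float(trace.max())
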